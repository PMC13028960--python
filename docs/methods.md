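# Methods

## Model and rationale

Dispersibility is treated as a distribution-level property. A formulation's
deagglomeration limit is defined operationally: the cumulative volume-based
size distribution Q3(x) measured under high-energy, device-independent dry
dispersion (compressed-air disperser at a pressure on the dispersion
plateau, conventionally 3.0 bar). Inhaler-generated aerosols, measured under
clinically relevant device resistance × pressure drop conditions, are
compared to this reference by the one-dimensional Wasserstein-1 distance,
which for CDFs reduces to the L1 distance between the curves:

    W1(F_R, F_D) = ∫ |F_R(x) − F_D(x)| dx    [µm].

W1 is the total particle volume times the distance it must be transported
along the size axis to turn the aerosol into the reference. It integrates
the entire distribution, so it responds to partial agglomerate breakup,
emergence of fines and persistence of coarse fragments — redistributions
that median-type descriptors can miss — while remaining robust to local
binning noise because it operates on cumulative curves.

### Discretization

The integral is evaluated as the left-endpoint Riemann sum
Σ_{i=1}^{n−1} |ΔF(x_i)|·(x_{i+1}−x_i) on the instrument's diameter grid;
the final grid point carries no weight. The left-endpoint rule (rather than
trapezoidal) is deliberately the simplest convention consistent with the
integral; the test suite bounds its discretization error by grid refinement
(halving the step changes W1 by less than the coarse step — first-order
convergence) and by agreement with the exact sorted-quantile transport
solution on point-mass distributions (within two grid steps). Interpolation
between grid points is linear in diameter, not log-diameter, keeping the
interpolant consistent with the linear-increment quadrature.

### Pairing and pooling

Replicate curves (typically triplicate) are pooled by pointwise arithmetic
mean into one representative curve per side *before* the distance is taken;
W1 is never averaged over replicate pairs. Pooling sorts the replicate
values at each grid point before summing so the result is exactly invariant
to replicate order. Two curves are compared on the sorted union of their
grids restricted to the intersection of their ranges; endpoint values extend
flat by at most one source grid step, and a comparison with disjoint ranges
or fewer than two shared points is an error.

### Import canonicalization

Instrument exports arrive as percent undersize. They are divided by 100,
clipped to [0, 1] and made non-decreasing by running maximum; dips deeper
than 0.01 (absolute, probability scale) are rejected as corrupted exports
rather than silently repaired, and a final value below 98% is rejected as a
truncated size range. Final values in [98%, 100%) are rescaled to exactly 1.
The 0.01 and 98% thresholds are this package's choices, set to tolerate
instrument rounding while refusing structurally incomplete data.

### Sub-lens truncation bound

A diffraction lens resolves diameters only above a cutoff (0.5 µm for an R3
lens). The worst-case contribution of unresolved fines to W1 is bounded by
assuming the largest CDF gap observed near the cutoff — taken over resolved
diameters up to twice the lens minimum, a window this package defines —
persists uniformly across an assumed unresolved interval (default 0.25–0.5
µm): bound = ΔF_max · (lens_min − floor), also reported as a fraction of the
resolved W1. With ΔF_max = 0.24 the bound is 0.06 µm, about 2% of a typical
3 µm distance, which is why lens truncation does not drive conclusions.

## Bootstrap uncertainty

Each condition's W1 is one number built from three replicate curves per
side, so uncertainty is estimated by nonparametric bootstrap: per iteration
(default 2000), replicates are resampled with replacement independently on
each side (reference and inhaler runs are independent experiments), pooled
by pointwise mean, and W1 recomputed. The bootstrap distribution is
summarized by mean, sample SD (n−1 denominator — material with three
replicates, hence fixed and documented) and the 2.5/97.5 empirical
percentiles with linear rank interpolation. The observed W1 always comes
from the unresampled pooled curves. A root seed spawns per-condition
sub-seeds by CRC-hashing the condition triple, so adding or removing
conditions never perturbs other conditions' draws. With only three
replicates per side the plug-in bootstrap SD is intrinsically conservative
low (expected factor √(2/3) ≈ 0.82 of the true repeated-experiment SD for a
near-linear statistic); the test suite verifies this calibration against a
Monte-Carlo repeated-experiment oracle, aggregating per-dataset SDs in
quadrature as variances combine.

Effect-to-noise ratios are descriptive: the formulation effect is the SD
(n−1) of bootstrap-mean W1 across formulations within each device–pressure
cell, averaged over cells; device-resistance and pressure-drop effects use
the across-level range (max − min) within fixed combinations of the other
factors, averaged likewise. The noise level for every factor is the mean
bootstrap SD over all conditions. A full factorial with at least two levels
per factor is required; missing cells are reported by name.

## Cascade impaction

Stage cut diameters follow the archival NGI calibration of Marple et al.,
d50 = C·(60/Q)^x with stage-specific coefficients, valid for 30–100 L/min
without a pre-separator; the coefficient table is shipped as data and
validated by reproducing the conventional 4.60 µm stage-2 cut at 56.6 L/min. Emitted
fraction counts the inhaler body plus mouthpiece adaptor as device retention
(both sit upstream of the induction port; configurable by construction of
the run). Fine particle fraction sums the stages whose flow-scaled cutoffs
fall below the threshold (default 5 µm) plus the MOC, over the emitted
dose — membership is cutoff-driven, never a hard-coded stage index, so the
selection adapts correctly to flow rate. MMAD and GSD come from
least-squares regression of probit-transformed cumulative undersize against
log10 cutoff diameter over stages strictly inside (0, 1); MMAD =
10^(−intercept/slope), GSD = 10^(1/slope), with a positive-slope sanity
check. The regression denominator is the size-classified mass (stages 1–7 +
MOC), excluding the induction port per standard impactor practice; an
`include_induction_port` flag exposes the alternative since conventions
differ. The MOC is the terminal undersize catch with no cutoff of its own.
Mass balance is total recovery over nominal dose with an inclusive 85–115%
acceptance window.

## Synthetic data generators

The PSD generator draws replicate curves around a bimodal volume-weighted
log-normal CDF: F = (1−w)·LN(fine) + w·LN(coarse). Spray-dried respirable
powders typically show a fine primary mode with a coarse agglomerate
shoulder whose weight w falls as dispersion energy rises; log-normals are
the standard aerosol model and give closed-form oracles (e.g. W1 between
mixture and pure fine mode is exactly w times the fine-coarse distance).
Defaults: 100 log-spaced grid points over 0.5–100 µm (an R3-lens-like
export), fine mode 2.0 µm / GSD 1.6, coarse mode 20 µm / GSD 1.8, three
replicates, replicate noise 0.05 SD on the logit of F. Noise is smooth
correlated Gaussian (unit-l2 Gaussian kernel, σ = 3 grid points) added on
the logit scale, then re-monotonized by running maximum and clipped — every
draw is a valid CDF mimicking correlated instrument variability. Noiseless
curves equal the ideal mixture exactly; generated curves keep the mixture's
mass below the grid maximum at their endpoint, as real saturating exports
do. Condition grids derive per-condition sub-seeds from the root seed by
hashing the condition, giving seed isolation between conditions.

The impaction generator is a sharp-cut stage model: an emitted fraction of
the recovered mass passes the device (retention split 3:1 body:adaptor), an
induction-port fraction deposits pre-classification, and the remainder lands
on stages by log-normal CDF differences between consecutive cutoffs (MOC
catches everything below stage 7). Real impactor stages have overlapping
collection-efficiency curves; convolving them is out of scope, so passing
recovery tests demonstrate correctness of the probit inversion, not
robustness to efficiency-curve overlap. Multiplicative log-normal noise with
specified CV (mean-preserving) is optional and off by default.

What the generators do not emulate: multimodal (>2 mode) aerosols,
non-log-normal shapes, flow-dependent induction-port classification,
inter-replicate drift, and carrier-based blends (detachment-dominated
dispersion, where a single high-energy reference state may not equal full
drug liberation). Passing tests therefore show the pipeline is correct under
the stated statistical model, not that real powders obey it.

## Numerical conventions and problem sizes

* Monotonicity tolerance on stored curves: 1e-9; dips up to 0.01 repaired at
  import; tail completeness: 98%.
* Bootstrap default 2000 iterations; fewer than 100 logs a warning.
* The bootstrap-calibration test uses 500 regenerated experiments for the
  oracle SD and 150 datasets × 500 iterations for the bootstrap aggregate —
  sizes chosen so Monte-Carlo error is a few percent while the whole suite
  runs in seconds.
* Flow-arithmetic display rounds to 0.1 (L/min, s); computation keeps full
  precision.
* All randomness flows through numpy Generators seeded from explicit integer
  seeds; every CLI output embeds version, seed and config hash.

## Known limitations

* W1 values depend on the measured common size range; comparisons should use
  matched lens/grid configurations.
* The reference state is operational (plateau of a dispersion-energy
  titration); for materials that fuse during drying it reflects stable fused
  units, not primary particles.
* Low- and high-resistance device constants are not shipped; they must come
  from user configuration (only the medium-resistance 0.025 kPa^(1/2)·min/L
  value is built in as a default table entry).
* Inferential statistics on W1 are intentionally absent; bootstrap summaries
  and effect-to-noise ratios are descriptive.
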