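"""W1 metric: Riemann-sum evaluation, metric axioms, transport oracle,
profiles, titration convergence and the sub-lens truncation bound."""

import numpy as np
import pytest
from scipy.stats import wasserstein_distance

from aerodisp import (
    DispersionCondition,
    PSDGeneratorSpec,
    ReplicateSet,
    SizeGrid,
    dispersibility_profile,
    fines_truncation_bound,
    generate_psd_replicates,
    pool_replicates,
    titration_convergence,
    wasserstein1,
)

from conftest import make_psd, random_monotone_cdf


def point_mass_cdf(grid, location):
    """Step CDF of a unit point mass at `location` on a dense grid."""
    return (grid >= location).astype(float)


class TestWasserstein1:
    def test_identical_curves_give_zero(self):
        psd = make_psd([1, 2, 3], [0.0, 0.5, 1.0])
        assert wasserstein1(psd, psd).value == 0.0

    def test_direct_riemann_sum(self):
        a = make_psd([1.0, 2.0, 3.0], [0.0, 0.5, 1.0])
        b = make_psd([1.0, 2.0, 3.0], [0.5, 1.0, 1.0])
        res = wasserstein1(a, b)
        assert res.value == pytest.approx(0.5 * 1 + 0.5 * 1)
        assert (res.grid_min, res.grid_max, res.n_grid_points) == (1.0, 3.0, 3)

    def test_final_grid_point_carries_no_weight(self):
        # curves differ only at the last grid point: left-endpoint sum ignores it
        a = make_psd([1.0, 2.0, 3.0], [0.0, 0.5, 0.9])
        b = make_psd([1.0, 2.0, 3.0], [0.0, 0.5, 1.0])
        assert wasserstein1(a, b).value == 0.0

    def test_point_mass_translation_closed_form(self):
        grid = np.arange(1.0, 7.0, 0.01)
        a = make_psd(grid, point_mass_cdf(grid, 2.0))
        b = make_psd(grid, point_mass_cdf(grid, 5.0))
        assert wasserstein1(a, b).value == pytest.approx(3.0, abs=0.02)

    def test_symmetry_and_internal_regridding(self):
        a = make_psd([1.0, 2.0, 3.0], [0.0, 0.5, 1.0])
        b = make_psd([1.5, 2.5, 3.5], [0.2, 0.7, 1.0])
        assert wasserstein1(a, b).value == pytest.approx(wasserstein1(b, a).value)
        res = wasserstein1(a, b)
        assert (res.grid_min, res.grid_max) == (1.5, 3.0)

    def test_disjoint_ranges_rejected(self):
        a = make_psd([1.0, 2.0], [0.0, 1.0])
        b = make_psd([5.0, 6.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="disjoint"):
            wasserstein1(a, b)

    def test_metric_axioms_on_random_curves(self):
        """Non-negativity, symmetry, identity and triangle inequality over
        1000 random monotone CDF pairs sharing a grid."""
        rng = np.random.default_rng(42)
        grid = SizeGrid(np.sort(rng.uniform(0.5, 50.0, 40)) + np.arange(40) * 1e-4)
        for _ in range(1000):
            f, g, h = (
                make_psd(grid.diameters, random_monotone_cdf(rng, grid))
                for _ in range(3)
            )
            d_fg = wasserstein1(f, g).value
            d_gf = wasserstein1(g, f).value
            assert d_fg >= 0.0
            assert d_fg == pytest.approx(d_gf, rel=1e-12)
            assert wasserstein1(f, f).value == 0.0
            d_fh = wasserstein1(f, h).value
            d_hg = wasserstein1(h, g).value
            assert d_fg <= d_fh + d_hg + 1e-9

    def test_agrees_with_quantile_transport_oracle_on_point_sets(self):
        """Riemann-sum W1 on a dense grid matches the sorted-quantile optimal
        transport oracle for finite weighted point sets."""
        rng = np.random.default_rng(7)
        grid = np.arange(0.5, 30.0, 0.01)
        step = 0.01
        for _ in range(20):
            pts_a = rng.uniform(1.0, 25.0, size=5)
            pts_b = rng.uniform(1.0, 25.0, size=5)
            wts_a = rng.random(5)
            wts_b = rng.random(5)
            fa = np.sum(
                [w * point_mass_cdf(grid, p) for p, w in zip(pts_a, wts_a / wts_a.sum())],
                axis=0,
            )
            fb = np.sum(
                [w * point_mass_cdf(grid, p) for p, w in zip(pts_b, wts_b / wts_b.sum())],
                axis=0,
            )
            ours = wasserstein1(make_psd(grid, fa), make_psd(grid, fb)).value
            oracle = wasserstein_distance(pts_a, pts_b, wts_a, wts_b)
            assert ours == pytest.approx(oracle, abs=2 * step)

    def test_translation_shifts_w1_by_the_shift(self):
        grid = np.arange(0.5, 40.0, 0.01)
        base = make_psd(grid, 1 / (1 + np.exp(-(grid - 10.0))))
        for delta in (0.5, 2.0, 5.0):
            shifted = make_psd(grid, 1 / (1 + np.exp(-(grid - 10.0 - delta))))
            assert wasserstein1(base, shifted).value == pytest.approx(delta, abs=0.02)

    def test_grid_refinement_first_order_convergence(self):
        """Halving the grid step changes W1 by less than the coarse step."""
        coarse = np.linspace(1.0, 21.0, 21)   # step 1.0
        fine = np.linspace(1.0, 21.0, 41)     # step 0.5
        f = lambda x: np.clip((np.log(x) - 0.5) / 2.5, 0, 1)  # noqa: E731
        g = lambda x: np.clip((np.log(x) - 1.0) / 2.2, 0, 1)  # noqa: E731
        w_coarse = wasserstein1(make_psd(coarse, f(coarse)), make_psd(coarse, g(coarse))).value
        w_fine = wasserstein1(make_psd(fine, f(fine)), make_psd(fine, g(fine))).value
        assert abs(w_coarse - w_fine) < 1.0


def _replicate_set(formulation, device_class, pressure, weight, noise=0.0, seed=0):
    cond = DispersionCondition(
        formulation=formulation,
        disperser="inhaler",
        device_resistance_class=device_class,
        pressure_drop=pressure,
    )
    spec = PSDGeneratorSpec(coarse_weight=weight, replicate_noise=noise, seed=seed)
    return generate_psd_replicates(spec, condition=cond)


def _reference_set(formulation="f", noise=0.0, seed=0, weight=0.0):
    cond = DispersionCondition(
        formulation=formulation, disperser="reference", rodos_pressure=3.0
    )
    spec = PSDGeneratorSpec(coarse_weight=weight, replicate_noise=noise, seed=seed)
    return generate_psd_replicates(spec, condition=cond)


class TestDispersibilityProfile:
    def test_identical_conditions_give_zero_everywhere(self):
        ref = _reference_set()
        dispersed = {
            ("medium", p): _replicate_set("f", "medium", p, weight=0.0)
            for p in (1.0, 2.0, 4.0)
        }
        prof = dispersibility_profile(ref, dispersed)
        assert all(res.value == pytest.approx(0.0, abs=1e-12) for *_, res in prof.entries)

    def test_w1_increases_with_coarse_agglomerate_weight(self):
        """More coarse-mode volume means more transport to reach the
        reference; checked against direct W1 on the noiseless curves."""
        ref = _reference_set()
        weights = {1.0: 0.4, 2.0: 0.2, 4.0: 0.0}
        dispersed = {
            ("medium", p): _replicate_set("f", "medium", p, weight=w)
            for p, w in weights.items()
        }
        prof = dispersibility_profile(ref, dispersed)
        by_pressure = {p: res.value for _, p, res in prof.entries}
        assert by_pressure[1.0] > by_pressure[2.0] > by_pressure[4.0]
        ref_pooled = pool_replicates(ref)
        for (_, p), rs in dispersed.items():
            direct = wasserstein1(ref_pooled, pool_replicates(rs)).value
            assert by_pressure[p] == pytest.approx(direct)

    def test_cardinality_three_by_three(self):
        ref = _reference_set()
        dispersed = {
            (c, p): _replicate_set("f", c, p, weight=0.1)
            for c in ("low", "medium", "high")
            for p in (1.0, 2.0, 4.0)
        }
        assert len(dispersibility_profile(ref, dispersed).entries) == 9

    def test_formulation_mismatch_rejected(self):
        ref = _reference_set("f")
        dispersed = {("medium", 2.0): _replicate_set("other", "medium", 2.0, 0.1)}
        with pytest.raises(ValueError, match="mismatch"):
            dispersibility_profile(ref, dispersed)


class TestTitrationConvergence:
    def test_reference_only_curve(self):
        curve = titration_convergence({3.0: _reference_set()}, 3.0)
        assert curve.points == ((3.0, 0.0),)

    def test_w1_nonincreasing_as_pressure_approaches_reference(self):
        """Coarse weight ∝ 1/pressure: rising dispersion energy converges the
        curve to the reference, so W1 falls monotonically."""
        measurements = {
            p: _reference_set(weight=0.4 / p) for p in (0.5, 1.0, 2.0)
        }
        measurements[3.0] = _reference_set(weight=0.0)
        curve = titration_convergence(measurements, 3.0)
        w1s = [w for _, w in curve.points]
        assert all(a >= b - 1e-12 for a, b in zip(w1s, w1s[1:]))
        assert curve.points[-1] == (3.0, 0.0)

    def test_replicate_vs_its_own_pool_nonnegative(self):
        rs = _reference_set(noise=0.05, seed=3)
        curve = titration_convergence({3.0: rs, 2.0: rs.replicates[0]}, 3.0)
        assert dict(curve.points)[2.0] >= 0.0

    def test_missing_reference_pressure_rejected(self):
        with pytest.raises(ValueError, match="reference pressure"):
            titration_convergence({2.0: _reference_set()}, 3.0)


class TestFinesTruncationBound:
    def test_worst_case_arithmetic(self):
        """A 0.24 cumulative-fines gap persisting over the unresolved
        0.25-0.5 µm interval adds at most 0.06 µm; against a 3.0 µm distance
        that is a 2% fractional error."""
        grid = np.linspace(0.5, 13.0, 126)  # step 0.1
        f_r = np.linspace(0.24, 1.0, grid.size)
        f_d = f_r - 0.24
        res = fines_truncation_bound(make_psd(grid, f_r), make_psd(grid, f_d))
        assert res.delta_f_max == pytest.approx(0.24)
        assert res.bound_um == pytest.approx(0.06)
        # constant 0.24 gap over 12.5 µm: W1 = 3.0 µm exactly
        assert res.fraction_of_w1 == pytest.approx(0.06 / 3.0)

    def test_identical_distributions_bound_zero(self):
        psd = make_psd([0.5, 1.0, 2.0], [0.1, 0.5, 1.0])
        res = fines_truncation_bound(psd, psd)
        assert res.bound_um == 0.0
        assert res.fraction_of_w1 == 0.0

    def test_invalid_floor_rejected(self):
        psd = make_psd([0.5, 1.0, 2.0], [0.1, 0.5, 1.0])
        with pytest.raises(ValueError):
            fines_truncation_bound(psd, psd, lens_min=0.5, assumed_floor=0.6)
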