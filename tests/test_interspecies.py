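"""Cross-species scaling, alignment, normalization and conservation scoring."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import devochron as dc
from devochron.errors import AlignmentError, InsufficientDataError
from devochron.io import frame_to_profiles
from devochron.pipeline import _species_means, _species_t0

from conftest import make_profile


def _sigmoid_profile(gene, t0, grid, a=4.0, b=3.0, c=1.0, rep="mean", scale=1.0):
    p = make_profile(a, b, c, t0, grid, gene, rep)
    return dc.ExpressionProfile(gene, rep, p.times, p.levels * scale)


class TestEstimateRateRatio:
    def test_exact_proportionality(self):
        t0_a = {"g1": 5.0, "g2": 10.0, "g3": 20.0}
        t0_b = {g: 1.3 * v for g, v in t0_a.items()}
        est = dc.estimate_rate_ratio(t0_a, t0_b)
        assert est.ratio == pytest.approx(1.3)
        assert est.r2 == pytest.approx(1.0)
        assert est.n_genes == 3

    def test_agrees_with_brute_force_slope(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(4, 24, 20)
        y = 1.3 * x * rng.lognormal(0, 0.08, 20)
        t0_a = {f"g{i}": xv for i, xv in enumerate(x)}
        t0_b = {f"g{i}": yv for i, yv in enumerate(y)}
        est = dc.estimate_rate_ratio(t0_a, t0_b)
        brute = minimize_scalar(lambda s: np.sum((y - s * x) ** 2), bounds=(0.1, 5), method="bounded")
        assert est.ratio == pytest.approx(brute.x, abs=1e-5)

    def test_exclusions_respected(self):
        t0_a = {"g1": 5.0, "g2": 10.0, "g3": 20.0, "odd": 8.0}
        t0_b = {"g1": 6.5, "g2": 13.0, "g3": 26.0, "odd": 30.0}
        est = dc.estimate_rate_ratio(t0_a, t0_b, exclude=["odd"])
        assert est.ratio == pytest.approx(1.3)
        assert est.excluded_genes == ["odd"]
        with pytest.raises(InsufficientDataError):
            dc.estimate_rate_ratio({"g1": 5.0, "g2": 10.0}, {"g1": 6.0, "g2": 12.0})


class TestRescaleAndAlign:
    def test_identity_alignment(self, grid):
        p = _sigmoid_profile("g", 10.0, grid)
        times, la, lb = dc.rescale_and_align(p, p, 1.0)
        assert np.array_equal(times, grid)
        assert la == pytest.approx(p.levels, rel=1e-9)
        assert lb == pytest.approx(p.levels, rel=1e-9)

    def test_node_coincidence(self):
        a = dc.ExpressionProfile("g", "m", [0.0, 10.0, 20.0], [1.0, 100.0, 10.0])
        b = dc.ExpressionProfile("g", "m", [0.0, 13.0, 26.0], [2.0, 3.0, 4.0])
        times, la, _ = dc.rescale_and_align(a, b, 1.3)
        # B grid point 13 coincides with scaled A node 10 -> exact level.
        assert la[list(times).index(13.0)] == pytest.approx(100.0, rel=1e-9)

    def test_against_dense_resampling_oracle(self, grid):
        a = _sigmoid_profile("g", 9.0, grid, c=1.7)
        grid_b = np.arange(0.0, 39.5, 1.0)
        b = _sigmoid_profile("g", 9.0 * 1.3, grid_b, c=1.7 / 1.3)
        times, la, _ = dc.rescale_and_align(a, b, 1.3)
        floor = a.default_floor()
        dense_t = np.arange(0.0, 39.0, 0.01)
        dense = np.interp(dense_t, a.times * 1.3, np.log10(a.levels + floor))
        oracle = 10 ** np.interp(times, dense_t, dense) - floor
        assert la == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_empty_overlap(self, grid):
        a = _sigmoid_profile("g", 10.0, grid)
        b = dc.ExpressionProfile("g", "m", grid + 100.0, a.levels)
        with pytest.raises(AlignmentError):
            dc.rescale_and_align(a, b, 1.0)


class TestNormalizeToMax:
    def test_examples(self):
        assert dc.normalize_to_max([2, 5, 10]) == pytest.approx([20, 50, 100])
        assert dc.normalize_to_max([7]) == pytest.approx([100.0])

    def test_idempotent(self):
        once = dc.normalize_to_max([3.0, 9.0, 6.0])
        assert dc.normalize_to_max(once) == pytest.approx(once)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dc.normalize_to_max([0.0, 0.0])


class TestDynamicsCorrelation:
    def test_perfect_conservation(self, grid):
        grid_b = 1.3 * grid  # node coincidence: no interpolation error
        pairs = []
        for gene, t0 in (("g1", 6.0), ("g2", 12.0), ("g3", 18.0)):
            a = _sigmoid_profile(gene, t0, grid)
            b = _sigmoid_profile(gene, 1.3 * t0, grid_b, c=1.0 / 1.3)
            pairs.append(dc.align_pair(a, b, 1.3))
        per_gene, mean = dc.dynamics_correlation(pairs)
        assert mean == pytest.approx(1.0, abs=1e-9)
        assert all(r == pytest.approx(1.0, abs=1e-9) for r in per_gene.values())

    def test_anti_phase_negative(self, grid):
        rising = _sigmoid_profile("g", 15.0, grid)
        falling = dc.ExpressionProfile("g", "m", grid, rising.levels[::-1].copy())
        pair = dc.align_pair(rising, falling, 1.0)
        assert pair.pearson < 0

    def test_scale_invariance(self, grid):
        a = _sigmoid_profile("g", 10.0, grid)
        b = _sigmoid_profile("g", 10.0, grid, c=1.2)
        r1 = dc.align_pair(a, b, 1.0).pearson
        a_scaled = _sigmoid_profile("g", 10.0, grid, scale=37.0)
        r2 = dc.align_pair(a_scaled, b, 1.0).pearson
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestRandomPairBaseline:
    @staticmethod
    def _species(grid, ratio=1.0, t0s=(5.0, 11.0, 17.0, 23.0)):
        return {
            f"g{i}": _sigmoid_profile(f"g{i}", ratio * t0, ratio * grid, c=1.0 / ratio)
            for i, t0 in enumerate(t0s)
        }

    def test_exchangeable_genes_match_baseline(self, grid):
        # Two genes with identical dynamics: baseline equals matched mean.
        pa = {g: _sigmoid_profile(g, 10.0, grid) for g in ("g1", "g2")}
        matched = np.mean([dc.align_pair(pa[g], pa[g], 1.0).pearson for g in pa])
        baseline = dc.random_pair_baseline(pa, pa, 1.0)
        assert baseline == pytest.approx(matched, abs=1e-9)

    def test_staggered_t0_baseline_below_matched(self, grid):
        pa = self._species(grid)
        pb = self._species(grid, ratio=1.3)
        pairs = [dc.align_pair(pa[g], pb[g], 1.3) for g in pa]
        _, matched = dc.dynamics_correlation(pairs)
        baseline = dc.random_pair_baseline(pa, pb, 1.3)
        assert baseline < matched

    def test_exhaustive_mode_deterministic(self, grid):
        pa = self._species(grid)
        pb = self._species(grid, ratio=1.3)
        b1 = dc.random_pair_baseline(pa, pb, 1.3)
        b2 = dc.random_pair_baseline(dict(reversed(list(pa.items()))), pb, 1.3)
        assert b1 == b2

    def test_sampled_mode_seeded(self, grid):
        pa = self._species(grid)
        pb = self._species(grid, ratio=1.3)
        s1 = dc.random_pair_baseline(pa, pb, 1.3, mode="sampled", n_pairs=6, seed=4)
        s2 = dc.random_pair_baseline(pa, pb, 1.3, mode="sampled", n_pairs=6, seed=4)
        assert s1 == s2


class TestTrueRatioIsOptimal:
    def test_matched_correlation_peaks_at_true_ratio(self):
        """Aligning with the true rho beats halving or doubling it (noiseless)."""
        cfg = dc.SimConfig(seed=5, meas_sigma=0.0, timing_cv=0.0, level_cv=0.0,
                           n_repeats=1, grid_b=1.3 * np.arange(0.0, 30.5, 1.0))
        df_a, df_b, _ = dc.generate_dataset(cfg)
        means_a = _species_means(frame_to_profiles(df_a))
        means_b = _species_means(frame_to_profiles(df_b))

        def matched_mean(ratio):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pairs = [dc.align_pair(means_a[g], means_b[g], ratio) for g in means_a]
                return dc.dynamics_correlation(pairs)[1]

        true = matched_mean(1.3)
        assert true >= matched_mean(0.65)
        assert true >= matched_mean(2.6)
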