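import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimphys.periodicity import (
    InsufficientPeaksError,
    IntervalSet,
    PeriodicityResult,
    estimate_periodicity,
    find_density_peaks,
    interval_mode,
    peak_intervals,
    stoichiometry_kde,
    weighted_gaussian_mixture,
)


def mixture_density(grid, centers, width, weights=None):
    """Oracle: naive per-kernel loop, trapezoid-normalized on the grid."""
    centers = np.asarray(centers, dtype=float)
    if weights is None:
        weights = np.ones_like(centers)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    out = np.zeros_like(grid)
    for c, w in zip(centers, weights):
        out += w * np.exp(-0.5 * ((grid - c) / width) ** 2) / (
            width * np.sqrt(2 * np.pi)
        )
    return out


class TestStoichiometryKDE:
    def test_single_sample_unimodal(self):
        dist = stoichiometry_kde([5.0])
        mode = dist.grid[np.argmax(dist.density)]
        assert mode == pytest.approx(5.0, abs=0.011)
        assert len(dist.peaks) == 1

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        dist = stoichiometry_kde(rng.uniform(1, 20, 50))
        assert np.trapezoid(dist.density, dist.grid) == pytest.approx(1.0, abs=1e-6)

    def test_two_sample_peaks_match_analytic_mixture(self):
        # oracle: maxima of the two-Gaussian mixture located numerically
        dist = stoichiometry_kde([5.0, 10.0])
        fine = np.linspace(0, 15, 150001)
        oracle = mixture_density(fine, [5.0, 10.0], 0.7)
        from scipy.signal import argrelmax

        oracle_peaks = fine[argrelmax(oracle)[0]]
        got = [p for p, _ in dist.peaks]
        assert len(got) == len(oracle_peaks) == 2
        np.testing.assert_allclose(got, oracle_peaks, atol=0.02)

    def test_weighted_mode_at_majority(self):
        dist = stoichiometry_kde([5.0, 5.0, 5.0, 10.0])
        mode = dist.grid[np.argmax(dist.density)]
        fine = np.linspace(0, 15, 150001)
        oracle = mixture_density(fine, [5.0, 5.0, 5.0, 10.0], 0.7)
        assert mode == pytest.approx(fine[np.argmax(oracle)], abs=0.02)
        assert mode == pytest.approx(5.0, abs=0.02)

    def test_empty_samples_error(self):
        with pytest.raises(ValueError):
            stoichiometry_kde([])

    def test_matches_brute_force_mixture(self):
        # spec property: vectorized KDE equals the naive mixture to 1e-9
        rng = np.random.default_rng(7)
        centers = rng.uniform(1, 15, 40)
        grid = np.sort(rng.uniform(0, 20, 1000))
        got = weighted_gaussian_mixture(grid, centers, 0.7)
        want = np.zeros_like(grid)
        for c in centers:
            want += np.exp(-0.5 * ((grid - c) / 0.7) ** 2) / (
                0.7 * np.sqrt(2 * np.pi) * centers.size
            )
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestFindDensityPeaks:
    def test_two_peaks_from_bimodal(self):
        dist = stoichiometry_kde([5.0, 10.0])
        peaks = find_density_peaks(dist)
        assert len(peaks) == 2

    def test_monotone_segment_no_interior_peak(self):
        from slimphys.periodicity import StoichiometryDistribution

        grid = np.linspace(0, 10, 500)
        dist = StoichiometryDistribution(
            grid=grid, density=np.exp(grid / 10), kernel_width=0.7
        )
        assert find_density_peaks(dist) == []

    def test_flat_density_no_peaks(self):
        from slimphys.periodicity import StoichiometryDistribution

        grid = np.linspace(0, 10, 500)
        dist = StoichiometryDistribution(
            grid=grid, density=np.ones_like(grid), kernel_width=0.7
        )
        assert find_density_peaks(dist) == []


class TestPeakIntervals:
    def test_pairwise_enumeration(self):
        iset = peak_intervals({0: [5.0, 10.0, 15.0]}, mean_stoichiometry=10.0)
        assert sorted(iset.intervals) == pytest.approx([5.0, 5.0, 10.0])
        np.testing.assert_allclose(
            np.sort(iset.weights)[::-1],
            [5.0**-0.5, 5.0**-0.5, 10.0**-0.5],
        )

    def test_adjacent_only(self):
        iset = peak_intervals(
            {0: [5.0, 10.0, 15.0]}, mean_stoichiometry=10.0, pairwise=False
        )
        assert sorted(iset.intervals) == pytest.approx([5.0, 5.0])

    def test_single_peak_empty(self):
        with pytest.raises(InsufficientPeaksError):
            peak_intervals({0: [5.0]}, mean_stoichiometry=5.0)

    def test_aggregation_across_acquisitions(self):
        iset = peak_intervals(
            {0: [5.0, 10.0], 1: [5.0, 10.0]}, mean_stoichiometry=7.5
        )
        assert sorted(iset.intervals) == pytest.approx([5.0, 5.0])
        assert iset.n_intervals == 2


class TestIntervalMode:
    def test_weighted_mixture_oracle(self):
        iset = peak_intervals({0: [5.0, 10.0, 15.0]}, mean_stoichiometry=10.0)
        result = interval_mode(iset, n_bootstrap=0)
        # oracle: evaluate the 3-kernel weighted mixture on a fine grid
        bw = 0.7 * np.sqrt(10.0 / 3)
        fine = np.linspace(0, 16, 320001)
        oracle = mixture_density(
            fine, [5.0, 5.0, 10.0], bw, weights=[5**-0.5, 5**-0.5, 10**-0.5]
        )
        assert result.periodicity == pytest.approx(fine[np.argmax(oracle)], abs=0.01)
        assert result.interval_kernel_width == pytest.approx(bw)

    def test_identical_intervals_degenerate_ci(self):
        iset = peak_intervals(
            {0: [5.0, 10.0], 1: [3.0, 8.0]}, mean_stoichiometry=6.0
        )
        result = interval_mode(iset, n_bootstrap=200, seed=0)
        assert result.periodicity == pytest.approx(5.0, abs=0.01)
        assert result.ci95[0] == pytest.approx(5.0, abs=0.01)
        assert result.ci95[1] == pytest.approx(5.0, abs=0.01)

    def test_single_interval_flagged(self):
        iset = peak_intervals({0: [5.0, 10.0]}, mean_stoichiometry=7.5)
        result = interval_mode(iset, n_bootstrap=100, seed=0)
        assert result.periodicity == pytest.approx(5.0, abs=0.01)
        assert result.degenerate_ci

    def test_ci_brackets_mode(self):
        rng = np.random.default_rng(3)
        peaks = {
            a: list(np.sort(5 * np.arange(1, 4) + rng.normal(0, 0.3, 3)))
            for a in range(6)
        }
        iset = peak_intervals(peaks, mean_stoichiometry=10.0)
        result = interval_mode(iset, n_bootstrap=300, seed=1)
        assert result.ci95[0] <= result.periodicity <= result.ci95[1]

    def test_bootstrap_seeded(self):
        peaks = {0: [5.0, 10.1], 1: [4.9, 10.0], 2: [5.2, 10.3]}
        iset = peak_intervals(peaks, mean_stoichiometry=7.5)
        r1 = interval_mode(iset, n_bootstrap=100, seed=7)
        r2 = interval_mode(iset, n_bootstrap=100, seed=7)
        assert r1.ci95 == r2.ci95

    def test_weight_rescaling_invariance(self):
        # periodicity must not change under uniform weight rescaling
        iset = peak_intervals({0: [5.0, 9.8, 15.1]}, mean_stoichiometry=10.0)
        base = interval_mode(iset, n_bootstrap=0).periodicity
        from slimphys.periodicity import _density_mode, _interval_bandwidth

        sizes = iset.intervals
        bw = _interval_bandwidth(10.0, sizes.size)
        for c in (0.1, 3.0, 100.0):
            assert _density_mode(sizes, c * iset.weights, bw) == pytest.approx(
                base, abs=1e-9
            )


class TestEstimatePeriodicity:
    def test_multiples_of_five(self):
        rng = np.random.default_rng(11)
        samples = {}
        for a in range(8):
            vals = np.concatenate(
                [
                    rng.normal(5.0, 0.7, 20),
                    rng.normal(10.0, 0.7, 12),
                    rng.normal(15.0, 0.7, 8),
                ]
            )
            samples[a] = vals.tolist()
        out = estimate_periodicity(samples, seed=0, n_bootstrap=100)
        assert out["status"] == "ok"
        assert out["result"].periodicity == pytest.approx(5.0, abs=0.5)
        lo, hi = out["result"].ci95
        assert lo <= out["result"].periodicity <= hi

    def test_no_samples(self):
        out = estimate_periodicity({})
        assert out["status"] == "insufficient peaks"
        assert out["result"] is None

    def test_single_cluster_insufficient(self):
        rng = np.random.default_rng(2)
        samples = {0: rng.normal(5.0, 0.3, 30).tolist()}
        out = estimate_periodicity(samples)
        assert out["status"] == "insufficient peaks"

    def test_result_ci_invariant(self):
        with pytest.raises(ValueError):
            PeriodicityResult(
                periodicity=5.0, ci95=(5.5, 6.0), interval_kernel_width=0.4,
                n_intervals=3,
            )


@given(
    st.lists(st.floats(0.5, 30.0), min_size=1, max_size=60),
    st.floats(0.2, 2.0),
)
@settings(max_examples=40, deadline=None)
def test_kde_density_properties(samples, width):
    dist = stoichiometry_kde(samples, kernel_width=width)
    assert np.all(dist.density >= 0)
    assert np.trapezoid(dist.density, dist.grid) == pytest.approx(1.0, abs=1e-6)
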