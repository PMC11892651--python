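import math

import numpy as np
import pytest

from ibdkit import GenomeMap
from ibdkit.split_model import (
    BinnedSpectrum,
    ModelPrediction,
    SplitModelParams,
    chi2_half_threshold,
    expected_bin_counts,
    expected_density_split,
    poisson_loglik,
    segment_density,
    time_offset_generations,
    total_rate,
)


class TestSegmentDensity:
    def test_closed_form_single_chromosome(self, one_chrom):
        # L = 1 M, m = 2, l = 0.5 M: ((L-l) m^2 + 2m) e^{-ml}
        expected = (0.5 * 4 + 4) * math.exp(-1.0)
        assert segment_density(0.5, 2.0, one_chrom) == pytest.approx(expected, rel=1e-12)

    def test_zero_beyond_longest_chromosome(self, gmap):
        assert segment_density(gmap.max_cM / 100.0 + 0.01, 5.0, gmap) == 0.0

    def test_domain_errors(self, gmap):
        with pytest.raises(ValueError):
            segment_density(-0.1, 2.0, gmap)
        with pytest.raises(ValueError):
            segment_density(0.1, 0.0, gmap)

    def test_against_crossover_placement_monte_carlo(self, one_chrom):
        """Gap-length histogram of a rate-m Poisson crossover process on one
        chromosome matches ((L-l) m^2 + 2m) e^{-ml} integrated over bins."""
        rng = np.random.default_rng(42)
        m, L = 2.0, 1.0
        n_draws = 200_000
        counts = rng.poisson(m * L, size=n_draws)
        edges = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        hist = np.zeros(len(edges) - 1)
        # draw all points at once; gaps per replicate include both chromosome ends
        total_pts = counts.sum()
        pts = rng.uniform(0.0, L, total_pts)
        start = 0
        for k in counts:
            x = np.sort(pts[start:start + k])
            start += k
            if k == 0:
                # an untouched chromosome is the whole-chromosome point mass
                # at l = L, deliberately absent from the continuous density
                continue
            gaps = np.diff(np.concatenate([[0.0], x, [L]]))
            h, _ = np.histogram(gaps, bins=edges)
            hist += h
        from scipy.integrate import quad

        for b in range(len(edges) - 1):
            mu = n_draws * quad(
                lambda l: float(segment_density(l, m, one_chrom)),
                edges[b], edges[b + 1],
            )[0]
            se = math.sqrt(mu)
            assert abs(hist[b] - mu) <= 3.5 * se, (b, hist[b], mu)

    def test_doubling_m_matches_formula_ratio(self, one_chrom):
        l, m = 0.3, 1.5
        L = 1.0
        ratio = segment_density(l, 2 * m, one_chrom) / segment_density(l, m, one_chrom)
        expected = (
            ((L - l) * 4 * m**2 + 4 * m) / ((L - l) * m**2 + 2 * m)
            * math.exp(-m * l)
        )
        assert ratio == pytest.approx(expected, rel=1e-12)


@pytest.fixture(scope="module")
def params(gmap):
    """The fitted point estimates of the study design."""
    return SplitModelParams(n0=34245, t0=18, delta_gens=17, gmap=gmap)


class TestExpectedDensitySplit:
    def test_quadrature_equals_closed_form(self, gmap):
        """Adaptive quadrature over coalescence time agrees with the analytic
        reduction to exponential moments, to 1e-9 relative."""
        for n0 in (500.0, 34245.0, 2e5):
            for t0 in (0.0, 17.0, 60.0):
                p = SplitModelParams(n0=n0, t0=t0, delta_gens=17, gmap=gmap)
                for l in (8.5, 12.0, 20.0, 45.0):
                    cf = expected_density_split(l, p)
                    qd = expected_density_split(l, p, method="quadrature")
                    assert qd == pytest.approx(cf, rel=1e-9)

    def test_point_mass_limit_small_n0(self, gmap):
        """As N0 -> 0 the coalescence-time distribution degenerates at t_min
        and lambda(l) -> segment_density(l, 2 t_min - delta); the error decays
        linearly in N0."""
        ls = np.array([8.5, 15.0, 30.0])
        direct = np.array([segment_density(l / 100, 19.0, gmap) for l in ls])
        errs = []
        for n0 in (1e-3, 1e-6):
            p = SplitModelParams(n0=n0, t0=18, delta_gens=17, gmap=gmap)
            lam = np.asarray(expected_density_split(ls, p))
            errs.append(np.max(np.abs(lam - direct) / direct))
        assert errs[1] < 1e-5
        assert errs[1] < errs[0] * 1e-2  # O(N0) convergence

    def test_monotone_decreasing_in_length(self, params):
        ls = np.linspace(8.0, 30.0, 100)
        lam = np.asarray(expected_density_split(ls, params))
        assert np.all(np.diff(lam) < 0)

    def test_monotone_decreasing_in_split_time(self, gmap):
        ls = np.array([9.0, 14.0, 25.0])
        lams = [
            np.asarray(
                expected_density_split(
                    ls, SplitModelParams(34245, t0, 17, gmap)
                )
            )
            for t0 in (18, 60, 200, 500)
        ]
        for a, b in zip(lams[:-1], lams[1:]):
            assert np.all(b < a)

    def test_cm_morgan_round_trip_is_identity(self):
        x = np.array([8.0, 12.5, 100.0])
        assert np.allclose(x / 100.0 * 100.0, x)


class TestExpectedBinCounts:
    def test_linearity_in_pairs(self, params):
        mu1 = np.array(expected_bin_counts(params, n_pairs=1).mu)
        mu2 = np.array(expected_bin_counts(params, n_pairs=2).mu)
        assert np.allclose(mu2, 2 * mu1, rtol=1e-12)

    def test_bin_additivity(self, params):
        whole = expected_bin_counts(params, bin_edges_cM=(8.0, np.inf), n_pairs=612)
        parts = expected_bin_counts(
            params, bin_edges_cM=(8.0, 12.0, 16.0, 20.0, np.inf), n_pairs=612
        )
        assert sum(parts.mu) == pytest.approx(whole.mu[0], rel=1e-9)

    def test_total_rate_consistent_with_open_bin(self, params):
        whole = expected_bin_counts(params, bin_edges_cM=(8.0, np.inf), n_pairs=1)
        assert whole.mu[0] == pytest.approx(4 * total_rate(params, 8.0), rel=1e-12)

    def test_bad_edges_rejected(self, params):
        with pytest.raises(ValueError):
            expected_bin_counts(params, bin_edges_cM=(12.0, 8.0), n_pairs=1)


class TestPoissonLoglik:
    def _pred(self, mu):
        edges = tuple(float(i) for i in range(len(mu) + 1))
        return ModelPrediction(edges, tuple(mu), 1)

    def _spec(self, obs):
        edges = tuple(float(i) for i in range(len(obs) + 1))
        return BinnedSpectrum(edges, tuple(obs), 1)

    def test_zero_count_bin(self):
        assert poisson_loglik(self._spec([0]), self._pred([1.0])) == pytest.approx(-1.0)

    def test_direct_arithmetic(self):
        ll = poisson_loglik(self._spec([2]), self._pred([2.0]))
        assert ll == pytest.approx(2 * math.log(2) - 2)

    def test_maximized_at_mu_equals_observed(self):
        from scipy.optimize import minimize_scalar

        obs = 7
        res = minimize_scalar(
            lambda mu: -poisson_loglik(self._spec([obs]), self._pred([mu])),
            bounds=(0.1, 50.0), method="bounded",
        )
        assert res.x == pytest.approx(obs, rel=1e-4)

    def test_zero_mu_with_positive_count_is_neg_inf(self):
        assert poisson_loglik(self._spec([3]), self._pred([0.0])) == -np.inf

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            poisson_loglik(self._spec([1, 2]), self._pred([1.0]))


class TestScalarHelpers:
    def test_offset_between_study_group_dates(self):
        assert time_offset_generations(519, 25, 29) == 17

    def test_offset_zero_and_exact(self):
        assert time_offset_generations(25, 25, 29) == 0
        assert time_offset_generations(100, 42, 29) == 2

    def test_offset_symmetric_and_half_up(self):
        assert time_offset_generations(25, 519, 29) == 17
        assert time_offset_generations(0, 14.5, 29) == 1  # exact .5 rounds away

    def test_chi2_drop_values(self):
        assert chi2_half_threshold() == pytest.approx(1.92, abs=0.005)
        assert chi2_half_threshold(0.95, 2) == pytest.approx(5.991 / 2, abs=0.005)
        assert chi2_half_threshold(1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_chi2_domain(self):
        with pytest.raises(ValueError):
            chi2_half_threshold(1.5)


class TestBinnedSpectrum:
    def test_from_segments_histogram(self, toy_segments):
        spec = BinnedSpectrum.from_segments(toy_segments, n_pairs=4)
        assert spec.observed == (4, 0, 0, 1)  # 9,9,10,9 medium; 25 in the open bin

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            BinnedSpectrum((8.0, 8.0), (1,), 1)
        with pytest.raises(ValueError):
            BinnedSpectrum((8.0, 12.0), (-1,), 1)
        with pytest.raises(ValueError):
            BinnedSpectrum((8.0, 12.0), (1,), 0)
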