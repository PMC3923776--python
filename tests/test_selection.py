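"""Adjusted explained deviance, bootstrap CV, t-test model selection."""

import numpy as np
import pytest

from spatregime.errors import InvalidConfigError, UndefinedAdjustmentError
from spatregime.selection import (
    ThresholdCandidate,
    adjusted_explained_deviance,
    bootstrap_cv,
    gaussian_aic,
    paired_pvalue,
    select_degree,
    select_model,
    select_threshold_model,
)
from spatregime.simulate import (
    generate_hauls,
    scenario_no_shift,
    scenario_sharp_1998,
)
from spatregime.thresholds import ThresholdSpec

from conftest import make_hauls


class TestAdjustedD2:
    def test_perfect_fit(self):
        d2, d2a = adjusted_explained_deviance(10.0, 0.0, 50, 5)
        assert d2 == 1.0 and d2a == 1.0

    def test_null_model(self):
        d2, d2a = adjusted_explained_deviance(10.0, 10.0, 50, 1)
        assert d2 == 0.0 and d2a == 0.0

    def test_arithmetic_oracle(self):
        d2, d2a = adjusted_explained_deviance(100.0, 40.0, 50, 5)
        assert d2 == pytest.approx(0.6, abs=1e-12)
        assert d2a == pytest.approx(1.0 - (49 / 45) * 0.4, abs=1e-12)

    def test_adjustment_undefined_when_n_le_p(self):
        with pytest.raises(UndefinedAdjustmentError):
            adjusted_explained_deviance(10.0, 5.0, 5, 5)

    def test_d2_adj_bounded_by_one(self, rng):
        for _ in range(50):
            null = rng.uniform(1, 100)
            resid = rng.uniform(0, 2 * null)
            n = int(rng.integers(10, 200))
            p = int(rng.integers(1, n))
            _, d2a = adjusted_explained_deviance(null, resid, n, p)
            assert d2a <= 1.0 + 1e-12


class TestGaussianAIC:
    def test_arithmetic_oracle(self):
        # independent arithmetic: n ln(2 pi rss/n) + n + 2(p+1)
        n, rss, p = 80, 12.5, 4
        expected = n * np.log(2 * np.pi * rss / n) + n + 2 * (p + 1)
        assert gaussian_aic(n, rss, p) == pytest.approx(expected, abs=1e-12)

    def test_lower_rss_lower_aic(self):
        assert gaussian_aic(100, 5.0, 3) < gaussian_aic(100, 10.0, 3)


def _step_hauls(seed, n_per_year=60):
    rng = np.random.default_rng(seed)
    years = np.repeat(np.arange(1994, 2002), n_per_year)
    n = years.size
    lon = rng.uniform(-5, 9, n)
    lat = rng.uniform(51, 61, n)
    from spatregime.gridding import mercator_correct

    lc = mercator_correct(lon, lat)
    resp = 1.0 + 0.2 * lc + 2.0 * (years >= 1998) + rng.normal(0, 1.0, n)
    return make_hauls(lon, lat, years, resp)


class TestBootstrapCV:
    def test_identical_candidates_tie_with_p_one(self):
        records = _step_hauls(1)
        cands = [
            ThresholdCandidate(ThresholdSpec(1994, 2001, (1998,)), degree_k=1),
            ThresholdCandidate(ThresholdSpec(1994, 2001, (1998,)), degree_k=1),
        ]
        s = bootstrap_cv(records, cands, n_replicates=10, seed=5)
        np.testing.assert_array_equal(s[0].d2_adj, s[1].d2_adj)
        assert paired_pvalue(s[0].d2_adj, s[1].d2_adj) == 1.0

    def test_fixed_seed_reproducible_bitwise(self):
        records = _step_hauls(2)
        for _ in range(2):
            cands = [ThresholdCandidate(ThresholdSpec(1994, 2001), degree_k=1)]
            s = bootstrap_cv(records, cands, n_replicates=8, seed=9)[0]
        cands2 = [ThresholdCandidate(ThresholdSpec(1994, 2001), degree_k=1)]
        s2 = bootstrap_cv(records, cands2, n_replicates=8, seed=9)[0]
        np.testing.assert_array_equal(s.d2_adj, s2.d2_adj)
        np.testing.assert_array_equal(s.aic, s2.aic)
        assert s.split_hashes == s2.split_hashes

    def test_paired_splits_shared_across_candidates(self):
        records = _step_hauls(3)
        cands = [
            ThresholdCandidate(ThresholdSpec(1994, 2001), degree_k=0),
            ThresholdCandidate(ThresholdSpec(1994, 2001, (1998,)), degree_k=2),
        ]
        s = bootstrap_cv(records, cands, n_replicates=6, seed=1)
        assert s[0].split_hashes == s[1].split_hashes

    def test_true_model_beats_underfit(self):
        # step at 1998, SNR 2: threshold model should win most replicates
        records = _step_hauls(4)
        cands = [
            ThresholdCandidate(ThresholdSpec(1994, 2001, (1998,)), degree_k=1),
            ThresholdCandidate(ThresholdSpec(1994, 2001), degree_k=1),
        ]
        s = bootstrap_cv(records, cands, n_replicates=20, seed=2)
        assert s[0].mean_d2_adj > s[1].mean_d2_adj

    def test_candidate_period_cache_matches_direct_fit(self):
        """The per-period cached CV path must equal a direct fit of the
        full period-crossed design."""
        from spatregime.thresholds import build_design, solve_least_squares

        records = _step_hauls(5)
        spec = ThresholdSpec(1994, 2001, (1998,))
        cand = ThresholdCandidate(spec, degree_k=1)
        cand.prepare(records)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(records))
        train, val = np.sort(perm[:360]), np.sort(perm[360:])
        aic, d2, d2a, p = cand.fit_score(train, val)
        # direct route: crossed design, single least squares
        d = build_design(records, spec, degree_k=1)
        beta, rank, _ = solve_least_squares(d.X[train], d.y[train])
        pred = d.X[val] @ beta
        resid = float(np.sum((d.y[val] - pred) ** 2))
        null = float(np.sum((d.y[val] - d.y[val].mean()) ** 2))
        d2_direct = (null - resid) / null
        assert d2 == pytest.approx(d2_direct, rel=1e-10)
        assert p == rank

    def test_validation_d2_converges_to_signal_fraction(self):
        # at n=2000 the validated D2_adj of the generating model approaches
        # the true signal fraction of variance
        rng = np.random.default_rng(42)
        n = 2000
        years = rng.integers(1994, 2002, n)
        lon = rng.uniform(-5, 9, n)
        lat = rng.uniform(51, 61, n)
        from spatregime.gridding import mercator_correct

        lc = mercator_correct(lon, lat)
        signal = 2.0 * (years >= 1998)
        noise = rng.normal(0, 1.0, n)
        records = make_hauls(lon, lat, years, signal + noise)
        true_frac = np.var(signal) / (np.var(signal) + 1.0)
        cand = ThresholdCandidate(
            ThresholdSpec(1994, 2001, (1998,)), degree_k=0
        )
        s = bootstrap_cv(records, [cand], n_replicates=30, seed=3)[0]
        assert s.mean_d2_adj == pytest.approx(true_frac, abs=0.05)


class TestSelectModel:
    def test_single_candidate_wins(self):
        records = _step_hauls(6)
        cands = [ThresholdCandidate(ThresholdSpec(1994, 2001), degree_k=1)]
        s = bootstrap_cv(records, cands, n_replicates=6, seed=1)
        winner, trace = select_model(s)
        assert winner.label == cands[0].label

    def test_parsimony_rule_prefers_simple_within_noise(self):
        # no real structure: degree-0 should beat degree-2 on parsimony
        rng = np.random.default_rng(10)
        n = 400
        years = rng.integers(1994, 2002, n)
        records = make_hauls(
            rng.uniform(-5, 9, n), rng.uniform(51, 61, n), years,
            rng.normal(0, 1, n),
        )
        cands = [
            ThresholdCandidate(ThresholdSpec(1994, 2001), degree_k=0),
            ThresholdCandidate(ThresholdSpec(1994, 2001), degree_k=2),
        ]
        s = bootstrap_cv(records, cands, n_replicates=30, seed=4)
        winner, _ = select_model(s)
        assert winner.label == cands[0].label

    def test_alpha_boundaries(self):
        records = _step_hauls(7)
        cands = [
            ThresholdCandidate(ThresholdSpec(1994, 2001), degree_k=0),
            ThresholdCandidate(ThresholdSpec(1994, 2001, (1998,)), degree_k=1),
        ]
        s = bootstrap_cv(records, cands, n_replicates=20, seed=5)
        # alpha = 0: nothing is ever significantly worse, so the most
        # parsimonious candidate wins
        w_lo, _ = select_model(s, alpha=0.0)
        assert w_lo.n_params == min(x.n_params for x in s)
        # alpha = 1: any deficit counts, so the highest mean wins
        w_hi, _ = select_model(s, alpha=1.0)
        best = max(s, key=lambda x: x.mean_d2_adj)
        assert w_hi.label == best.label

    def test_candidate_order_invariance(self):
        records = _step_hauls(8)
        c1 = [
            ThresholdCandidate(ThresholdSpec(1994, 2001), degree_k=0),
            ThresholdCandidate(ThresholdSpec(1994, 2001, (1998,)), degree_k=1),
            ThresholdCandidate(ThresholdSpec(1994, 2001), degree_k=2),
        ]
        s1 = bootstrap_cv(records, c1, n_replicates=15, seed=6)
        w1, _ = select_model(s1)
        s2 = bootstrap_cv(records, list(reversed(c1)), n_replicates=15, seed=6)
        w2, _ = select_model(s2)
        assert w1.label == w2.label

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidConfigError):
            select_model([])


class TestSelectDegree:
    def test_degree1_surface_selects_k1(self):
        rng = np.random.default_rng(21)
        n = 1500
        years = rng.integers(1994, 2002, n)
        lon = rng.uniform(-5, 9, n)
        lat = rng.uniform(51, 61, n)
        from spatregime.gridding import mercator_correct

        lc = mercator_correct(lon, lat)
        resp = 1.0 + 0.8 * lc - 0.5 * (lat - 56) + rng.normal(0, 0.3, n)
        records = make_hauls(lon, lat, years, resp)
        k, gains, capped = select_degree(
            records, ThresholdSpec(1994, 2001), n_replicates=20, seed=7
        )
        assert k == 1 and not capped

    def test_pure_noise_selects_k0(self):
        rng = np.random.default_rng(22)
        n = 600
        years = rng.integers(1994, 2002, n)
        records = make_hauls(
            rng.uniform(-5, 9, n), rng.uniform(51, 61, n), years,
            rng.normal(0, 1, n),
        )
        k, gains, capped = select_degree(
            records, ThresholdSpec(1994, 2001), n_replicates=20, seed=8
        )
        assert k == 0 and not capped


class TestSelectThresholdModel:
    def test_sharp_scenario_recovers_single_threshold(self):
        records, truth = generate_hauls(scenario_sharp_1998(), seed=0)
        spec, _, trace = select_threshold_model(
            records, 1989, 2008, max_thresholds=2, seed=0
        )
        assert spec.turnover_years == (1998,)

    def test_no_shift_scenario_keeps_zero_thresholds(self):
        records, _ = generate_hauls(scenario_no_shift(), seed=0)
        spec, _, _ = select_threshold_model(
            records, 1989, 2008, max_thresholds=2, seed=0
        )
        assert spec.turnover_years == ()
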