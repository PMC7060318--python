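"""Meta-analysis pooling against the published worked example, exact
binomial sign tests, pruning and power utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methwas.meta import (bonferroni_threshold, effect_concordance,
                          empirical_sign_null, ivw_meta, ivw_meta_tables,
                          prune_probes_by_r2, replication_power,
                          sign_concordance_binomial)


class TestIVWMeta:
    def test_published_two_cohort_pool_moa(self):
        # cg26033520: discovery (-1.55, 0.29) + replication (-1.17, 0.56)
        rec = ivw_meta([(-1.55, 0.29), (-1.17, 0.56)])
        assert rec.b == pytest.approx(-1.47, abs=0.01)
        assert rec.se == pytest.approx(0.26, abs=0.01)

    def test_published_two_cohort_pool_moment(self):
        rec = ivw_meta([(-1.09, 0.29), (-0.77, 0.53)])
        assert rec.b == pytest.approx(-1.01, abs=0.01)
        assert rec.se == pytest.approx(0.25, abs=0.01)

    def test_identical_cohorts_shrink_se_by_sqrt2(self):
        rec = ivw_meta([(0.8, 0.2), (0.8, 0.2)])
        assert rec.b == pytest.approx(0.8)
        assert rec.se == pytest.approx(0.2 / np.sqrt(2))

    def test_order_invariant_and_merge_associative(self):
        pairs = [(0.5, 0.3), (-0.2, 0.4), (0.1, 0.25)]
        a = ivw_meta(pairs)
        b = ivw_meta(pairs[::-1])
        assert (a.b, a.se) == pytest.approx((b.b, b.se))
        # pooling a pooled record with the third cohort = pooling all three
        first = ivw_meta(pairs[:2])
        merged = ivw_meta([(first.b, first.se), pairs[2]])
        assert merged.b == pytest.approx(a.b)
        assert merged.se == pytest.approx(a.se)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ivw_meta([(0.5, 0.3)])
        with pytest.raises(ValueError):
            ivw_meta([(0.5, 0.3), (0.2, 0.0)])

    def test_table_pool_restricted_to_common_probes(self):
        t1 = pd.DataFrame({"Chr": "1", "Probe": ["a", "b", "c"], "bp": 1,
                           "Gene": "", "b": [1.0, 2.0, 3.0],
                           "se": [0.5, 0.5, 0.5], "p": 0.5, "method": "MOA"})
        t2 = t1.iloc[:2].copy()
        pooled = ivw_meta_tables([t1, t2])
        assert pooled.attrs["n_common_probes"] == 2
        assert list(pooled["Probe"]) == ["a", "b"]


class TestBonferroni:
    @pytest.mark.parametrize("m,expected", [
        (229_071, 2.18e-7), (263_264, 1.9e-7), (242_205, 2.06e-7), (12, 4.2e-3),
    ])
    def test_published_thresholds(self, m, expected):
        thr = bonferroni_threshold(m)
        assert thr == pytest.approx(expected, rel=0.01)   # printed 2-3 sf

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestSignConcordance:
    def test_published_17_of_21(self):
        assert sign_concordance_binomial(17, 21) == pytest.approx(3.6e-3,
                                                                  rel=0.02)

    def test_all_concordant_closed_form(self):
        assert sign_concordance_binomial(9, 9) == pytest.approx(0.5**9)

    def test_eight_of_ten_enumerated(self):
        assert sign_concordance_binomial(8, 10) == pytest.approx(56 / 1024)

    def test_tail_complement_sums_to_one(self):
        for k in range(0, 22):
            upper = sign_concordance_binomial(k, 21)
            lower = float(stats.binom.cdf(k - 1, 21, 0.5))
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            sign_concordance_binomial(5, 4)


class TestPruning:
    def _setup(self, pvals, corr):
        probes = [f"p{i}" for i in range(len(pvals))]
        recs = pd.DataFrame({"Probe": probes, "p": pvals,
                             "b": np.ones(len(pvals))})
        C = pd.DataFrame(corr, index=probes, columns=probes)
        return recs, C

    def test_perfectly_correlated_pair_keeps_smaller_p(self):
        recs, C = self._setup([0.01, 0.001], [[1, 1], [1, 1]])
        kept = prune_probes_by_r2(recs, C, r2_max=0.1)
        assert list(kept["Probe"]) == ["p1"]

    def test_r2max_one_keeps_all_non_duplicates(self):
        corr = np.array([[1, 0.9, 0.5], [0.9, 1, 0.2], [0.5, 0.2, 1]])
        recs, C = self._setup([0.1, 0.2, 0.3], corr)
        kept = prune_probes_by_r2(recs, C, r2_max=1.0)
        assert len(kept) == 3

    def test_matches_greedy_oracle_on_block(self):
        rng = np.random.default_rng(2)
        G = rng.normal(size=(40, 5))
        G[:, 1] = G[:, 0] + rng.normal(0, 0.3, 40)      # correlated pair
        C = np.corrcoef(G, rowvar=False)
        pv = [0.04, 0.01, 0.2, 0.005, 0.5]
        recs, Cdf = self._setup(pv, C)
        kept = set(prune_probes_by_r2(recs, Cdf, r2_max=0.1)["Probe"])
        # independent re-implementation of the greedy rule
        order = sorted(range(5), key=lambda i: (pv[i], f"p{i}"))
        oracle = []
        for i in order:
            if all(C[i, j] ** 2 < 0.1 for j in oracle):
                oracle.append(i)
        assert kept == {f"p{i}" for i in oracle}
        # hard invariant: no kept pair above the r2 ceiling
        kept_idx = [int(p[1]) for p in kept]
        for a in kept_idx:
            for b in kept_idx:
                assert a == b or C[a, b] ** 2 < 0.1

    def test_misaligned_correlation_rejected(self):
        recs, C = self._setup([0.1, 0.2], [[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            prune_probes_by_r2(recs, C.iloc[:1, :1], r2_max=0.1)


class TestEmpiricalSignNull:
    def _cohorts(self, n=200, concordant_frac=0.5, seed=0):
        rng = np.random.default_rng(seed)
        b1 = rng.normal(size=n)
        # deterministic flips: the realized concordant fraction is exact
        flip = (np.arange(n) % max(1, round(1 / (1 - concordant_frac)
                                            )) == 0) if concordant_frac < 1 else np.zeros(n, bool)
        b2 = np.where(flip, -b1, b1) * np.abs(rng.normal(size=n))
        probes = [f"p{i}" for i in range(n)]
        mk = lambda b: pd.DataFrame({"Probe": probes, "b": b, "p": 0.5})
        return mk(b1), mk(b2)

    def test_coin_flip_null_tracks_exact_binomial(self):
        disc, rep = self._cohorts(concordant_frac=0.5, seed=4)
        observed = 16
        emp = empirical_sign_null(disc, rep, observed, n_select=21,
                                  reps=4000, seed=1)
        exact = sign_concordance_binomial(observed, 21)
        assert emp == pytest.approx(exact, rel=0.5, abs=0.01)

    def test_fully_concordant_null_gives_p_one(self):
        disc, rep = self._cohorts(concordant_frac=1.0, seed=5)
        p = empirical_sign_null(disc, rep, 21, n_select=21, reps=500, seed=2)
        assert p == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        disc, rep = self._cohorts(seed=6)
        p1 = empirical_sign_null(disc, rep, 15, reps=500, seed=9)
        p2 = empirical_sign_null(disc, rep, 15, reps=500, seed=9)
        assert p1 == p2

    def test_oversized_selection_rejected(self):
        disc, rep = self._cohorts(n=10)
        with pytest.raises(ValueError):
            empirical_sign_null(disc, rep, 5, n_select=11)


class TestEffectConcordance:
    def _records(self, b, p=None):
        return pd.DataFrame({"Probe": [f"p{i}" for i in range(len(b))],
                             "b": b, "p": 0.01 if p is None else p})

    def test_self_concordance_is_one(self):
        r, _, n = effect_concordance(self._records([1.0, 2.0, -1.0]),
                                     self._records([1.0, 2.0, -1.0]))
        assert r == pytest.approx(1.0)

    def test_negated_effects_give_minus_one(self):
        a = self._records([1.0, 2.0, -1.0])
        b = self._records([-1.0, -2.0, 1.0])
        r, _, _ = effect_concordance(a, b)
        assert r == pytest.approx(-1.0)

    def test_bivariate_normal_correlation_recovered(self):
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=50)
        r, _, n = effect_concordance(self._records(z[:, 0]),
                                     self._records(z[:, 1]))
        assert n == 50
        assert abs(r - 0.8) < 0.15

    def test_too_few_shared_rejected(self):
        with pytest.raises(ValueError):
            effect_concordance(self._records([1.0, 2.0]),
                               self._records([1.0, 2.0]))


class TestReplicationPower:
    se_model = staticmethod(lambda n: 2.0 / np.sqrt(n))

    def test_power_half_exactly_at_threshold(self):
        b = stats.norm.isf(0.05) / 10.0    # |b|/se(100) == z_alpha exactly
        curve, _ = replication_power(b, lambda n: 1.0 / np.sqrt(n),
                                     n_grid=[100], target=None)
        assert curve["power"].iloc[0] == pytest.approx(0.5, abs=1e-10)

    def test_power_is_monotone_and_target_found(self):
        curve, n_req = replication_power(0.3, self.se_model,
                                         n_grid=range(100, 5001, 100))
        assert (np.diff(curve["power"]) >= -1e-12).all()
        assert n_req is not None
        assert curve.set_index("n").loc[n_req, "power"] >= 0.8

    def test_null_effect_power_is_alpha(self):
        curve, n_req = replication_power(0.0, self.se_model, alpha=0.05,
                                         n_grid=[100, 1000], target=None)
        assert np.allclose(curve["power"], 0.05)
        assert n_req is None

    def test_null_effect_with_target_rejected(self):
        with pytest.raises(ValueError):
            replication_power(0.0, self.se_model, target=0.8)


class TestPooledInvariants:
    """Property tests over randomly drawn cohort summaries."""

    from hypothesis import given, settings, strategies as st

    pairs = st.lists(
        st.tuples(st.floats(-5, 5, allow_nan=False),
                  st.floats(0.01, 3, allow_nan=False)),
        min_size=2, max_size=6)

    @settings(derandomize=True, max_examples=50)
    @given(pairs)
    def test_pooled_se_never_exceeds_best_cohort(self, pairs):
        rec = ivw_meta(pairs)
        assert rec.se <= min(se for _, se in pairs) + 1e-12
        assert min(b for b, _ in pairs) - 1e-12 <= rec.b <= max(b for b, _ in pairs) + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 40), st.integers(0, 40))
    def test_binomial_tail_is_monotone_in_k(self, k, n):
        if k > n:
            with pytest.raises(ValueError):
                sign_concordance_binomial(k, n)
        elif k < n:
            assert (sign_concordance_binomial(k, n)
                    >= sign_concordance_binomial(k + 1, n))
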