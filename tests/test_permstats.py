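import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imsync import cohens_d, fdr_bh, holm_bonferroni, rm_anova_2x2, shuffle_series
from imsync.permstats import (
    condition_coefficients, consistency_test, one_sample_t, permutation_p,
    pseudo_condition_coefficients, run_consistency, single_combo_consistency,
)


# ---------------------------------------------------------------------------
# independent definitional oracles
# ---------------------------------------------------------------------------

def brute_force_bh(p):
    """BH step-up from the definition: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


def brute_force_holm(p):
    """Holm step-down from the definition: adj_(i) = max_{j<=i} (m-j+1) p_(j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order, start=1):
        running = max(running, (m - rank + 1) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


class TestShuffle:
    def test_multiset_preserved(self, rng):
        x = rng.standard_normal(50)
        out = shuffle_series(x, rng)
        np.testing.assert_allclose(np.sort(out), np.sort(x))

    def test_seed_reproducible(self):
        x = np.arange(100.0)
        a = shuffle_series(x, np.random.default_rng(7))
        b = shuffle_series(x, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_circular_shift_preserves_order(self, rng):
        x = np.arange(10.0)
        out = shuffle_series(x, rng, scheme="circular_shift")
        k = int(np.argmin(out))
        np.testing.assert_array_equal(np.roll(out, -k), x)

    def test_uniform_over_orderings(self):
        # exact enumeration oracle: each of the 6 orderings of [1,2,3]
        # should occur with frequency 1/6 within 3 binomial SEs
        rng = np.random.default_rng(5)
        counts = {}
        n = 10_000
        for _ in range(n):
            key = tuple(shuffle_series(np.array([1, 2, 3]), rng))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 6) < 3 * se


class TestMultipleComparisons:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)
        assert holm_bonferroni([0.03])[0] == pytest.approx(0.03)

    def test_bh_hand_example(self):
        q = fdr_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_holm_hand_example(self):
        np.testing.assert_allclose(holm_bonferroni([0.01, 0.04]), [0.02, 0.04])

    def test_holm_order_equivariance(self, rng):
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        np.testing.assert_allclose(holm_bonferroni(p)[perm],
                                   holm_bonferroni(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])
        with pytest.raises(ValueError):
            holm_bonferroni([-0.1])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_bh_matches_definition(self, p):
        np.testing.assert_allclose(fdr_bh(p), brute_force_bh(p), atol=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_holm_matches_definition(self, p):
        np.testing.assert_allclose(holm_bonferroni(p), brute_force_holm(p),
                                   atol=1e-12)

    def test_bh_q_at_least_p(self, rng):
        p = rng.uniform(size=40)
        assert np.all(fdr_bh(p) >= p - 1e-15)


class TestEffectSizes:
    def test_cohens_d_hand_formula(self):
        assert cohens_d([0.2, 0.4]) == pytest.approx(0.3 / np.std([0.2, 0.4], ddof=1))

    def test_zero_sd_signalled(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            cohens_d([0.5, 0.5, 0.5])

    def test_antisymmetry(self, rng):
        v = rng.standard_normal(15)
        assert cohens_d(-v) == pytest.approx(-cohens_d(v))

    def test_one_sample_t_degenerate(self):
        assert one_sample_t(np.zeros(8)) == 0.0
        assert one_sample_t(np.full(8, 0.3)) == np.inf


class TestRmAnova2x2:
    def test_all_cells_equal_zero_f(self):
        y = np.full((8, 2, 2), 1.7)
        res = rm_anova_2x2(y)
        for eff in res.values():
            assert eff["F"] == 0.0

    def test_pure_vision_effect_no_noise(self):
        n = 10
        y = np.zeros((n, 2, 2))
        y[:, :, 1] = 1.0  # vision axis is fast
        res = rm_anova_2x2(y)
        assert res["vision"]["F"] == np.inf
        assert res["proximity"]["F"] == 0.0
        assert res["interaction"]["F"] == 0.0

    def test_matches_pingouin_on_random_tables(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(100):
            n = int(rng.integers(5, 12))
            y = rng.standard_normal((n, 2, 2))
            res = rm_anova_2x2(y)
            df = pd.DataFrame({
                "subj": np.repeat(np.arange(n), 4),
                "A": np.tile([0, 0, 1, 1], n),
                "B": np.tile([0, 1, 0, 1], n),
                "y": y.reshape(-1),
            })
            tab = pg.rm_anova(data=df, dv="y", within=["A", "B"],
                              subject="subj", detailed=True)
            f = tab.set_index("Source")["F"]
            assert res["proximity"]["F"] == pytest.approx(f["A"], abs=1e-8, rel=1e-8)
            assert res["vision"]["F"] == pytest.approx(f["B"], abs=1e-8, rel=1e-8)
            assert res["interaction"]["F"] == pytest.approx(f["A * B"],
                                                            abs=1e-8, rel=1e-8)

    def test_eta_g_in_unit_interval(self, rng):
        y = rng.standard_normal((9, 2, 2))
        for eff in rm_anova_2x2(y).values():
            assert 0.0 <= eff["eta_g"] <= 1.0

    def test_f_invariant_to_constant_shift(self, rng):
        y = rng.standard_normal((7, 2, 2))
        r1 = rm_anova_2x2(y)
        r2 = rm_anova_2x2(y + 42.0)
        for e in r1:
            assert r1[e]["F"] == pytest.approx(r2[e]["F"], rel=1e-10)


class TestPermutationMachinery:
    def test_permutation_p_strict_and_smoothed(self):
        null = np.array([1.0, 2.0, 3.0, 4.0])
        assert permutation_p(2.5, null[:, None])[0] == pytest.approx(0.5)
        assert permutation_p(5.0, null[:, None])[0] == 0.0
        assert permutation_p(5.0, null[:, None], smoothing=True)[0] == \
            pytest.approx(1 / 5)

    def test_zero_genuine_coefficients_give_half_p(self, rng):
        genuine = np.zeros((10, 55))
        pseudo = rng.standard_normal((500, 10, 55)) * 0.1
        res = consistency_test(genuine, pseudo)
        assert np.all(res["t"] == 0.0)
        assert res["p_raw"].mean() == pytest.approx(0.5, abs=0.05)

    def test_single_combo_strong_coupling_p_zero(self, rng):
        n, n_dyads = 800, 12
        shared = rng.standard_normal((n_dyads, n))
        a = np.abs(shared + 0.3 * rng.standard_normal((n_dyads, n)))
        b = np.abs(shared + 0.3 * rng.standard_normal((n_dyads, n)))
        res = single_combo_consistency(a, b, n_perm=200, rng=rng)
        assert res.p_raw == 0.0
        assert res.genuine_stat > 10

    def test_too_few_dyads_refused(self, rng):
        a = np.abs(rng.standard_normal((2, 100)))
        with pytest.raises(ValueError, match="at least 3 dyads"):
            single_combo_consistency(a, a, 10, rng)

    def test_pseudo_coefficients_reproducible(self, tiny_study):
        study, _cfg = tiny_study
        p1 = pseudo_condition_coefficients(study, 20, np.random.default_rng(3))
        p2 = pseudo_condition_coefficients(study, 20, np.random.default_rng(3))
        np.testing.assert_array_equal(p1, p2)

    def test_genuine_stats_independent_of_n_perm(self, tiny_study):
        study, _cfg = tiny_study
        g1 = condition_coefficients(study)
        r1 = run_consistency(study, n_perm=10, rng=np.random.default_rng(0),
                             genuine=g1)
        r2 = run_consistency(study, n_perm=30, rng=np.random.default_rng(99),
                             genuine=g1)
        np.testing.assert_allclose(r1["t"], r2["t"])

    def test_coupled_study_detects_vision_combos(self, tiny_study):
        study, _cfg = tiny_study
        rng = np.random.default_rng(4)
        res = run_consistency(study, n_perm=100, rng=rng, smoothing=True)
        vis = res[res.vision == "Vision"]
        novis = res[res.vision == "NoVision"]
        # coupling is homologous and Vision-only in this fixture
        from imsync.synchrony import COMBO_LABELS, HOMOLOGOUS_COMBOS
        hom = [COMBO_LABELS[k] for k in HOMOLOGOUS_COMBOS]
        assert vis[vis.combo.isin(hom)]["p_raw"].median() < 0.05
        assert novis["p_raw"].median() > 0.2
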