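import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circsponge import diffexpr, quantify, synth
from helpers_oracles import bh_bruteforce


class TestFoldChange:
    def test_ratio_four_in_small_pseudo_limit(self):
        _fc, lfc = diffexpr.fold_change(100.0, 400.0, pseudo=1e-9)
        assert lfc == pytest.approx(2.0, abs=1e-9)

    def test_double_zero_is_symmetric(self):
        fc, lfc = diffexpr.fold_change(0.0, 0.0, pseudo=0.5)
        assert fc == 1.0 and lfc == 0.0

    def test_dropout_regime_reaches_extreme_log2fc(self):
        """A circRNA absent in the reference group and abundant in the test
        group lands in the |log2FC| ~ 18-20 regime for a pseudocount of a
        few RPM, and stays finite."""
        pseudo = 1e6 / (2**19 - 1)
        _fc, lfc = diffexpr.fold_change(0.0, 1e6, pseudo=pseudo)
        assert lfc == pytest.approx(19.0, abs=1e-9)
        for p in (0.5, 1.0, 4.0):
            _fc, l = diffexpr.fold_change(0.0, 1e6, pseudo=p)
            assert 17.0 < l < 21.5 and np.isfinite(l)

    @given(
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=1e-6, max_value=10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, a, b, pseudo):
        _f1, l1 = diffexpr.fold_change(a, b, pseudo)
        _f2, l2 = diffexpr.fold_change(b, a, pseudo)
        assert l1 == pytest.approx(-l2, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.fold_change(-1.0, 1.0, 0.5)


def _counts_frame(ref_counts, test_counts):
    n = len(ref_counts[0])
    data = {}
    for r, col in enumerate(ref_counts):
        data[f"r{r}"] = col
    for t, col in enumerate(test_counts):
        data[f"t{t}"] = col
    counts = pd.DataFrame(data)
    groups = {f"r{r}": "ref" for r in range(len(ref_counts))}
    groups.update({f"t{t}": "test" for t in range(len(test_counts))})
    return counts, groups


class TestDeTest:
    def test_all_zero_feature_gets_p_one(self):
        counts, groups = _counts_frame([[0, 10]], [[0, 10]])
        p = diffexpr.de_test(counts, groups, "ref", "test")
        assert p.iloc[0] == 1.0

    def test_central_outcome_is_not_significant(self):
        # m=10 split 5/5 under pi0=0.5 (balanced library sizes)
        counts, groups = _counts_frame([[5, 100]], [[5, 100]])
        p = diffexpr.de_test(counts, groups, "ref", "test")
        assert p.iloc[0] == 1.0

    def test_extreme_outcome_matches_enumeration(self):
        # balanced library sizes (pi0 = 1/2), m=10 all in test:
        # two-sided p = 2 * (1/2)^10
        counts, groups = _counts_frame([[0, 110]], [[10, 100]])
        p = diffexpr.de_test(counts, groups, "ref", "test")
        assert p.iloc[0] == pytest.approx(2 / 1024, rel=1e-12)

    def test_welch_log_method_orders_signal(self):
        # a large flat ballast feature keeps the library sizes comparable
        counts, groups = _counts_frame(
            [[10, 12, 10000], [11, 13, 10000], [9, 12, 10000]],
            [[80, 11, 10000], [90, 12, 10000], [85, 10, 10000]],
        )
        p = diffexpr.de_test(counts, groups, "ref", "test", method="welch_log")
        assert p.iloc[0] < 0.05 < p.iloc[1]

    def test_unknown_method_rejected(self):
        counts, groups = _counts_frame([[1]], [[1]])
        with pytest.raises(ValueError):
            diffexpr.de_test(counts, groups, "ref", "test", method="bogus")


class TestBhAdjust:
    def test_hand_evaluated_step_up(self):
        q = diffexpr.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert diffexpr.bh_adjust([0.2])[0] == 0.2

    def test_matches_bruteforce_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1.0, size=500)
        q = diffexpr.bh_adjust(p)
        assert np.allclose(q, bh_bruteforce(p), atol=1e-12)
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([0.0, 0.5])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-9, 1.0, size=40)
        perm = rng.permutation(40)
        assert np.allclose(diffexpr.bh_adjust(p)[perm], diffexpr.bh_adjust(p[perm]))


class TestClassify:
    @pytest.mark.parametrize(
        "lfc,q,expected",
        [
            (1.5, 0.01, "up"),
            (-2.0, 0.2, "ns"),
            (1.0, 0.01, "ns"),  # strict inequality at the boundary
            (-1.5, 0.01, "down"),
            (0.5, 0.001, "ns"),
        ],
    )
    def test_threshold_logic(self, lfc, q, expected):
        assert diffexpr.classify(lfc, q) == expected


class TestSharedDe:
    def test_intersection_order_stable(self):
        assert diffexpr.shared_de(["a", "b", "c"], ["c", "b", "d"]) == ["b", "c"]

    def test_disjoint_empty(self):
        assert diffexpr.shared_de(["a"], ["b"]) == []

    def test_persistent_planted_circs_are_shared(self):
        cfg = synth.SynthConfig(seed=13, n_circ=400, frac_de=0.3, mean_count=50.0,
                                n_genes=60, n_true_axes=4, hub_mirna_fanin=6,
                                hub_mirna_fanout=8)
        data = synth.build(cfg)
        rpm = quantify.rpm(data.counts)
        comps = data.truth.comparisons
        results = {}
        for comp in comps:
            ref, test = comp.split("_vs_")
            results[comp] = diffexpr.run_comparison(data.counts, rpm, data.group_of, ref, test)
        shared = diffexpr.shared_de(
            diffexpr.de_ids(results[comps[0]]), diffexpr.de_ids(results[comps[1]])
        )
        planted_persistent = set(data.truth.de_circ_ids[comps[0]]) & set(
            data.truth.de_circ_ids[comps[1]]
        )
        assert planted_persistent and planted_persistent <= set(shared)


class TestTrend:
    def test_monotone_profiles(self):
        assert diffexpr.trend_classify([1, 2, 3])[1] == "continuous_increase"
        assert diffexpr.trend_classify([3, 2, 1])[1] == "continuous_decrease"

    def test_peaked_profiles(self):
        assert diffexpr.trend_classify([1, 5, 2])[1] == "increase_decrease"
        assert diffexpr.trend_classify([5, 1, 2])[1] == "decrease_increase"

    def test_population_zscore_values(self):
        z, _ = diffexpr.trend_classify([1, 2, 3])
        assert np.allclose(z, [-1.22474487, 0.0, 1.22474487])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_profiles_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.trend_classify([2, 2, 2])
        with pytest.raises(ValueError):
            diffexpr.trend_classify([1, 1, 3])


def test_run_comparison_output_contract(small_data):
    rpm = quantify.rpm(small_data.counts)
    res = diffexpr.run_comparison(small_data.counts, rpm, small_data.group_of, "Ac4", "Ac5")
    assert list(res.columns) == ["fc", "log2fc", "p", "q", "status"]
    assert ((res["p"] > 0) & (res["p"] <= 1)).all()
    assert set(res["status"]) <= {"up", "down", "ns"}
    # status is consistent with its own q / log2fc columns
    for _cid, row in res.iterrows():
        assert row["status"] == diffexpr.classify(row["log2fc"], row["q"])
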