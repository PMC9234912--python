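import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncnet.diffexpr import (apply_de_filters, bh_adjust,
                             infer_layer_from_prefix, moderated_t_test,
                             split_layers, two_sample_t)
from lncnet.types import Layer

from conftest import make_matrix, make_meta


def _random_case(seed, n_feat=50, na=8, nb=7, effect=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_feat, na + nb))
    x[:, :na] += effect
    m = make_matrix(x)
    meta = make_meta(["A"] * na + ["B"] * nb)
    return m, meta


class TestModeratedT:
    def test_identical_groups_give_null_result(self):
        x = np.tile([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], (5, 1))
        x += np.random.default_rng(0).normal(size=(5, 1))  # feature offsets
        m = make_matrix(x)
        meta = make_meta(["A"] * 3 + ["B"] * 3)
        res = moderated_t_test(m, meta)
        assert np.allclose(res["log2_fc"], 0.0)
        assert np.allclose(res["p_raw"], 1.0)

    def test_d0_zero_recovers_pooled_t_exactly(self):
        m, meta = _random_case(1)
        res = moderated_t_test(m, meta, d0=0)
        xa, xb = m.values[:, :8], m.values[:, 8:]
        oracle = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
        assert np.abs(res["statistic"].to_numpy() - oracle.statistic).max() <= 1e-10
        assert np.abs(res["p_raw"].to_numpy() - oracle.pvalue).max() <= 1e-10

    def test_huge_d0_pools_variances_to_prior(self):
        m, meta = _random_case(2)
        res = moderated_t_test(m, meta, d0=1e8)
        s2_post = res.attrs["s2_post"]
        assert np.abs(s2_post - res.attrs["s0_sq"]).max() <= 1e-5

    def test_estimated_prior_shrinks_between_limits(self):
        m, meta = _random_case(3, n_feat=300)
        res = moderated_t_test(m, meta)
        s2_post = res.attrs["s2_post"]
        raw = moderated_t_test(m, meta, d0=0).attrs["s2_post"]
        s0 = res.attrs["s0_sq"]
        lo = np.minimum(raw, s0) - 1e-12
        hi = np.maximum(raw, s0) + 1e-12
        assert ((s2_post >= lo) & (s2_post <= hi)).all()

    def test_null_p_values_uniform(self):
        m, meta = _random_case(4, n_feat=2000, na=20, nb=20)
        res = moderated_t_test(m, meta)
        frac = (res["p_raw"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_degenerate_all_constant_rejected(self):
        m = make_matrix(np.ones((10, 6)))
        meta = make_meta(["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValueError, match="zero residual variance"):
            moderated_t_test(m, meta)


class TestTwoSampleT:
    def test_hand_example(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        meta = make_meta(["A"] * 3 + ["B"] * 3)
        res = two_sample_t(m, meta)
        assert res["statistic"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        assert res["df"].iloc[0] == 4
        assert res["p_raw"].iloc[0] == pytest.approx(0.0213, abs=2e-4)

    def test_group_role_swap_negates_t_keeps_p(self):
        # reference group = first-occurring level; leading with B swaps roles
        m, _ = _random_case(5)
        meta_ab = make_meta(["A"] * 8 + ["B"] * 7)
        swapped = make_matrix(np.hstack([m.values[:, 8:], m.values[:, :8]]),
                              sample_ids=m.sample_ids[8:] + m.sample_ids[:8])
        meta_ba = make_meta(["B"] * 7 + ["A"] * 8,
                            sample_ids=swapped.sample_ids)
        r1 = two_sample_t(m, meta_ab)
        r2 = two_sample_t(swapped, meta_ba)
        assert np.allclose(r1["statistic"], -r2["statistic"])
        assert np.allclose(r1["p_raw"], r2["p_raw"])

    def test_null_t_values_bounded(self):
        m, meta = _random_case(6, n_feat=500, na=20, nb=20)
        res = two_sample_t(m, meta)
        assert res["statistic"].abs().max() < 6


class TestBHAdjust:
    def test_hand_stepup(self):
        q = bh_adjust([0.005, 0.009, 0.04, 0.05, 0.2])
        assert np.allclose(q, [0.0225, 0.0225, 0.0625, 0.0625, 0.2])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == 0.3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @staticmethod
    def brute_force(p):
        """q_i = smallest FDR level at which p_i would be rejected."""
        p = np.asarray(p)
        m = len(p)
        out = np.empty(m)
        for i, pi in enumerate(p):
            candidates = [pj * m / (p <= pj).sum() for pj in p if pj >= pi]
            out[i] = min(1.0, min(candidates))
        return out

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), self.brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(8)
        p = rng.random(200)
        ours = bh_adjust(p)
        theirs = sm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_property_matches_oracle_on_arbitrary_vectors(self):
        from hypothesis import given, settings, strategies as st
        floats01 = st.floats(min_value=0.0, max_value=1.0,
                             allow_nan=False, allow_infinity=False)

        @settings(max_examples=100, derandomize=True, deadline=None)
        @given(st.lists(floats01, min_size=1, max_size=25))
        def check(p):
            q = bh_adjust(p)
            assert np.allclose(q, self.brute_force(p), atol=1e-12)
            assert ((q >= np.asarray(p) - 1e-15) & (q <= 1.0)).all()

        check()

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(9)
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()


class TestFilters:
    def _result(self, p_adj, log2_fc):
        return pd.DataFrame({
            "layer": "mrna", "log2_fc": log2_fc, "statistic": 0.0, "df": 10.0,
            "p_raw": p_adj, "p_adj": p_adj, "significant": False,
            "passes_fc": False,
        }, index=["f1"])

    def test_fdr_boundary_inclusive(self):
        res = apply_de_filters(self._result(0.05, 1.0))
        assert bool(res["significant"].iloc[0])

    def test_fc_boundary_strict(self):
        res = apply_de_filters(self._result(0.01, 0.58), use_fc=True)
        assert not bool(res["passes_fc"].iloc[0])

    def test_passing_both_gates(self):
        res = apply_de_filters(self._result(0.04, 0.6), use_fc=True)
        assert bool(res["significant"].iloc[0]) and bool(res["passes_fc"].iloc[0])

    def test_fc_gate_off_by_default(self):
        res = apply_de_filters(self._result(0.04, 0.1))
        assert bool(res["passes_fc"].iloc[0])


class TestSplitLayers:
    def _results(self, ids):
        return pd.DataFrame({
            "layer": "transcript", "log2_fc": 0.0, "statistic": 0.0,
            "df": 1.0, "p_raw": 1.0, "p_adj": 1.0,
            "significant": False, "passes_fc": True,
        }, index=ids)

    def test_prefix_rule(self):
        mrna, lnc = split_layers(self._results(["NM_0001", "NR_0002", "XR_0003"]))
        assert list(mrna.index) == ["NM_0001"]
        assert list(lnc.index) == ["NR_0002", "XR_0003"]

    def test_ensembl_prefix_is_noncoding(self):
        _, lnc = split_layers(self._results(["ENST00000504733"]))
        assert list(lnc.index) == ["ENST00000504733"]

    def test_explicit_map_overrides_prefix(self):
        mrna, lnc = split_layers(self._results(["NR_0002"]),
                                 annotation={"NR_0002": Layer.MRNA})
        assert list(mrna.index) == ["NR_0002"] and lnc.empty

    def test_empty_input(self):
        mrna, lnc = split_layers(self._results([]))
        assert mrna.empty and lnc.empty

    def test_unannotated_feature_rejected(self):
        with pytest.raises(ValueError, match="GENE_X"):
            split_layers(self._results(["GENE_X"]))

    def test_prefix_inference_helper(self):
        assert infer_layer_from_prefix("NM_001") == Layer.MRNA
        assert infer_layer_from_prefix("XR_001") == Layer.LNCRNA
        assert infer_layer_from_prefix("weird") is None
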