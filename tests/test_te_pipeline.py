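"""TE pipeline: CPM, all-pairs TE, ratio testing, BH, summaries, concordance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from translatekit import te_pipeline as tep
from translatekit.io_formats import ExpressionMatrix

from conftest import make_matrix


def brute_force_bh(pvals):
    """Independent BH construction: sort, p*m/rank, cumulative min from top."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestCPM:
    def test_single_gene_column_is_one_million(self):
        m = make_matrix([[7.0], [0.0]], conditions=("CRPC",))
        c = tep.cpm(m)
        assert c.values[0, 0] == pytest.approx(1e6)
        assert c.unit == "CPM"

    def test_hand_arithmetic(self):
        m = make_matrix([[1.0], [3.0]], conditions=("CRPC",))
        c = tep.cpm(m)
        assert c.values[:, 0] == pytest.approx([250_000, 750_000])

    def test_scale_invariance_per_column(self):
        m = make_matrix([[1.0, 5.0], [3.0, 7.0]])
        scaled = make_matrix([[10.0, 5.0], [30.0, 7.0]])
        assert tep.cpm(m).values == pytest.approx(tep.cpm(scaled).values)

    def test_zero_column_rejected(self):
        m = make_matrix([[0.0], [0.0]], conditions=("CRPC",))
        with pytest.raises(ValueError, match="all-zero"):
            tep.cpm(m)


class TestFilterExpressed:
    def test_boundary_is_inclusive_and_zeros_drop(self):
        # g0 sits exactly at min_cpm everywhere; g1 is absent from translatome
        trans = tep.cpm(make_matrix([[5.0, 5.0], [995.0, 995.0]]))
        # scale so g0 lands exactly on 5 CPM: 5/1000 * 1e6 = 5000... use raw
        trans = ExpressionMatrix(trans.genes, trans.samples,
                                 [[5.0, 5.0], [10.0, 10.0]], unit="CPM")
        poly = ExpressionMatrix(trans.genes,
                                [s.__class__(s.sample_id.replace("total", "poly"),
                                             s.condition, "polysomal", s.replicate)
                                 for s in trans.samples],
                                [[5.0, 5.0], [0.0, 0.0]], unit="CPM")
        kept = tep.filter_expressed(trans, poly, min_cpm=5.0)
        assert kept == ["g0"]

    def test_matches_brute_force_on_simulated_set(self, small_sim):
        _, transcriptome, translatome, _ = small_sim
        trans, poly = tep.cpm(transcriptome), tep.cpm(translatome)
        kept = set(tep.filter_expressed(trans, poly, min_cpm=5.0,
                                        min_fraction_of_samples=0.5))
        expected = set()
        for i, gid in enumerate(trans.gene_ids):
            ok_t = np.mean(trans.values[i] >= 5.0) >= 0.5
            ok_p = np.mean(poly.values[i] >= 5.0) >= 0.5
            if ok_t and ok_p:
                expected.add(gid)
        assert kept == expected


class TestPairwiseTE:
    def _pair(self, trans_vals, poly_vals, condition="CRPC"):
        trans = ExpressionMatrix(
            make_matrix(trans_vals, conditions=("CRPC",) * len(trans_vals[0])).genes,
            make_matrix(trans_vals, conditions=("CRPC",) * len(trans_vals[0])).samples,
            trans_vals, unit="CPM",
        )
        base = make_matrix(poly_vals, conditions=("CRPC",) * len(poly_vals[0]),
                           fraction="polysomal")
        poly = ExpressionMatrix(base.genes, base.samples, poly_vals, unit="CPM")
        return tep.pairwise_te(trans, poly, condition)

    def test_formula(self):
        te = self._pair([[5.0, 5.0]], [[10.0, 10.0]])
        assert te["g0"] == pytest.approx([2.0, 2.0, 2.0, 2.0])

    def test_two_by_two_gives_four_values(self):
        te = self._pair([[4.0, 8.0]], [[2.0, 6.0]])
        assert len(te["g0"]) == 4
        assert sorted(te["g0"]) == pytest.approx([0.25, 0.5, 0.75, 1.5])

    def test_zero_transcriptome_gives_missing_not_inf(self):
        te = self._pair([[0.0, 5.0]], [[10.0, 10.0]])
        vals = te["g0"]
        assert np.isnan(vals).sum() == 2  # the zero-denominator replicate row
        assert np.nansum(np.isfinite(vals)) == 2

    def test_absent_condition_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            self._pair([[1.0]], [[1.0]], condition="ER")


class TestTERatioTest:
    def test_null_gene_unchanged(self):
        te_s = {"g": np.array([1.0, 2.0, 4.0])}
        res = tep.te_ratio_test(te_s, {"g": np.array([1.0, 2.0, 4.0])})
        assert res[0].te_ratio == pytest.approx(1.0)
        assert res[0].te_class == "unchanged"

    def test_ratio_arithmetic_and_degenerate_variance(self):
        res = tep.te_ratio_test(
            {"g": np.array([1.0, 1.0, 1.0, 1.0])},
            {"g": np.array([2.0, 2.0, 2.0, 2.0])},
        )
        assert res[0].te_ratio == pytest.approx(2.0)
        # all-identical replicate values: t statistic undefined
        assert res[0].te_class == "untestable"
        assert math.isnan(res[0].p_raw)

    def test_untestable_with_fewer_than_two_values(self):
        res = tep.te_ratio_test(
            {"g": np.array([1.0, np.nan, np.nan])},
            {"g": np.array([2.0, 2.1, 1.9])},
        )
        assert res[0].te_class == "untestable"

    def test_partition_into_classes(self, small_sim):
        _, transcriptome, translatome, _ = small_sim
        df = tep.run_te_pipeline(transcriptome, translatome, "CRPC", "ER")
        assert len(df) == len(transcriptome.genes)
        assert set(df.te_class) <= set(tep.TE_CLASSES)
        assert df.te_class.isin(tep.TE_CLASSES).all()

    def test_antisymmetry_under_condition_swap(self, small_sim):
        _, transcriptome, translatome, _ = small_sim
        trans, poly = tep.cpm(transcriptome), tep.cpm(translatome)
        te_c = tep.pairwise_te(trans, poly, "CRPC")
        te_e = tep.pairwise_te(trans, poly, "ER")
        fwd = {r.gene_id: r for r in tep.te_ratio_test(te_c, te_e)}
        rev = {r.gene_id: r for r in tep.te_ratio_test(te_e, te_c)}
        for gid, r in fwd.items():
            if math.isfinite(r.te_ratio) and r.te_ratio > 0:
                assert rev[gid].te_ratio == pytest.approx(1.0 / r.te_ratio)
                assert rev[gid].log2_te_ratio == pytest.approx(-r.log2_te_ratio)

    def test_te_invariant_to_library_scaling(self, small_sim):
        _, transcriptome, translatome, _ = small_sim
        scaled_values = translatome.values.copy()
        scaled_values[:, 0] *= 13.0
        scaled = ExpressionMatrix(
            translatome.genes, translatome.samples, scaled_values
        )
        te_a = tep.pairwise_te(tep.cpm(transcriptome), tep.cpm(translatome), "CRPC")
        te_b = tep.pairwise_te(tep.cpm(transcriptome), tep.cpm(scaled), "CRPC")
        for gid in te_a:
            np.testing.assert_allclose(te_a[gid], te_b[gid], rtol=1e-12)

    def test_adjusted_p_matches_brute_force_bh(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(3, 60))
            te_s = {f"g{i}": rng.lognormal(0, 0.3, 5) for i in range(n)}
            te_r = {f"g{i}": rng.lognormal(0, 0.3, 5) for i in range(n)}
            res = tep.te_ratio_test(te_s, te_r)
            tested = [r for r in res if not math.isnan(r.p_raw)]
            adj = brute_force_bh([r.p_raw for r in tested])
            for r, a in zip(tested, adj):
                assert r.p_adj == pytest.approx(a, abs=1e-12)
                assert r.p_adj >= r.p_raw - 1e-12


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=200)
)
def test_bh_brute_force_matches_statsmodels(pvals):
    """The frozen BH oracle agrees with the library adjustment everywhere."""
    from statsmodels.stats.multitest import multipletests

    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    np.testing.assert_allclose(brute_force_bh(pvals), adj, atol=1e-12)


class TestSummaries:
    def test_all_unit_ratios_give_zero_median(self):
        te = {f"g{i}": np.array([1.0, 2.0, 3.0]) for i in range(5)}
        res = tep.te_ratio_test(te, {k: v.copy() for k, v in te.items()})
        (summary,) = tep.summarize_te(res)
        assert summary.median_log2_te_ratio == pytest.approx(0.0)

    def test_significant_only_uses_up_down_exactly(self, small_sim):
        _, transcriptome, translatome, _ = small_sim
        trans, poly = tep.cpm(transcriptome), tep.cpm(translatome)
        res = tep.te_ratio_test(
            tep.pairwise_te(trans, poly, "CRPC"),
            tep.pairwise_te(trans, poly, "ER"),
            biotypes={g.gene_id: g.biotype for g in transcriptome.genes},
        )
        (summary,) = tep.summarize_te(res, significant_only=True)
        assert summary.n == sum(1 for r in res if r.te_class in ("up", "down"))


class TestConcordance:
    def test_printed_overlap_fractions(self):
        # 119 of 608 transcriptome-up genes also translatome-up -> 20%
        a = {f"g{i}" for i in range(608)}
        b = {f"g{i}" for i in range(119)} | {f"x{i}" for i in range(50)}
        assert tep.concordance_fraction(a, b, "nearest") == 20
        # 136 of 361 -> 37% under floor rounding
        a2 = {f"g{i}" for i in range(361)}
        b2 = {f"g{i}" for i in range(136)}
        assert tep.concordance_fraction(a2, b2, "floor") == 37

    def test_identical_sets_give_100(self):
        assert tep.concordance_fraction({"a", "b"}, {"b", "a"}) == 100

    def test_empty_query_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tep.concordance_fraction(set(), {"a"})
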