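"""Origin classification, two-hit integration and genotype-group t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tscpipe.cna import CopySegment
from tscpipe.hits import (
    classify_origin,
    grouped_expression_test,
    integrate_hits,
    summarize_cohort,
)

TSC2 = ("chr16", 2_050_000, 2_090_000)


def _call(pos0=2_060_000, dp=100, alt=50, **kw):
    row = dict(CHROM="chr16", POS=pos0 + 1, REF="C", ALT="T", SAMPLE="L1",
               DP=dp, AD_REF=dp - alt, AD_ALT=alt, IMPACT="high",
               PATHOGENIC_DB="pathogenic", POP_AF=np.nan, PLATFORM="WES",
               CLASS="nonsense")
    row.update(kw)
    return pd.Series(row)


class TestClassifyOrigin:
    def test_present_in_normal_is_germline(self):
        assert classify_origin(_call(alt=47), _call(alt=48)) == "germline"

    def test_low_normal_vaf_is_mosaic(self):
        assert classify_origin(_call(alt=30), _call(dp=1000, alt=20)) == "mosaic"

    def test_absent_from_normal_is_somatic(self):
        assert classify_origin(_call(alt=20), _call(alt=0)) == "somatic"

    def test_unmatched_midrange_vaf_on_copy_neutral_locus(self):
        assert classify_origin(_call(alt=47), None, "normal") == "predicted_germline"

    def test_unmatched_high_vaf_in_cnloh(self):
        assert classify_origin(_call(alt=92), None, "cn_loh") == "predicted_germline"

    def test_unmatched_low_vaf_is_predicted_somatic(self):
        assert classify_origin(_call(alt=15), None, "normal") == "predicted_somatic"

    def test_no_copy_state_falls_back_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            origin = classify_origin(_call(alt=50), None, None)
        assert origin == "predicted_germline"
        assert "copy-state" in caplog.text


def _cnloh_segment():
    return CopySegment("chr16", 0, 3_000_000, 800, mean_lrr=0.01, mean_mbaf=0.8,
                       state="cn_loh")


def _accepted(*rows):
    return pd.DataFrame([dict(r) for r in rows])


class TestIntegrateHits:
    def test_germline_nonsense_plus_cnloh(self):
        calls = _accepted(_call(CLASS="nonsense", ORIGIN="germline"))
        geno = integrate_hits(calls, [_cnloh_segment()], lesion_id="L1")
        assert geno.n_hits == 2
        assert geno.combination == "cn_loh+point"
        assert geno.truncating == 2  # CN-LOH duplicates the truncating allele

    def test_germline_missense_plus_cnloh_not_truncating(self):
        calls = _accepted(_call(CLASS="missense", IMPACT="moderate",
                                ORIGIN="germline"))
        geno = integrate_hits(calls, [_cnloh_segment()])
        assert geno.n_hits == 2
        assert geno.truncating == 0

    def test_sole_cnloh_not_counted(self):
        geno = integrate_hits(_accepted(), [_cnloh_segment()])
        assert geno.n_hits == 0

    def test_single_missense_one_hit(self):
        calls = _accepted(_call(CLASS="missense", ORIGIN="germline"))
        geno = integrate_hits(calls, [])
        assert geno.n_hits == 1 and geno.combination is None

    def test_two_point_hits_same_gene(self):
        calls = _accepted(
            _call(CLASS="frameshift", REF="CAG", ALT="C", ORIGIN="germline"),
            _call(pos0=2_070_000, CLASS="nonsense", ORIGIN="somatic"),
        )
        geno = integrate_hits(calls, [])
        assert geno.n_hits == 2
        assert geno.combination == "point+point"
        assert geno.truncating == 2

    def test_deletion_segment_and_variant_row_deduplicated(self):
        calls = _accepted(
            _call(CLASS="large_deletion", ALT="<DEL>", pos0=2_055_000,
                  ORIGIN="germline"),
        )
        seg = CopySegment("chr16", 2_050_000, 2_120_000, 30, mean_lrr=-0.5,
                          mean_mbaf=0.7, state="deletion")
        geno = integrate_hits(calls, [seg])
        assert geno.n_hits == 1
        assert geno.hits[0]["class"] == "large_deletion"

    def test_trans_heterozygous_kept_verbatim(self):
        calls = _accepted(
            _call(CLASS="nonsense", ORIGIN="germline"),
            _call(CHROM="chr9", pos0=20_010_000, CLASS="missense",
                  ORIGIN="somatic"),
        )
        geno = integrate_hits(calls, [])
        assert geno.genes == {"TSC1", "TSC2"}
        assert geno.n_hits == 2


def _geno(patient, lesion_type="TUB", hits=(), eligible=True, lesion_id=None):
    from tscpipe.hits import LesionGenotype

    g = LesionGenotype(patient, lesion_id or f"{patient}-{lesion_type}1",
                       lesion_type, eligible=eligible)
    g.hits = [dict(gene="TSC2", **h) for h in hits]
    return g


class TestSummarize:
    def test_empty_summary(self):
        assert summarize_cohort([]) == {}

    def test_single_patient_gene_split(self):
        g = _geno("P1", hits=[{"class": "nonsense", "origin": "germline"}])
        s = summarize_cohort([g])
        assert s["gene_pct"]["TSC2"] == 100.0
        assert s["pct_patients_with_mutation"] == 100.0

    def test_all_one_hit_no_combinations(self):
        gs = [_geno(f"P{i}", hits=[{"class": "missense", "origin": "germline"}])
              for i in range(5)]
        assert summarize_cohort(gs)["combination_histogram"] == {}

    def test_ineligible_one_hit_excluded_from_denominator(self):
        two = _geno("P1", hits=[{"class": "nonsense", "origin": "germline"},
                                {"class": "cn_loh", "origin": "somatic"}])
        one_ok = _geno("P2", hits=[{"class": "nonsense", "origin": "germline"}])
        one_bad = _geno("P3", eligible=False,
                        hits=[{"class": "nonsense", "origin": "germline"}])
        s = summarize_cohort([two, one_ok, one_bad])
        assert s["two_hit_by_type"]["TUB"] == {
            "two_hit": 1, "eligible": 2, "pct": 50.0,
        }


class TestGroupedExpressionTest:
    def test_identical_groups_null(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labs = np.array(["a"] * 3 + ["b"] * 3)
        results, _, _ = grouped_expression_test(vals, labs)
        assert results[0].t == pytest.approx(0.0)
        assert results[0].p == pytest.approx(1.0)

    def test_hand_case_welch(self):
        # A = {1,2,3}, B = {4,5,6}: t = -3.674 on 4 df (variances equal here)
        vals = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        labs = np.array(["A"] * 3 + ["B"] * 3)
        results, _, _ = grouped_expression_test(vals, labs)
        r = results[0]
        assert r.t == pytest.approx(-3.674, abs=1e-3)
        assert r.df == pytest.approx(4.0)

    def test_matches_reference_welch(self, rng):
        vals = rng.normal(size=24)
        labs = np.repeat(["g1", "g2", "g3"], 8)
        results, bart, bart_p = grouped_expression_test(vals, labs)
        for r in results:
            a = vals[labs == r.group_a]
            b = vals[labs == r.group_b]
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert r.t == pytest.approx(float(ref.statistic))
            assert r.p == pytest.approx(float(ref.pvalue))
        groups = [vals[labs == g] for g in ("g1", "g2", "g3")]
        ref_b = stats.bartlett(*groups)
        assert bart == pytest.approx(float(ref_b.statistic))

    def test_bh_adjustment_bounds(self, rng):
        vals = np.concatenate([rng.normal(size=10), rng.normal(2.0, 1, 10),
                               rng.normal(4.0, 1, 10)])
        labs = np.repeat(["a", "b", "c"], 10)
        results, _, _ = grouped_expression_test(vals, labs)
        for r in results:
            assert r.p_adj >= r.p - 1e-12
            assert 0.0 <= r.p_adj <= 1.0

    def test_small_group_skipped(self, caplog):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        labs = np.array(["a", "a", "b", "b", "tiny"])
        with caplog.at_level("INFO"):
            results, _, _ = grouped_expression_test(vals, labs)
        assert [(r.group_a, r.group_b) for r in results] == [("a", "b")]
        assert "skipped" in caplog.text

    def test_power_on_separated_groups(self, rng):
        # N(0,1) n=15 vs N(1.5,1) n=15: adjusted p < 0.05 in >=95% of 200 runs
        hits_sig = 0
        for _ in range(200):
            vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(1.5, 1, 15)])
            labs = np.repeat(["a", "b"], 15)
            results, _, _ = grouped_expression_test(vals, labs)
            hits_sig += results[0].p_adj < 0.05
        assert hits_sig >= 190
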