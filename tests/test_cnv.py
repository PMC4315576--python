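"""Control-panel depth-ratio CNV calling, ledger filters, MLPA rule, QC."""
import numpy as np
import pandas as pd
import pytest

from pseudocall.calling import VariantCall
from pseudocall.cnv import (CnvCall, CnvParams, apply_filter_ledger, call_cnv,
                            coverage_qc, mlpa_ratio, normalize_and_ratio,
                            normalize_coverage, split_targets,
                            target_coverage_matrix)

TARGETS = [("m", i * 200, i * 200 + 150, f"exon{i + 1}") for i in range(8)]
NAMES = [t[3] for t in TARGETS]


def _depths(per_target, length=1600):
    arr = np.zeros(length)
    for (c, s, e, _n), d in zip(TARGETS, per_target):
        arr[s:e] = d
    return {"m": arr}


def _ratio_frame(values_by_target, controls=6):
    data = {f"ctrl{i + 1}": [values_by_target.get(n, 0.0) for n in NAMES]
            for i in range(controls)}
    return pd.DataFrame(data, index=NAMES)


class TestCoverageMatrix:
    def test_uniform_sample(self):
        m = target_coverage_matrix({"s": _depths([100] * 8)}, TARGETS)
        assert (m.loc["s"] == 100).all()

    def test_zero_coverage_target(self):
        m = target_coverage_matrix({"s": _depths([50] * 7 + [0])}, TARGETS)
        assert m.loc["s", "exon8"] == 0

    def test_half_covered_target_weighted_mean(self):
        arr = np.zeros(1600)
        arr[0:75] = 100  # half of exon1's 150 bases
        m = target_coverage_matrix({"s": {"m": arr}}, TARGETS)
        assert m.loc["s", "exon1"] == pytest.approx(100 * 75 / 150)

    def test_split_targets_honours_max_segment(self):
        segs = split_targets([("m", 0, 900, "big")], 300)
        assert len(segs) == 3
        assert segs[0][1:3] == (0, 300)
        assert segs[-1][2] == 900
        assert all(e - s <= 300 for _c, s, e, _n in segs)


class TestNormalizeAndRatio:
    def test_identical_samples_ratio_zero(self):
        depths = {"index": _depths([100] * 8), "c1": _depths([100] * 8),
                  "c2": _depths([100] * 8), "c3": _depths([100] * 8)}
        m = target_coverage_matrix(depths, TARGETS)
        r = normalize_and_ratio(m, "index", ["c1", "c2", "c3"])
        assert np.allclose(r.values, 0.0)

    def test_halved_target_log2_minus_one(self):
        idx = [100] * 8
        idx[3] = 50
        depths = {"index": _depths(idx)}
        for i in range(3):
            depths[f"c{i + 1}"] = _depths([100] * 8)
        m = target_coverage_matrix(depths, TARGETS)
        r = normalize_and_ratio(m, "index", ["c1", "c2", "c3"])
        # internal normalisation shifts all ratios by the sample-mean factor
        expected_shift = np.log2(1 / (7.5 / 8))
        assert np.allclose(r.loc["exon4"], -1 + expected_shift, atol=1e-9)

    def test_global_scaling_invariance(self):
        depths = {"index": _depths([200] * 8), "c1": _depths([100] * 8),
                  "c2": _depths([100] * 8), "c3": _depths([100] * 8)}
        m = target_coverage_matrix(depths, TARGETS)
        r = normalize_and_ratio(m, "index", ["c1", "c2", "c3"])
        assert np.allclose(r.values, 0.0)

    def test_row_normalisation_unit_mean(self):
        m = target_coverage_matrix({"a": _depths([10, 20, 30, 40, 10, 20, 30, 40]),
                                    "b": _depths([5] * 8)}, TARGETS)
        norm = normalize_coverage(m)
        assert np.allclose(norm.mean(axis=1), 1.0)


class TestCallCnv:
    def test_full_support_deletion_passes(self):
        r = _ratio_frame({"exon4": -1.0})
        calls = call_cnv(r, TARGETS)
        dels = [c for c in calls if c.direction == "del"]
        assert len(dels) == 1
        assert dels[0].status == "pass"
        assert dels[0].targets == ["exon4"]
        assert dels[0].support_fraction == 1.0

    def test_partial_support_is_indicated(self):
        r = _ratio_frame({})
        r.loc["exon4", ["ctrl1", "ctrl2", "ctrl3", "ctrl4"]] = -1.0  # 4/6 controls
        calls = call_cnv(r, TARGETS)
        assert [c.status for c in calls] == ["indicated"]

    def test_below_magnitude_no_call(self):
        r = _ratio_frame({n: -0.5 for n in NAMES})
        assert call_cnv(r, TARGETS) == []

    def test_adjacent_passing_targets_merge(self):
        r = _ratio_frame({"exon3": -1.0, "exon4": -0.9, "exon5": -1.1})
        calls = call_cnv(r, TARGETS)
        assert len(calls) == 1
        call = calls[0]
        assert call.targets == ["exon3", "exon4", "exon5"]
        assert (call.start, call.end) == (400, 950)

    def test_non_adjacent_events_stay_separate(self):
        r = _ratio_frame({"exon2": -1.0, "exon6": -1.0})
        assert len(call_cnv(r, TARGETS)) == 2

    def test_amplification_direction(self):
        r = _ratio_frame({"exon7": 1.0})
        calls = call_cnv(r, TARGETS)
        assert calls[0].direction == "amp" and calls[0].status == "pass"


class TestFilterLedger:
    def _del_call(self, start=400, end=550, targets=("exon3",)):
        return CnvCall("m", start, end, list(targets), "del", -1.0, 1.0, "pass")

    def test_critical_region_filtered(self):
        params = CnvParams(critical_regions=(("m", 450, 500, "exon3"),))
        out = apply_filter_ledger([self._del_call()], params)
        assert out[0].status == "filtered"
        assert out[0].filter_reasons == {"critical-region"}

    def test_artifact_region_filtered(self):
        params = CnvParams(artifact_regions=(("m", 400, 550, "exon43"),))
        out = apply_filter_ledger([self._del_call()], params)
        assert out[0].filter_reasons == {"artifact-region"}

    def test_het_evidence_filters_deletion(self):
        het = VariantCall("m", 470, "A", "G", 0.45, "het", "standard", 500)
        out = apply_filter_ledger([self._del_call()], CnvParams(), [het])
        assert out[0].status == "filtered"
        assert out[0].filter_reasons == {"het-evidence"}

    def test_hom_fraction_call_is_not_het_evidence(self):
        hom_like = VariantCall("m", 470, "A", "G", 0.95, "hom", "standard", 500)
        out = apply_filter_ledger([self._del_call()], CnvParams(), [hom_like])
        assert out[0].status == "pass"

    def test_clean_call_unchanged(self):
        out = apply_filter_ledger([self._del_call()], CnvParams())
        assert out[0].status == "pass" and out[0].filter_reasons == set()

    def test_filter_order_independent(self):
        params_a = CnvParams(critical_regions=(("m", 450, 500, "x"),),
                             artifact_regions=(("m", 400, 420, "y"),))
        params_b = CnvParams(artifact_regions=(("m", 400, 420, "y"),),
                             critical_regions=(("m", 450, 500, "x"),))
        het = VariantCall("m", 470, "A", "G", 0.5, "het", "standard", 500)
        out_a = apply_filter_ledger([self._del_call()], params_a, [het])
        out_b = apply_filter_ledger([self._del_call()], params_b, [het])
        assert out_a[0].filter_reasons == out_b[0].filter_reasons == {
            "critical-region", "artifact-region", "het-evidence"}


class TestMlpa:
    @pytest.mark.parametrize("ratio,expected", [
        (0.5, "deletion"), (0.74, "deletion"),
        (0.75, "normal"), (1.0, "normal"),
    ])
    def test_deletion_rule_grid(self, ratio, expected):
        probes = mlpa_ratio({"p1": ratio}, {"p1": 1.0})
        assert probes[0].status == expected
        assert probes[0].ratio == pytest.approx(ratio)

    def test_zero_control_rpa_undefined(self):
        probes = mlpa_ratio({"p1": 0.5}, {"p1": 0.0})
        assert probes[0].status == "undefined" and probes[0].ratio is None

    def test_mismatched_probe_sets_rejected(self):
        with pytest.raises(ValueError):
            mlpa_ratio({"p1": 1.0}, {"p2": 1.0})


class TestCoverageQc:
    def test_uniform_coverage_full_fraction(self):
        df, agg = coverage_qc(_depths([100] * 8), TARGETS, floor=20)
        assert (df["frac_ge_floor"] == 1.0).all()
        assert agg["frac_bases_ge_floor"] == 1.0
        assert agg["lowcov_targets"] == []

    def test_empty_target_zero(self):
        targets = TARGETS + [("m", 1590, 1590, "empty")]
        df, _agg = coverage_qc(_depths([100] * 8), targets, floor=20)
        assert df.loc["empty", "frac_ge_floor"] == 0.0

    def test_half_low_half_high(self):
        arr = np.zeros(1600)
        arr[0:75] = 10
        arr[75:150] = 30
        df, _agg = coverage_qc({"m": arr}, [("m", 0, 150, "t")], floor=20)
        assert df.loc["t", "frac_ge_floor"] == pytest.approx(0.5)


class TestCnvRecovery:
    """Planted heterozygous deletions against a simulated control panel."""

    def test_single_exon_deletion_recovered(self, single_exon_cnv_study):
        study = single_exon_cnv_study
        passes = [c for c in study.index_calls
                  if c.status == "pass" and c.direction == "del"]
        assert len(passes) == 1
        assert passes[0].targets == ["exon22"]

    def test_seven_exon_deletion_merges_to_one_event(self, multi_exon_cnv_study):
        study = multi_exon_cnv_study
        passes = [c for c in study.index_calls
                  if c.status == "pass" and c.direction == "del"]
        assert len(passes) == 1
        assert passes[0].targets == [f"exon{i}" for i in range(15, 22)]

    def test_control_vs_control_specificity(self, single_exon_cnv_study):
        assert single_exon_cnv_study.control_pass_calls == 0

    def test_deletion_log2_near_minus_one(self, single_exon_cnv_study):
        call = [c for c in single_exon_cnv_study.index_calls
                if c.status == "pass"][0]
        assert -1.4 < call.median_log2 < -0.7
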