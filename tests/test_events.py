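"""Event classification, loss levels, fraction recovery, HL resolution."""

import numpy as np
import pandas as pd
import pytest

from cnevolve import simulate as sim
from cnevolve.events import (
    CnEvent,
    Thresholds,
    assign_ocl,
    call_events,
    classify_segment,
    detect_loss_levels,
    estimate_fraction,
    resolve_homozygous_subclonal,
)
from cnevolve.pipeline import analyze_sample
from cnevolve.windows import expected_log2


def seg_row(mean_log2, fold=None, chrom="chr1", start=0, end=5_000_000, n_windows=100):
    return pd.Series(dict(chrom=chrom, start=start, end=end, n_windows=n_windows,
                          mean_log2=mean_log2, mean_folded_baf=fold))


class TestClassifySegment:
    def test_clonal_het_loss(self):
        ev = classify_segment(seg_row(-1.0, fold=0.5), purity=1.0)
        assert ev.category == "LOH"
        assert ev.clonality == "complete"
        assert ev.est_fraction == pytest.approx(1.0, abs=0.01)

    def test_balanced_deep_loss_is_subclonal_hl(self):
        """Log2 at the het-loss depth with BAF ~ 0.5: homozygous loss in half the cells."""
        evs = [classify_segment(seg_row(-1.0, fold=0.01), purity=1.0),
               classify_segment(seg_row(-1.0, fold=0.45, start=6_000_000, end=11_000_000), purity=1.0)]
        detect_loss_levels(evs)
        resolve_homozygous_subclonal(evs)
        hl = evs[0]
        assert hl.category == "HL" and hl.clonality == "subclonal"
        assert hl.est_fraction == pytest.approx(0.5, abs=0.01)

    def test_neutral_segment_no_event(self):
        assert classify_segment(seg_row(0.0, fold=0.01), purity=1.0) is None

    def test_shallow_balanced_below_threshold(self):
        assert classify_segment(seg_row(-0.05, fold=0.01), purity=1.0) is None

    def test_deep_loss_beyond_het_range_is_hl(self):
        # log2 -2.4 at purity 0.9 implies p*f > 1 under c=1: must be homozygous
        ev = classify_segment(seg_row(-2.4, fold=0.02), purity=0.9)
        assert ev.category == "HL"
        assert ev.clonality == "complete"

    def test_missing_baf_indeterminate(self):
        ev = classify_segment(seg_row(-0.4, fold=None), purity=1.0)
        assert ev.category == "LOH"
        assert ev.clonality == "indeterminate"
        assert ev.est_fraction == pytest.approx(2 - 2 ** 0.6, abs=1e-9)

    @pytest.mark.parametrize(
        "copies,category",
        [(3, "HCG"), (6, "VHCG"), (8, "EHCG")],
    )
    def test_gain_grades_purity_adjusted(self, copies, category):
        """The grade depends on the purity-corrected copy state, not raw log2."""
        for purity in (1.0, 0.7):
            L = expected_log2(copies, purity, 1.0)
            ev = classify_segment(seg_row(L, fold=0.2), purity=purity)
            assert ev.is_gain
            assert ev.category == category
            assert ev.clonality == "indeterminate"  # gains carry no clonality call

    def test_noiseless_classification_zero_confusion(self):
        """On exact inputs each category band maps to exactly one label."""
        cases = [
            (expected_log2(1, 1, 1), 0.5, 1.0, "LOH"),
            (expected_log2(0, 0.95, 1), 0.02, 0.95, "HL"),
            (0.30, 0.25, 1.0, "CG"),
            (expected_log2(3, 1, 1), 0.3, 1.0, "HCG"),
            (expected_log2(5, 1, 1), 0.35, 1.0, "VHCG"),
            (expected_log2(8, 1, 1), 0.4, 1.0, "EHCG"),
        ]
        for L, fold, purity, want in cases:
            ev = classify_segment(seg_row(L, fold=fold), purity=purity)
            assert ev.category == want, (L, want)


class TestEstimateFraction:
    @pytest.mark.parametrize("m,pf", [(0.0, 1.0), (0.5, 0.0), (1 / 3, 0.5)])
    def test_baf_inversion(self, m, pf):
        est = estimate_fraction(mean_log2=np.log2(1 - pf / 2), folded_baf=0.5 - m)
        assert est.baf_based == pytest.approx(pf, abs=1e-9)

    def test_log2_diagnostic_consistent(self):
        for pf in (0.2, 0.5, 0.8, 1.0):
            L = float(np.log2((2 - pf) / 2))
            minor = (1 - pf) / (2 - pf)
            est = estimate_fraction(L, folded_baf=0.5 - minor)
            assert est.log2_based == pytest.approx(pf, abs=1e-9)
            assert abs(est.baf_based - est.log2_based) < 1e-9

    def test_impossible_fold_clipped(self):
        est = estimate_fraction(-0.5, folded_baf=0.6)
        assert est.baf_based == 1.0

    def test_hom_loss_uses_log2_route(self):
        est = estimate_fraction(-1.0, folded_baf=0.01, kind="hom_loss")
        assert est.baf_based is None
        assert est.log2_based == pytest.approx(0.5)


class TestLossLevels:
    def test_two_levels_recovered_with_membership(self):
        rng = np.random.default_rng(0)
        evs = []
        for i in range(12):
            evs.append(classify_segment(seg_row(-1.0 + rng.normal(0, 0.02),
                                                fold=0.45, start=i * 10**6,
                                                end=(i + 1) * 10**6), purity=1.0))
        for i in range(17):
            evs.append(classify_segment(seg_row(-0.37 + rng.normal(0, 0.02),
                                                fold=0.15, chrom="chr2",
                                                start=i * 10**6,
                                                end=(i + 1) * 10**6), purity=1.0))
        detect_loss_levels(evs)
        assert sum(e.loss_level == 1 for e in evs) == 17
        assert all(e.loss_level == 1 for e in evs if e.mean_log2 > -0.6)
        assert all(e.clonality == "subclonal" for e in evs if e.loss_level == 1)

    def test_single_level_all_complete(self):
        evs = [classify_segment(seg_row(-1.0 + d, fold=0.45), purity=1.0)
               for d in (-0.02, 0.0, 0.02)]
        detect_loss_levels(evs)
        assert all(e.loss_level == 2 for e in evs)

    def test_close_levels_not_split(self):
        evs = [classify_segment(seg_row(L, fold=0.3), purity=1.0)
               for L in (-0.50, -0.50, -0.60, -0.60)]
        detect_loss_levels(evs, min_separation=0.25)
        assert all(e.loss_level == 2 for e in evs)


class TestAssignOcl:
    def test_loss_inside_earlier_gain_relabeled(self):
        gain = CnEvent("chr8", 87_000_000, 146_000_000, "HCG", mean_log2=0.9)
        loss = CnEvent("chr8", 112_000_000, 146_000_000, "LOH", mean_log2=0.3)
        loss.category = "LOH"
        assign_ocl([loss], [gain])
        assert loss.category == "OCL"

    def test_unrelated_loss_untouched(self):
        gain = CnEvent("chr8", 87_000_000, 146_000_000, "HCG", mean_log2=0.9)
        loss = CnEvent("chr2", 0, 40_000_000, "LOH", mean_log2=-1.0)
        assign_ocl([loss], [gain])
        assert loss.category == "LOH"


class TestParameterRecovery:
    def test_metastasis_mimic_level1_membership(self, scenario, analyzed):
        """17 catastrophic-burst losses recovered as level 1 with >=95% accuracy."""
        evs = analyzed["metastasis"][2]
        truth = scenario.truth_events("metastasis")
        sub = truth[truth.is_loss & (truth.clone == "F") & (truth.kind == "het_loss")]
        level1 = [e for e in evs if e.loss_level == 1]
        assert len(level1) == 17
        correct = 0
        for _, t in sub.iterrows():
            hit = any(
                e.chrom == t.chrom and abs(e.start - t.start) <= 100_000
                and abs(e.end - t.end) <= 100_000
                for e in level1
            )
            correct += hit
        assert correct / len(sub) >= 0.95

    def test_subclonal_hom_loss_fraction_recovered(self, scenario, analyzed):
        evs = analyzed["metastasis"][2]
        hl = [e for e in evs if e.category == "HL" and e.clonality == "subclonal"]
        assert len(hl) == 1
        truth_pf = scenario.tree.carrier_fraction("metastasis", "F")
        assert hl[0].est_fraction == pytest.approx(truth_pf, abs=0.05)

    def test_fraction_estimates_internally_consistent(self, analyzed):
        """BAF- and log2-based p*f agree within 0.1 for called het losses."""
        for s, (_, _, evs) in analyzed.items():
            for e in evs:
                if e.category == "LOH" and e.folded_baf is not None and np.isfinite(e.folded_baf):
                    est = estimate_fraction(e.mean_log2, e.folded_baf)
                    if est.baf_based is not None:
                        assert abs(est.baf_based - est.log2_based) < 0.1
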