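"""Cross-sample totals, concordance, retention and the progression verdict."""

import numpy as np
import pandas as pd
import pytest

from cnevolve.events import CnEvent
from cnevolve.progression import (
    SampleEventSet,
    classify_progression,
    concordance,
    match_events,
    stage_acquisition,
    totals,
)
from cnevolve.tables import read_event_table, write_event_table


@pytest.fixture(scope="module")
def fixture_sets(event_table_path):
    sets = read_event_table(event_table_path)
    order = ["DCIS 1", "DCIS 2", "Primary tumor", "Metastasis"]
    by_name = {s.sample: s for s in sets}
    return [by_name[n] for n in order]


def ev(chrom, start_mb, end_mb, category="LOH", **kw):
    return CnEvent(chrom, int(start_mb * 1e6), int(end_mb * 1e6), category, **kw)


class TestEventTableIO:
    def test_fixture_dimensions(self, event_table_path):
        sets = read_event_table(event_table_path)
        assert {s.sample for s in sets} == {"DCIS 1", "DCIS 2", "Primary tumor", "Metastasis"}
        assert sum(len(s.events) for s in sets) == 36 + 44 + 59 + 95

    def test_reversed_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tstart_mb\tend_mb\tlength_mb\ttype\ts1\n1\t5.0\t2.0\t3.0\tLOH\tx\n")
        with pytest.raises(ValueError, match="end"):
            read_event_table(p)

    def test_unknown_category_rejected_with_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tstart_mb\tend_mb\tlength_mb\ttype\ts1\n1\t1.0\t2.0\t1.0\tBOGUS\tx\n")
        with pytest.raises(ValueError, match="row 1.*BOGUS"):
            read_event_table(p)

    def test_length_mismatch_warns(self, tmp_path):
        p = tmp_path / "warn.tsv"
        p.write_text("chrom\tstart_mb\tend_mb\tlength_mb\ttype\ts1\n1\t1.0\t2.0\t1.5\tLOH\tx\n")
        with pytest.warns(UserWarning, match="length"):
            read_event_table(p)

    def test_round_trip(self, fixture_sets, tmp_path):
        p = tmp_path / "events.tsv"
        write_event_table(fixture_sets, p)
        back = read_event_table(p)
        by_name = {s.sample: s for s in back}
        for st in fixture_sets:
            got = by_name[st.sample]
            a = sorted((e.chrom, e.start, e.end, e.category) for e in st.events)
            b = sorted((e.chrom, e.start, e.end, e.category) for e in got.events)
            assert a == b


class TestTotals:
    def test_empty_set_zero(self):
        t = totals(SampleEventSet("s", []))
        assert (t.gained_mb, t.lost_mb, t.n_gain, t.n_loss) == (0, 0, 0, 0)

    def test_first_lesion_totals(self, fixture_sets):
        t = totals(fixture_sets[0])
        assert t.gained_mb == 99.14
        assert t.lost_mb == 786.27
        assert (t.n_loss, t.n_gain) == (25, 11)

    def test_metastasis_counts(self, fixture_sets):
        t = totals(fixture_sets[3])
        assert (t.n_loss, t.n_gain) == (52, 43)
        assert t.lost_mb == 1902.27


class TestMatchEvents:
    def test_identical_sets_fully_matched(self, fixture_sets):
        m = match_events(fixture_sets[0], fixture_sets[0])
        assert len(m) == len(fixture_sets[0].events)

    def test_small_shift_within_tolerance(self):
        a = SampleEventSet("a", [ev("1", 10.0, 20.0)])
        b = SampleEventSet("b", [ev("1", 10.000001, 20.0)])
        assert match_events(a, b, bp_tol=10_000)
        assert not match_events(a, b, bp_tol=0)

    def test_class_mismatch_never_matches(self):
        a = SampleEventSet("a", [ev("1", 10.0, 20.0, "LOH")])
        b = SampleEventSet("b", [ev("1", 10.0, 20.0, "CG")])
        assert not match_events(a, b, bp_tol=10_000)

    def test_one_to_one_under_duplicates(self):
        a = SampleEventSet("a", [ev("1", 10.0, 20.0), ev("1", 10.0, 20.0)])
        b = SampleEventSet("b", [ev("1", 10.0, 20.0)])
        assert len(match_events(a, b)) == 1

    def test_early_breakpoints_retained_downstream(self, fixture_sets):
        first = fixture_sets[0]
        for later in fixture_sets[1:]:
            m = match_events(first, later)
            assert len(m) == len(first.events)


class TestConcordance:
    def test_primary_vs_first_lesion(self, fixture_sets):
        q = next(s for s in fixture_sets if s.sample == "Primary tumor")
        r = fixture_sets[0]
        assert concordance(q, r) == 72.10

    def test_self_concordance_100(self, fixture_sets):
        for s in fixture_sets:
            assert concordance(s, s) == 100.0

    def test_disjoint_zero_and_empty_none(self):
        a = SampleEventSet("a", [ev("1", 0, 10)])
        b = SampleEventSet("b", [ev("2", 0, 10)])
        assert concordance(a, b) == 0.0
        assert concordance(SampleEventSet("e", []), a) is None

    def test_invariant_to_row_order_and_splitting(self):
        base = [ev("1", 0, 10), ev("2", 5, 25)]
        refset = SampleEventSet("r", [ev("1", 0, 10), ev("2", 5, 25)])
        q1 = SampleEventSet("q", base)
        q2 = SampleEventSet("q", base[::-1])
        assert concordance(q1, refset) == concordance(q2, refset)
        # splitting a reference event into abutting halves preserves totals
        split_ref = SampleEventSet("r", [ev("1", 0, 10), ev("2", 5, 15), ev("2", 15, 25)])
        q_split = SampleEventSet("q", [ev("1", 0, 10), ev("2", 5, 15), ev("2", 15, 25)])
        assert concordance(q_split, split_ref) == 100.0


class TestClassifyProgression:
    def test_nested_fixture_linear(self, fixture_sets):
        rep = classify_progression(fixture_sets)
        assert rep.verdict == "linear-consistent"
        assert rep.earlier_private == []
        last = fixture_sets[-1].sample
        for s in fixture_sets[:-1]:
            assert rep.concordance[s.sample][last] == 100.0

    def test_earlier_private_event_is_parallel_evidence(self, fixture_sets):
        broken = [
            SampleEventSet(s.sample, list(s.events)) for s in fixture_sets
        ]
        rogue = ev("5", 100.0, 120.0, "LOH")
        broken[2].events.append(rogue)  # private to the primary tumor
        rep = classify_progression(broken)
        assert rep.verdict == "parallel-evidence"
        assert any(
            d["stage"] == "Primary tumor" and d["chrom"] == "5" for d in rep.earlier_private
        )

    def test_single_stage_trivially_linear(self, fixture_sets):
        rep = classify_progression(fixture_sets[:1])
        assert rep.verdict == "linear-consistent"

    def test_linear_nesting_implies_monotone_totals(self, fixture_sets):
        rep = classify_progression(fixture_sets)
        assert rep.verdict == "linear-consistent"
        gains = [rep.totals[s].gained_mb for s in rep.stages]
        losses = [rep.totals[s].lost_mb for s in rep.stages]
        assert gains == sorted(gains)
        assert losses == sorted(losses)


class TestStageAcquisition:
    def test_cumulative_losses_match_stage_totals(self, fixture_sets):
        _, cum = stage_acquisition(fixture_sets)
        assert cum[0]["cumulative_lost_mb"] == 786.27
        assert cum[-1]["cumulative_lost_mb"] == 1902.27

    def test_late_only_event_acquired_last(self):
        sets = [
            SampleEventSet("early", []),
            SampleEventSet("late", [ev("1", 0, 10)]),
        ]
        acq, _ = stage_acquisition(sets)
        assert acq[0]["stage"] == "late"

    def test_pipeline_events_acquired_at_truth_stage(self, scenario, event_sets):
        """Inferred acquisition stage equals the truth clone's first stage."""
        acq, _ = stage_acquisition(event_sets, bp_tol=100_000)
        first_stage = {}
        for e in scenario.events:
            for k, s in enumerate(scenario.stage_order):
                if scenario.event_carrier(s, e) > 0:
                    first_stage[(e.chrom, e.start, e.end)] = k
                    break
        hits = 0
        for d in acq:
            for (chrom, start, end), k in first_stage.items():
                if (
                    d["chrom"] == chrom
                    and abs(d["start"] - start) <= 100_000
                    and abs(d["end"] - end) <= 100_000
                ):
                    assert d["stage_index"] == k
                    hits += 1
        assert hits >= len(first_stage) * 0.95
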