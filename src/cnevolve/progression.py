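"""Cross-sample event integration and progression-model classification.

Given per-stage event sets (ordered by progression: e.g. pre-invasive
lesions, primary tumor, metastasis), computes per-sample gained/lost
megabase totals, pairwise Mb-weighted concordance, event retention across
stages, the linear-vs-parallel verdict, and molecular-time acquisition
staging.

The linear progression model predicts perfect nesting: every event of an
earlier stage is retained in every later stage, and no event is private to
an earlier sample.  Any earlier-private event is evidence for parallel
progression (independent evolution after early dissemination).

Mb totals sum event rows as tabulated — one row per event per sample where
present, without merging gain/loss overlaps; subclonal and complete
presence both count as present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .events import CnEvent

__all__ = [
    "SampleEventSet",
    "Totals",
    "ProgressionReport",
    "match_events",
    "totals",
    "concordance",
    "classify_progression",
    "stage_acquisition",
]


@dataclass
class SampleEventSet:
    """All copy-number events of one progression stage."""

    sample: str
    events: list[CnEvent]

    def sorted(self) -> list[CnEvent]:
        return sorted(self.events, key=lambda e: (e.chrom, e.start, e.end, e.category))


@dataclass
class Totals:
    gained_mb: float
    lost_mb: float
    n_gain: int
    n_loss: int


def totals(event_set: SampleEventSet) -> Totals:
    """Per-sample Mb totals and event counts by loss/gain class."""
    gained = sum(e.length_mb for e in event_set.events if e.is_gain)
    lost = sum(e.length_mb for e in event_set.events if e.is_loss)
    return Totals(
        gained_mb=round(gained, 2),
        lost_mb=round(lost, 2),
        n_gain=sum(1 for e in event_set.events if e.is_gain),
        n_loss=sum(1 for e in event_set.events if e.is_loss),
    )


def _cls(e: CnEvent) -> str:
    return "loss" if e.is_loss else "gain"


def match_events(
    set_a: SampleEventSet, set_b: SampleEventSet, bp_tol: int = 0
) -> dict[int, int]:
    """One-to-one correspondence between two event sets.

    Events match when they share the chromosome and class (loss vs gain) and
    both breakpoints agree within ``bp_tol`` base pairs.  Each event on
    either side is used at most once; among admissible partners the one with
    the smallest total breakpoint displacement wins.  Returns a map from
    index in ``set_a.events`` to index in ``set_b.events``.
    """
    used_b: set[int] = set()
    mapping: dict[int, int] = {}
    order = sorted(range(len(set_a.events)),
                   key=lambda i: (set_a.events[i].chrom, set_a.events[i].start))
    for i in order:
        a = set_a.events[i]
        best, best_d = None, None
        for j, b in enumerate(set_b.events):
            if j in used_b or b.chrom != a.chrom or _cls(a) != _cls(b):
                continue
            d1, d2 = abs(a.start - b.start), abs(a.end - b.end)
            if d1 <= bp_tol and d2 <= bp_tol:
                d = d1 + d2
                if best_d is None or d < best_d:
                    best, best_d = j, d
        if best is not None:
            mapping[i] = best
            used_b.add(best)
    return mapping


def concordance(
    query: SampleEventSet, reference: SampleEventSet, bp_tol: int = 0
) -> float | None:
    """Mb-weighted share of ``query`` events present in ``reference`` (percent).

    100 * (sum of length_mb of matched query events) / (total query Mb).
    Returns ``None`` when the query has no events.
    """
    total = sum(e.length_mb for e in query.events)
    if total == 0:
        return None
    matched = match_events(query, reference, bp_tol=bp_tol)
    got = sum(query.events[i].length_mb for i in matched)
    return round(100.0 * got / total, 2)


@dataclass
class ProgressionReport:
    stages: list[str]
    totals: dict[str, Totals]
    concordance: dict[str, dict[str, float | None]]
    verdict: str                      # linear-consistent | parallel-evidence
    earlier_private: list[dict]       # events of an earlier stage unmatched later
    acquisition: list[dict]           # per-event earliest stage
    cumulative: list[dict]            # per-stage cumulative gained/lost Mb

    def to_json(self, path=None) -> str:
        doc = {
            "stages": self.stages,
            "totals": {s: vars(t) for s, t in self.totals.items()},
            "concordance": self.concordance,
            "verdict": self.verdict,
            "earlier_private": self.earlier_private,
            "acquisition": self.acquisition,
            "cumulative": self.cumulative,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [f"Progression verdict: {self.verdict}", ""]
        for s in self.stages:
            t = self.totals[s]
            lines.append(
                f"  {s}: {t.gained_mb:.2f} Mb gained ({t.n_gain} events), "
                f"{t.lost_mb:.2f} Mb lost ({t.n_loss} events)"
            )
        if self.earlier_private:
            lines.append("")
            lines.append("Events private to an earlier stage (parallel evidence):")
            for d in self.earlier_private:
                lines.append(
                    f"  {d['stage']}: {d['chrom']}:{d['start']}-{d['end']} {d['category']}"
                )
        return "\n".join(lines)


def stage_acquisition(
    sets: list[SampleEventSet], bp_tol: int = 0
) -> tuple[list[dict], list[dict]]:
    """Earliest stage per event plus the cumulative Mb-per-stage table.

    Events are deduplicated across stages by matching; each distinct event
    is labeled with the first stage carrying it.  The cumulative table gives,
    per stage, the summed Mb of gains and losses acquired at or before it.
    """
    acquisition: list[dict] = []
    for k, st in enumerate(sets):
        for i, e in enumerate(st.events):
            seen = False
            for earlier in sets[:k]:
                if match_events(SampleEventSet(st.sample, [e]), earlier, bp_tol=bp_tol):
                    seen = True
                    break
            if not seen:
                acquisition.append(
                    dict(stage=st.sample, stage_index=k, chrom=e.chrom, start=e.start,
                         end=e.end, category=e.category, length_mb=e.length_mb,
                         cls=_cls(e))
                )
    cumulative = []
    for k, st in enumerate(sets):
        g = sum(d["length_mb"] for d in acquisition if d["stage_index"] <= k and d["cls"] == "gain")
        l = sum(d["length_mb"] for d in acquisition if d["stage_index"] <= k and d["cls"] == "loss")
        cumulative.append(dict(stage=st.sample, cumulative_gained_mb=round(g, 2),
                               cumulative_lost_mb=round(l, 2)))
    return acquisition, cumulative


def classify_progression(sets: list[SampleEventSet], bp_tol: int = 0) -> ProgressionReport:
    """Full cross-stage report with the linear-vs-parallel verdict.

    Linear-consistent iff every event of every earlier stage is matched in
    every later stage (perfect nesting); otherwise parallel-evidence, with
    the violating earlier-private events listed.
    """
    if not sets:
        raise ValueError("need at least one stage")
    tot = {s.sample: totals(s) for s in sets}
    conc = {
        q.sample: {r.sample: concordance(q, r, bp_tol=bp_tol) for r in sets} for q in sets
    }
    private: list[dict] = []
    for k, earlier in enumerate(sets):
        for later in sets[k + 1:]:
            matched = match_events(earlier, later, bp_tol=bp_tol)
            for i, e in enumerate(earlier.events):
                if i not in matched:
                    private.append(
                        dict(stage=earlier.sample, later_stage=later.sample,
                             chrom=e.chrom, start=e.start, end=e.end,
                             category=e.category, length_mb=e.length_mb)
                    )
    verdict = "linear-consistent" if not private else "parallel-evidence"
    acq, cum = stage_acquisition(sets, bp_tol=bp_tol)
    return ProgressionReport(
        stages=[s.sample for s in sets],
        totals=tot,
        concordance=conc,
        verdict=verdict,
        earlier_private=private,
        acquisition=acq,
        cumulative=cum,
    )
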