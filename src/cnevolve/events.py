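"""Copy-number event calling from segmented log2 + BAF tracks.

Implements the event vocabulary used for multi-stage tumor comparison:
losses (LOH, HL = homozygous loss, OCL = one-copy loss inside previously
amplified territory) and graded gains (CG / HCG / VHCG / EHCG).  Loss
clonality is read jointly from the log2 depth and the allelic imbalance:

* complete heterozygous loss: deep log2, BAF split toward 0/1;
* subclonal heterozygous loss: intermediate log2 and intermediate split;
* homozygous loss in a subclone: log2 at the *complete het-loss* depth but
  BAF still ~ 0.5, because the co-existing subclone retains both alleles —
  the same degeneracy makes expected_log2(0, p, f/2) = expected_log2(1, p, f).

The carried-cell share of a loss (p*f, purity times tumor-cell fraction) is
estimated by inverting the expected minor BAF, with the log2-based inversion
kept as a diagnostic:

    p*f = (1 - 2 m) / (1 - m)          from the minor BAF m
    p*f = 2 - 2^(L + 1)                from the log2 depth L  (c = 1)
    p*f = 1 - 2^L                      for a homozygous loss  (c = 0)

Gains never receive a clonality verdict: a moderate gain in all malignant
cells and a strong amplification in a subclone are indistinguishable in
coverage data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CnEvent",
    "Thresholds",
    "FractionEstimate",
    "classify_segment",
    "call_events",
    "detect_loss_levels",
    "estimate_fraction",
    "resolve_homozygous_subclonal",
    "assign_ocl",
    "LOSS_CATEGORIES",
    "GAIN_CATEGORIES",
]

LOSS_CATEGORIES = ("LOH", "HL", "OCL")
GAIN_CATEGORIES = ("CG", "HCG", "VHCG", "EHCG")


@dataclass
class Thresholds:
    """Tunable classification thresholds (log2 units unless noted).

    Gain grades are binned on the purity-adjusted log2 (the value the
    segment would show at purity 1 if the gain were fully clonal).
    """

    loss_log2: float = -0.1          # segments below this are loss candidates
    gain_log2: float = 0.15          # segments above this are gain candidates
    gain_bins: tuple[float, float, float, float] = (0.15, 0.55, 1.0, 1.8)
    hl_floor: float = -2.5           # purity-1 log2 at/below which HL is certain
    clonal_fraction: float = 0.8     # f >= this => complete
    level_min_separation: float = 0.25
    balanced_fold: float = 0.1       # folded BAF below this counts as balanced
    hl_excess: float = 0.1           # implied p*f above purity by this => HL


@dataclass
class FractionEstimate:
    """BAF-based p*f estimate with the log2-based inversion as diagnostic."""

    baf_based: float | None
    log2_based: float


@dataclass
class CnEvent:
    chrom: str
    start: int
    end: int
    category: str
    clonality: str = "indeterminate"   # complete | subclonal | indeterminate
    est_fraction: float | None = None  # p*f estimate
    loss_level: int | None = None      # 1 (subclonal) | 2 (complete) | None
    mean_log2: float = 0.0
    folded_baf: float | None = None
    n_windows: int = 0
    length_mb: float = field(default=0.0)
    sample: str | None = None

    def __post_init__(self) -> None:
        if not self.length_mb:
            self.length_mb = round((self.end - self.start) / 1e6, 2)

    @property
    def is_loss(self) -> bool:
        return self.category in LOSS_CATEGORIES

    @property
    def is_gain(self) -> bool:
        return self.category in GAIN_CATEGORIES

    def to_dict(self) -> dict:
        return asdict(self)


def estimate_fraction(
    mean_log2: float,
    folded_baf: float | None,
    purity: float = 1.0,
    kind: str = "het_loss",
) -> FractionEstimate:
    """Estimate the carried-cell share p*f of a loss segment.

    For a heterozygous loss the minor BAF ``m = 0.5 - folded_baf`` inverts
    to ``p*f = (1 - 2m)/(1 - m)``; the log2 depth gives ``2 - 2^(L+1)`` as
    an independent diagnostic.  For a homozygous loss only the log2 route
    applies (``1 - 2^L``), since survivors keep balanced alleles.
    """
    if kind == "hom_loss":
        pf_l = float(np.clip(1.0 - 2.0 ** mean_log2, 0.0, 1.0))
        return FractionEstimate(baf_based=None, log2_based=pf_l)
    pf_l = float(np.clip(2.0 - 2.0 ** (mean_log2 + 1.0), 0.0, 1.0))
    if folded_baf is None or not np.isfinite(folded_baf):
        return FractionEstimate(baf_based=None, log2_based=pf_l)
    m = 0.5 - min(float(folded_baf), 0.5)
    pf_b = (1.0 - 2.0 * m) / (1.0 - m)
    return FractionEstimate(baf_based=float(np.clip(pf_b, 0.0, 1.0)), log2_based=pf_l)


def _purity_adjusted_log2(mean_log2: float, purity: float) -> float:
    """Log2 the segment would show at purity 1 for a clonal event."""
    total = 2.0 * 2.0 ** mean_log2
    c = (total - 2.0 * (1.0 - purity)) / max(purity, 1e-9)
    if c <= 0:
        return float("-inf")
    return float(np.log2(c / 2.0))


def classify_segment(
    seg,
    purity: float = 1.0,
    thresholds: Thresholds | None = None,
    sample: str | None = None,
) -> CnEvent | None:
    """Classify one segment into an event, or ``None`` for neutral territory.

    ``seg`` is a row (namedtuple/Series) with chrom, start, end, n_windows,
    mean_log2 and optionally mean_folded_baf.  Losses use the BAF to decide
    clonality; when no BAF is available the category comes from log2 alone
    and the clonality is indeterminate.
    """
    th = thresholds or Thresholds()
    get = seg.get if hasattr(seg, "get") else lambda k, d=None: getattr(seg, k, d)
    L = float(get("mean_log2"))
    fold = get("mean_folded_baf", None)
    fold = float(fold) if fold is not None and np.isfinite(fold) else None
    base = dict(
        chrom=get("chrom"), start=int(get("start")), end=int(get("end")),
        mean_log2=L, folded_baf=fold, n_windows=int(get("n_windows", 0)), sample=sample,
    )

    if L >= th.gain_log2:
        adj = _purity_adjusted_log2(L, purity)
        b = th.gain_bins
        cat = "CG" if adj < b[1] else "HCG" if adj < b[2] else "VHCG" if adj < b[3] else "EHCG"
        return CnEvent(category=cat, clonality="indeterminate", **base)

    if L > th.loss_log2:
        return None

    est = estimate_fraction(L, fold, purity, kind="het_loss")
    pf_log2 = 2.0 - 2.0 ** (L + 1.0)  # unclipped: may exceed 1 for deep losses
    adj = _purity_adjusted_log2(L, purity)
    # deeper than any heterozygous loss can reach at this purity -> HL
    if pf_log2 > purity + th.hl_excess or adj <= th.hl_floor:
        pf = float(np.clip(1.0 - 2.0 ** L, 0.0, 1.0))
        f = pf / max(purity, 1e-9)
        clon = "complete" if f >= th.clonal_fraction else "subclonal"
        return CnEvent(category="HL", clonality=clon, est_fraction=pf, **base)

    pf = est.baf_based if est.baf_based is not None else est.log2_based
    if est.baf_based is None:
        clon = "indeterminate"
    else:
        f = pf / max(purity, 1e-9)
        clon = "complete" if f >= th.clonal_fraction else "subclonal"
    return CnEvent(category="LOH", clonality=clon, est_fraction=float(pf), **base)


def detect_loss_levels(
    events: list[CnEvent], min_separation: float | None = None, thresholds: Thresholds | None = None
) -> list[CnEvent]:
    """Assign level 1 (subclonal) / level 2 (complete) to heterozygous losses.

    Exact two-class 1-D clustering (least within-class sum of squares over
    all split points) of the loss-segment log2 means.  Two levels are
    accepted only when the class centers are at least ``min_separation``
    apart; otherwise every loss is level 2.  Segments already classified HL
    from raw depth are excluded from the clustering and keep ``level=None``.
    """
    th = thresholds or Thresholds()
    sep = th.level_min_separation if min_separation is None else min_separation
    losses = [e for e in events if e.is_loss and e.category != "HL"]
    if not losses:
        return events
    vals = np.array([e.mean_log2 for e in losses])
    order = np.argsort(vals)
    x = vals[order]
    n = len(x)
    two_levels = False
    split = None
    if n >= 2:
        best = np.inf
        for k in range(1, n):
            a, b = x[:k], x[k:]
            ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            if ss < best:
                best = ss
                split = k
        lo, hi = x[:split], x[split:]
        if abs(hi.mean() - lo.mean()) >= sep:
            two_levels = True
    for rank, idx in enumerate(order):
        e = losses[idx]
        if two_levels and rank >= split:
            e.loss_level = 1          # shallower cluster: subclonal
            e.clonality = "subclonal"
        else:
            e.loss_level = 2          # deeper (or only) cluster: complete
            if two_levels:
                e.clonality = "complete"
    return events


def resolve_homozygous_subclonal(
    events: list[CnEvent], thresholds: Thresholds | None = None
) -> list[CnEvent]:
    """Reclassify level-2 losses with balanced BAFs as subclonal HL.

    A loss at the complete-het-loss log2 depth whose folded BAF stays near 0
    cannot be a heterozygous loss (that would split the alleles); it is a
    homozygous loss confined to one subclone while a co-existing subclone
    retains both alleles.  The fraction follows from the c=0 inversion
    ``p*f = 1 - 2^L``.
    """
    th = thresholds or Thresholds()
    for e in events:
        if (
            e.category == "LOH"
            and e.loss_level == 2
            and e.folded_baf is not None
            and np.isfinite(e.folded_baf)
            and e.folded_baf < th.balanced_fold
        ):
            e.category = "HL"
            e.clonality = "subclonal"
            e.est_fraction = float(np.clip(1.0 - 2.0 ** e.mean_log2, 0.0, 1.0))
    return events


def assign_ocl(
    events: list[CnEvent],
    earlier_gains: list[CnEvent],
    min_copy_drop_log2: float = 0.3,
) -> list[CnEvent]:
    """Relabel losses inside previously amplified territory as OCL.

    A loss event whose interval lies within a gain event of an *earlier*
    progression stage is a one-copy loss on an amplified background rather
    than plain LOH.  ``min_copy_drop_log2`` guards against relabeling
    unrelated shallow overlaps.
    """
    for e in events:
        if not e.is_loss or e.category == "HL":
            continue
        for g in earlier_gains:
            if (
                g.is_gain
                and g.chrom == e.chrom
                and e.start >= g.start
                and e.end <= g.end
                and (g.mean_log2 - e.mean_log2) >= min_copy_drop_log2
            ):
                e.category = "OCL"
                break
    return events


def call_events(
    segments: pd.DataFrame,
    purity: float = 1.0,
    thresholds: Thresholds | None = None,
    sample: str | None = None,
) -> list[CnEvent]:
    """Classify all segments and run the loss-level and HL resolution passes."""
    th = thresholds or Thresholds()
    events = []
    for seg in segments.itertuples():
        ev = classify_segment(seg, purity=purity, thresholds=th, sample=sample)
        if ev is not None:
            events.append(ev)
    detect_loss_levels(events, thresholds=th)
    resolve_homozygous_subclonal(events, thresholds=th)
    return events
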