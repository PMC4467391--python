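"""Pseudo-CGH log2 ratio track from paired tumor/normal read counts.

Windows are defined by a fixed number of reads in the matched normal sample
(1000 by default); within each window the tumor reads are counted, the
tumor/normal ratio is log2-transformed, and the whole vector is centered by
subtracting its median.  A diploid window then sits at 0, a clonal single
copy gain (3:2) at ~0.58 and a clonal heterozygous loss (1:2) at -1; normal
cell admixture compresses everything toward the baseline.

Because median centering assumes the median window is diploid, an aneuploid
genome can land the baseline on an altered state; :func:`recenter_baseline`
re-anchors the track on territory whose germline-het SNPs show balanced
allele fractions (BAF ~ 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Log2Track",
    "build_windows",
    "compute_log2",
    "expected_log2",
    "recenter_baseline",
]


def expected_log2(copy_state: int, purity: float = 1.0, fraction: float = 1.0) -> float:
    """Expected centered log2 ratio for a copy state in an admixed sample.

    The sequenced cell population is ``1 - purity`` normal cells (2 copies),
    ``purity * (1 - fraction)`` unaffected tumor cells (2 copies) and
    ``purity * fraction`` event-carrying tumor cells (``copy_state`` copies)::

        log2( (2 (1-p) + p ((1-f) 2 + f c)) / 2 )

    ``c=2`` gives 0 for any admixture; ``c=3, p=f=1`` gives 0.585; ``c=1,
    p=f=1`` gives -1.  A totally deleted state (total copy 0) returns
    ``-inf`` as a sentinel.
    """
    if not 0 <= purity <= 1:
        raise ValueError("purity must be in [0, 1]")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if copy_state < 0:
        raise ValueError("copy_state must be >= 0")
    total = 2 * (1 - purity) + purity * ((1 - fraction) * 2 + fraction * copy_state)
    if total <= 0:
        return float("-inf")
    return float(np.log2(total / 2.0))


@dataclass
class Log2Track:
    """Ordered genome-wide windows with centered log2 ratios.

    ``data`` columns: chrom, start, end, n_normal, n_tumor, log2, plus
    boolean flags ``underfilled`` (short terminal window) and ``floored``
    (zero tumor reads).  ``centering_offset`` is the subtracted median;
    ``baseline_shift`` accumulates any later diploid re-anchoring.
    """

    data: pd.DataFrame
    centering_offset: float = 0.0
    baseline_shift: float = 0.0

    def values(self) -> np.ndarray:
        return self.data["log2"].to_numpy()


def build_windows(
    normal_cov: pd.DataFrame,
    tumor_cov: pd.DataFrame,
    reads_per_window: int = 1000,
) -> pd.DataFrame:
    """Cut the genome into windows holding a fixed normal read count.

    ``normal_cov`` / ``tumor_cov`` are per-position read counts with columns
    (chrom, pos, depth), sorted within each chromosome.  Each window
    accumulates at least ``reads_per_window`` normal reads; the final window
    of a chromosome keeps whatever remains and is flagged ``underfilled``.
    Tumor reads are counted over the same intervals.
    """
    if reads_per_window < 1:
        raise ValueError("reads_per_window must be >= 1")
    for df, name in ((normal_cov, "normal"), (tumor_cov, "tumor")):
        for chrom, sub in df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"{name} coverage not sorted on {chrom}")
    out = []
    tumor_by_chrom = dict(tuple(tumor_cov.groupby("chrom", sort=False)))
    for chrom, sub in normal_cov.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        dep = sub["depth"].to_numpy()
        cum = np.cumsum(dep)
        edges_idx = []
        target = reads_per_window
        for i, c in enumerate(cum):
            if c >= target:
                edges_idx.append(i)
                target = c + reads_per_window
        # window boundaries in bp: [start of chrom/prev boundary, pos+1)
        starts = [int(pos[0])]
        ends = []
        for i in edges_idx:
            ends.append(int(pos[i]) + 1)
            starts.append(int(pos[i]) + 1)
        underfilled = []
        if edges_idx and edges_idx[-1] == len(pos) - 1:
            starts.pop()  # no trailing remainder
            underfilled = [False] * len(ends)
        else:
            ends.append(int(pos[-1]) + 1)
            underfilled = [False] * (len(ends) - 1) + [True]
        tsub = tumor_by_chrom.get(chrom)
        tpos = tsub["pos"].to_numpy() if tsub is not None else np.empty(0, dtype=int)
        tdep = tsub["depth"].to_numpy() if tsub is not None else np.empty(0)
        tcum = np.concatenate([[0], np.cumsum(tdep)])
        ncum = np.concatenate([[0], cum])
        for s, e, uf in zip(starts, ends, underfilled):
            n_n = ncum[np.searchsorted(pos, e, "left")] - ncum[np.searchsorted(pos, s, "left")]
            n_t = tcum[np.searchsorted(tpos, e, "left")] - tcum[np.searchsorted(tpos, s, "left")]
            out.append(dict(chrom=chrom, start=s, end=e, n_normal=int(n_n),
                            n_tumor=int(n_t), underfilled=uf))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_normal", "n_tumor", "underfilled"])


def compute_log2(windows: pd.DataFrame, floor: float = -5.0) -> Log2Track:
    """Log2-transform tumor/normal window ratios and center on the median.

    Windows with no normal reads are dropped with a warning; windows with no
    tumor reads get the ``floor`` value and a ``floored`` flag.  Underfilled
    windows (if flagged by :func:`build_windows`) are kept but excluded from
    the median.
    """
    df = windows.copy()
    if "underfilled" not in df.columns:
        df["underfilled"] = False
    bad = df["n_normal"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} windows with zero normal reads")
        df = df[~bad].reset_index(drop=True)
    ratio = df["n_tumor"].to_numpy(dtype=float) / df["n_normal"].to_numpy(dtype=float)
    floored = ratio <= 0
    raw = np.where(floored, floor, np.log2(np.where(floored, 1.0, ratio)))
    usable = ~(df["underfilled"].to_numpy() | floored)
    med = float(np.median(raw[usable])) if usable.any() else 0.0
    df["log2"] = raw - med
    df["floored"] = floored
    return Log2Track(data=df, centering_offset=med, baseline_shift=0.0)


def recenter_baseline(
    track: Log2Track,
    baf_sites: pd.DataFrame,
    eps: float = 0.03,
    min_span: int = 50,
    min_sites: int = 10,
    level_tol: float = 0.1,
    min_probes: int = 10,
) -> Log2Track:
    """Anchor the log2 baseline on territory with balanced allele fractions.

    Median centering mis-calibrates when altered territory dominates the
    genome.  This pass segments the track, keeps segments of at least
    ``min_span`` windows whose germline-het SNPs show a depth-debiased
    allelic imbalance below ``eps``, groups the qualifying segments by mean
    log2 (``level_tol``), and subtracts the window-weighted mean of the
    heaviest group — the most abundant balanced state, taken to be diploid.
    A long homozygous loss also shows BAF ~ 0.5 (only the admixed normal
    cells retain alleles) but carries far less genomic mass than true
    diploid territory, so mass weighting keeps the anchor off it.

    ``baf_sites`` needs columns (chrom, pos, baf, depth) — the informative
    germline-het sites of the *tumor* sample.  Returns a new track; if no
    span qualifies the track is returned unchanged with a warning.
    """
    from .baf import folded_imbalance
    from .segment import segment_track

    segs = segment_track(track.data, min_probes=min_probes)
    cands = []
    for seg in segs.itertuples():
        if seg.n_windows < min_span:
            continue
        sub = baf_sites[
            (baf_sites["chrom"] == seg.chrom)
            & (baf_sites["pos"] >= seg.start)
            & (baf_sites["pos"] < seg.end)
        ]
        if len(sub) < min_sites:
            continue
        fold = folded_imbalance(sub["baf"].to_numpy(), sub["depth"].to_numpy())
        if fold < eps:
            cands.append((seg.mean_log2, seg.n_windows))
    if not cands:
        warnings.warn("no balanced-BAF span found; baseline left unchanged")
        return track
    cands.sort()
    groups: list[list[tuple[float, int]]] = []
    for mean, n in cands:
        if groups and abs(mean - groups[-1][-1][0]) <= level_tol:
            groups[-1].append((mean, n))
        else:
            groups.append([(mean, n)])
    best = max(groups, key=lambda g: sum(n for _, n in g))
    shift = float(np.average([m for m, _ in best], weights=[n for _, n in best]))
    data = track.data.copy()
    data["log2"] = data["log2"] - shift
    return Log2Track(
        data=data,
        centering_offset=track.centering_offset,
        baseline_shift=track.baseline_shift + shift,
    )
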