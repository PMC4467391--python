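"""Changepoint segmentation of log2 (and folded-BAF) tracks.

Uses exact penalized changepoint detection with a Gaussian-mean cost (the
PELT recursion with pruning) and a hard minimum segment length, defaulting
to the 10-probe minimum used for copy-number calls.  Deterministic for a
fixed input and penalty; invariant to adding a constant to the track.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["pelt_changepoints", "segment_track", "merge_adjacent", "joint_breakpoints"]


def _noise_sd(x: np.ndarray) -> float:
    """Robust noise scale from first differences (MAD-based)."""
    d = np.diff(x)
    if len(d) == 0:
        return 1.0
    mad = np.median(np.abs(d - np.median(d)))
    sd = mad / 0.6745 / np.sqrt(2)
    return float(sd) if sd > 0 else float(np.std(d) / np.sqrt(2)) or 1.0


def pelt_changepoints(
    x: np.ndarray, penalty: float | None = None, min_size: int = 10
) -> list[int]:
    """Exact penalized least-squares changepoints of a 1-D signal.

    Minimizes  sum_segments SS(segment) + penalty * (#changepoints) with
    segment sum-of-squares cost, subject to every segment spanning at least
    ``min_size`` points.  The default penalty is ``3 sigma^2 log n`` with a
    robust noise estimate — a BIC-flavored choice.  Returns interior
    breakpoint indices (a breakpoint at ``i`` splits ``x[:i] | x[i:]``).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_size:
        return []
    if penalty is None:
        sd = _noise_sd(x)
        penalty = 3.0 * sd * sd * np.log(n)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: np.ndarray, j: int) -> np.ndarray:
        m = j - i
        return (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / m

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    cands = np.array([0], dtype=int)
    for j in range(min_size, n + 1):
        valid = cands[cands <= j - min_size]
        if len(valid) == 0:
            continue
        tot = F[valid] + cost(valid, j) + penalty
        k = int(np.argmin(tot))
        F[j] = tot[k]
        last[j] = valid[k]
        # PELT pruning: candidates that can never win again
        keep = F[valid] + cost(valid, j) <= F[j]
        pruned = valid[keep]
        cands = np.concatenate([pruned, [j - min_size + 1]]) if j - min_size + 1 <= n else pruned
        cands = np.unique(cands[cands >= 0])
    bps = []
    j = n
    while j > 0:
        i = last[j]
        if i > 0:
            bps.append(int(i))
        j = i
    return sorted(bps)


def segment_track(
    track: pd.DataFrame,
    value_col: str = "log2",
    min_probes: int = 10,
    penalty: float | None = None,
) -> pd.DataFrame:
    """Partition each chromosome of a window track into constant segments.

    ``track`` is a window table (chrom, start, end, <value_col>).  A
    chromosome with fewer than ``2 * min_probes`` windows is returned as a
    single segment.  Output columns: chrom, start, end, n_windows,
    mean_log2, i0, i1 (window index range into the chromosome-sorted track).
    """
    rows = []
    offset = 0
    for chrom, sub in track.groupby("chrom", sort=False):
        x = sub[value_col].to_numpy(dtype=float)
        n = len(x)
        bps = pelt_changepoints(x, penalty=penalty, min_size=min_probes) if n >= 2 * min_probes else []
        edges = [0] + bps + [n]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i0, i1 in zip(edges[:-1], edges[1:]):
            rows.append(
                dict(
                    chrom=chrom,
                    start=int(starts[i0]),
                    end=int(ends[i1 - 1]),
                    n_windows=i1 - i0,
                    mean_log2=float(np.mean(x[i0:i1])),
                    i0=offset + i0,
                    i1=offset + i1,
                )
            )
        offset += n
    return pd.DataFrame(rows)


def merge_adjacent(
    segments: pd.DataFrame, tol: float = 0.1, baf_tol: float = 0.1
) -> pd.DataFrame:
    """Merge abutting segments with near-equal means (idempotent).

    Two segments merge when they abut on the same chromosome, their
    ``mean_log2`` differ by less than ``tol`` and their folded-BAF states
    agree (absent values always agree; present values within ``baf_tol``).
    Means are re-averaged with window weights.
    """
    if segments.empty:
        return segments.copy()
    has_baf = "mean_folded_baf" in segments.columns
    out = []
    for _, seg in segments.iterrows():
        seg = seg.copy()
        if out:
            prev = out[-1]
            abut = prev["chrom"] == seg["chrom"] and prev["i1"] == seg["i0"]
            close = abs(prev["mean_log2"] - seg["mean_log2"]) < tol
            baf_ok = True
            if has_baf:
                a, b = prev.get("mean_folded_baf"), seg.get("mean_folded_baf")
                if pd.notna(a) and pd.notna(b):
                    baf_ok = abs(a - b) < baf_tol
            if abut and close and baf_ok:
                w1, w2 = prev["n_windows"], seg["n_windows"]
                prev["mean_log2"] = (prev["mean_log2"] * w1 + seg["mean_log2"] * w2) / (w1 + w2)
                if has_baf and pd.notna(prev.get("mean_folded_baf")) and pd.notna(seg.get("mean_folded_baf")):
                    prev["mean_folded_baf"] = (
                        prev["mean_folded_baf"] * prev.get("n_sites", w1)
                        + seg["mean_folded_baf"] * seg.get("n_sites", w2)
                    ) / (prev.get("n_sites", w1) + seg.get("n_sites", w2))
                if has_baf:
                    prev["n_sites"] = prev.get("n_sites", 0) + seg.get("n_sites", 0)
                prev["end"] = seg["end"]
                prev["n_windows"] = w1 + w2
                prev["i1"] = seg["i1"]
                continue
        out.append(seg)
    return pd.DataFrame(out).reset_index(drop=True)


def joint_breakpoints(
    track: pd.DataFrame,
    baf_window_col: str | None = None,
    min_probes: int = 10,
    penalty: float | None = None,
) -> pd.DataFrame:
    """Segment on the union of log2 and folded-BAF breakpoints.

    When the track carries a per-window folded-BAF column, both signals are
    segmented and their breakpoints pooled (dropping any that would leave a
    fragment shorter than ``min_probes``); segment means are then taken from
    the log2 signal.  Without a BAF column this is :func:`segment_track`.
    """
    if baf_window_col is None or baf_window_col not in track.columns:
        return segment_track(track, min_probes=min_probes, penalty=penalty)
    rows = []
    offset = 0
    for chrom, sub in track.groupby("chrom", sort=False):
        x = sub["log2"].to_numpy(dtype=float)
        y = sub[baf_window_col].to_numpy(dtype=float)
        n = len(x)
        bps = set(pelt_changepoints(x, penalty=penalty, min_size=min_probes)) if n >= 2 * min_probes else set()
        if n >= 2 * min_probes and np.isfinite(y).all():
            bps |= set(pelt_changepoints(y, penalty=penalty, min_size=min_probes))
        edges = [0]
        for b in sorted(bps):
            if b - edges[-1] >= min_probes and n - b >= min_probes:
                edges.append(b)
        edges.append(n)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i0, i1 in zip(edges[:-1], edges[1:]):
            rows.append(
                dict(chrom=chrom, start=int(starts[i0]), end=int(ends[i1 - 1]),
                     n_windows=i1 - i0, mean_log2=float(np.mean(x[i0:i1])),
                     i0=offset + i0, i1=offset + i1)
            )
        offset += n
    return pd.DataFrame(rows)
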