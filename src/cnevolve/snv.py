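"""Somatic point-mutation filtering and clonality tracking across samples.

The somatic filter applies the documented discovery thresholds: the matched
normal must be covered at >= 10 reads and homozygous reference (BAF <
0.02); a variant is retained when at least one tumor sample shows >= 3
alternative reads at BAF > 0.15; it is then marked present in every sample
with BAF > 0.05.  Known population SNPs above 1% allele frequency are
excluded.

Here a variant's BAF is simply alt / depth in the tumor sample — for a
heterozygous mutation in a copy-neutral region it estimates half the
carried-cell fraction, so clonality can be compared across samples:
a variant subclonal early (BAF ~ 0.10-0.15) that becomes fully clonal late
(BAF ~ 0.40-0.48) has been *purified* — the late lesion descends from the
subclone that carried it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = [
    "FilterThresholds",
    "tumor_samples",
    "filter_somatic",
    "presence_matrix",
    "detect_purification",
    "vaf_density",
]


@dataclass
class FilterThresholds:
    """Somatic-call thresholds (documented defaults)."""

    min_normal_depth: int = 10
    max_normal_baf: float = 0.02
    min_alt: int = 3
    min_baf: float = 0.15
    presence_baf: float = 0.05
    max_pop_af: float = 0.01


def tumor_samples(calls: pd.DataFrame) -> list[str]:
    """Tumor sample names from depth_<s> columns (excluding the normal)."""
    return [
        c[len("depth_"):]
        for c in calls.columns
        if c.startswith("depth_") and c != "depth_normal"
    ]


def _baf(calls: pd.DataFrame, sample: str) -> pd.Series:
    d = calls[f"depth_{sample}"].astype(float)
    a = calls[f"alt_{sample}"].astype(float)
    return (a / d.where(d > 0)).fillna(0.0)


def filter_somatic(
    calls: pd.DataFrame,
    samples: list[str] | None = None,
    thresholds: FilterThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the somatic discovery filter; returns (retained, rejected).

    Retained rows carry ``baf_<s>`` and boolean ``present_<s>`` columns per
    tumor sample; rejected rows carry a ``reject_reason`` code.  The filter
    is row-wise, hence independent of input order.
    """
    th = thresholds or FilterThresholds()
    df = calls.copy()
    samples = samples or tumor_samples(df)
    if "depth_normal" not in df.columns:
        raise ValueError("calls need matched-normal depth_normal/alt_normal columns")
    nd = df["depth_normal"].astype(float)
    nb = (df["alt_normal"].astype(float) / nd.where(nd > 0)).fillna(1.0)
    df["baf_normal"] = nb

    reasons = pd.Series("", index=df.index)
    ok_nd = nd >= th.min_normal_depth
    reasons[~ok_nd] = "normal_depth"
    ok_nb = nb < th.max_normal_baf
    reasons[ok_nd & ~ok_nb] = "normal_not_homref"
    af = df["known_snp_af"] if "known_snp_af" in df.columns else pd.Series(np.nan, index=df.index)
    ok_af = af.isna() | (af <= th.max_pop_af)
    reasons[ok_nd & ok_nb & ~ok_af] = "common_snp"

    any_discovery = pd.Series(False, index=df.index)
    for s in samples:
        baf = _baf(df, s)
        df[f"baf_{s}"] = baf
        any_discovery |= (df[f"alt_{s}"] >= th.min_alt) & (baf > th.min_baf)
    reasons[ok_nd & ok_nb & ok_af & ~any_discovery] = "below_discovery"

    keep = ok_nd & ok_nb & ok_af & any_discovery
    for s in samples:
        df[f"present_{s}"] = keep & (df[f"baf_{s}"] > th.presence_baf)
    retained = df[keep].reset_index(drop=True)
    rejected = df[~keep].copy()
    rejected["reject_reason"] = reasons[~keep]
    return retained, rejected.reset_index(drop=True)


def presence_matrix(
    calls: pd.DataFrame, samples: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-variant presence matrix and membership-pattern counts.

    Patterns are keyed by '&'-joined sample names ('dcis1&primary&...'); an
    all-absent variant counts under ''.  Single-sample patterns are the
    private variants of that sample.
    """
    samples = samples or tumor_samples(calls)
    mat = pd.DataFrame(
        {s: calls[f"present_{s}"].astype(bool) for s in samples}, index=calls.index
    )
    counts: dict[str, int] = {}
    for _, row in mat.iterrows():
        key = "&".join([s for s in samples if row[s]])
        counts[key] = counts.get(key, 0) + 1
    return mat, counts


def detect_purification(
    calls: pd.DataFrame,
    early_sample: str,
    late_sample: str,
    subclonal_band: tuple[float, float] = (0.05, 0.25),
    clonal_band: tuple[float, float] = (0.35, 0.55),
) -> pd.Series:
    """Flag variants subclonal early and fully clonal late.

    A flagged variant is present in both samples, with the early BAF inside
    ``subclonal_band`` and the late BAF inside ``clonal_band`` — the
    signature of the late lesion descending from the early subclone.
    """
    be, bl = calls[f"baf_{early_sample}"], calls[f"baf_{late_sample}"]
    both = calls[f"present_{early_sample}"] & calls[f"present_{late_sample}"]
    return (
        both
        & be.between(subclonal_band[0], subclonal_band[1])
        & bl.between(clonal_band[0], clonal_band[1])
    )


def vaf_density(
    calls: pd.DataFrame,
    sample: str,
    exclude_events=None,
    min_variants: int = 5,
    grid: int = 256,
    prominence_frac: float = 0.10,
) -> dict:
    """Mutation-frequency density for one sample, away from copy events.

    Variants overlapping any supplied copy-number event are excluded (their
    BAF mixes copy state with clonality).  Returns the kernel density (on a
    Silverman bandwidth), the detected mode positions (peak prominence >=
    ``prominence_frac`` of the maximum) and ``n_modes`` — 1 is consistent
    with a monoclonal sample, 2 with two coexisting subclones.  With fewer
    than ``min_variants`` usable variants the mode count is None.
    """
    df = calls[calls[f"present_{sample}"]] if f"present_{sample}" in calls.columns else calls
    if exclude_events:
        keep = []
        for _, row in df.iterrows():
            hit = any(
                e.chrom == row["chrom"] and e.start <= row["pos"] < e.end
                for e in exclude_events
            )
            keep.append(not hit)
        df = df[np.array(keep, dtype=bool)] if len(df) else df
    vals = df[f"baf_{sample}"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    out: dict = {"n_variants": int(len(vals))}
    if len(vals) < min_variants or np.ptp(vals) == 0:
        out.update(n_modes=None, modes=[], x=[], density=[])
        return out
    kde = gaussian_kde(vals, bw_method="silverman")
    x = np.linspace(0.0, max(1.0, vals.max() + 0.1), grid)
    dens = kde(x)
    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    out.update(
        n_modes=int(len(peaks)),
        modes=[float(x[p]) for p in peaks],
        x=x.tolist(),
        density=dens.tolist(),
    )
    return out
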