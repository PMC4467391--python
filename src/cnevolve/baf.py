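"""B-allele frequencies at germline heterozygous known-SNP sites.

BAF = B-allele depth / (A + B depth).  At an unaltered germline-het site the
tumor BAF is 0.5; a complete heterozygous loss splits the BAFs to 0 and 1,
and admixture or subclonality pulls the split inward.  Because the A/B
orientation follows the germline genotype, imbalance magnitude is measured
with the folded BAF |baf - 0.5|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_baf",
    "select_informative_sites",
    "expected_baf",
    "folded_imbalance",
    "baf_track",
    "segment_folded_baf",
]


def compute_baf(a_depth, b_depth):
    """BAF = b / (a + b); NaN where the site has no coverage."""
    a = np.asarray(a_depth, dtype=float)
    b = np.asarray(b_depth, dtype=float)
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, b / np.where(tot > 0, tot, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def select_informative_sites(
    sites: pd.DataFrame,
    min_depth: int = 30,
    het_band: tuple[float, float] = (0.25, 0.75),
) -> pd.DataFrame:
    """Keep known-SNP germline-het sites covered >= ``min_depth`` in both samples.

    Expects columns a_depth_t/b_depth_t/a_depth_n/b_depth_n plus the
    ``known_snp`` flag.  Germline heterozygosity is taken from the
    ``germline_het`` column when present, otherwise called from the normal
    BAF falling inside ``het_band``.  Returns the retained sites with
    ``baf_t``, ``baf_n`` and ``depth_t`` columns added.
    """
    df = sites.copy()
    dt = df["a_depth_t"] + df["b_depth_t"]
    dn = df["a_depth_n"] + df["b_depth_n"]
    df["baf_n"] = compute_baf(df["a_depth_n"], df["b_depth_n"])
    df["baf_t"] = compute_baf(df["a_depth_t"], df["b_depth_t"])
    df["depth_t"] = dt
    if "germline_het" in df.columns:
        het = df["germline_het"].astype(bool)
    else:
        het = (df["baf_n"] >= het_band[0]) & (df["baf_n"] <= het_band[1])
    known = df["known_snp"].astype(bool) if "known_snp" in df.columns else True
    keep = known & het & (dt >= min_depth) & (dn >= min_depth)
    return df[keep].reset_index(drop=True)


def expected_baf(purity: float, fraction: float, kind: str = "het_loss") -> tuple[float, float]:
    """Expected (minor, major) BAF under a copy event in fraction ``f`` of tumor cells.

    For a heterozygous loss hitting fraction ``f`` of tumor cells at purity
    ``p``, the affected haplotype keeps ``1 - p f`` of its copies against a
    total of ``2 - p f``::

        minor = (1 - p f) / (2 - p f),  major = 1 - minor

    ``p = f = 1`` gives the complete (0, 1) split.  Balanced states
    (no event, balanced gain) return (0.5, 0.5).
    """
    if not 0 <= purity <= 1 or not 0 <= fraction <= 1:
        raise ValueError("purity and fraction must be in [0, 1]")
    if kind in ("none", "balanced_gain") or fraction == 0:
        return 0.5, 0.5
    if kind == "het_loss":
        pf = purity * fraction
        minor = (1 - pf) / (2 - pf)
        return minor, 1 - minor
    if kind == "hom_loss":
        # both alleles lost in carriers; survivors are balanced
        return 0.5, 0.5
    raise ValueError(f"unknown event kind {kind!r}")


def folded_imbalance(bafs: np.ndarray, depths: np.ndarray) -> float:
    """Depth-debiased allelic-imbalance magnitude of a set of het sites.

    The naive mean |baf - 0.5| overstates imbalance at finite depth: pure
    binomial noise folds to a positive value (~0.4 / sqrt(depth)).  Using
    E[(baf - 0.5)^2] = fold^2 + q(1-q)/depth, the per-site statistic

        s_i = (baf_i - 0.5)^2 - baf_i (1 - baf_i) / (depth_i - 1)

    has expectation fold^2; the estimator is sqrt(max(0, mean s_i)).
    """
    b = np.asarray(bafs, dtype=float)
    d = np.asarray(depths, dtype=float)
    ok = np.isfinite(b) & (d > 1)
    if not ok.any():
        return float("nan")
    b, d = b[ok], d[ok]
    s = (b - 0.5) ** 2 - b * (1 - b) / (d - 1)
    return float(np.sqrt(max(0.0, float(np.mean(s)))))


def baf_track(sites: pd.DataFrame, min_depth: int = 30) -> pd.DataFrame:
    """Informative-site BAF track: chrom, pos, baf, folded_baf, depth."""
    keep = select_informative_sites(sites, min_depth=min_depth)
    out = keep[["chrom", "pos"]].copy()
    out["baf"] = keep["baf_t"]
    out["folded_baf"] = (keep["baf_t"] - 0.5).abs()
    out["depth"] = keep["depth_t"]
    return out


def segment_folded_baf(segments: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Attach per-segment debiased folded BAF and site counts to segments.

    ``sites`` is a :func:`baf_track` table.  Adds ``mean_folded_baf`` (NaN
    when fewer than 3 sites fall in the segment) and ``n_sites``.
    """
    segs = segments.copy()
    folds = np.full(len(segs), np.nan)
    counts = np.zeros(len(segs), dtype=int)
    by_chrom = dict(tuple(sites.groupby("chrom", sort=False)))
    for i, seg in enumerate(segs.itertuples()):
        sub = by_chrom.get(seg.chrom)
        if sub is None:
            continue
        inside = sub[(sub["pos"] >= seg.start) & (sub["pos"] < seg.end)]
        counts[i] = len(inside)
        if len(inside) >= 3:
            folds[i] = folded_imbalance(inside["baf"].to_numpy(), inside["depth"].to_numpy())
    segs["mean_folded_baf"] = folds
    segs["n_sites"] = counts
    return segs
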