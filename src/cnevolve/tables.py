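"""Readers/writers for the pipeline's tabular contracts.

The central format is the multi-sample copy-number event table: one row per
event with Mb coordinates to two decimals (Chr, Start, End, Length,
Cytobands, Type) followed by one presence column per sample — a bare sample
column, or a ``<sample> complete`` / ``<sample> subclone`` pair whose marks
are merged into a single presence flag per sample.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .events import CnEvent, LOSS_CATEGORIES, GAIN_CATEGORIES
from .progression import SampleEventSet

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_window_counts",
    "write_window_counts",
    "read_snp_table",
    "write_snp_table",
    "read_variant_table",
    "read_vcf_variants",
]

VALID_CATEGORIES = set(LOSS_CATEGORIES) | set(GAIN_CATEGORIES)
META_COLS = {"chrom", "start_mb", "end_mb", "length_mb", "cytobands", "type", "n_genes"}


def _presence_samples(columns) -> dict[str, list[str]]:
    """Group presence columns by sample, merging complete/subclone pairs."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        if col in META_COLS:
            continue
        name = col
        for suffix in (" complete", " subclone"):
            if col.endswith(suffix):
                name = col[: -len(suffix)]
                break
        groups.setdefault(name, []).append(col)
    return groups


def read_event_table(path, length_warn_mb: float = 0.011) -> list[SampleEventSet]:
    """Parse a multi-sample event TSV into per-sample event sets.

    Coordinates are Mb (two decimals); lengths are validated against
    End - Start and mismatches above ``length_warn_mb`` draw a warning.
    Unknown category tokens and reversed intervals raise with the row
    number.  Clonality per sample is 'complete' / 'subclonal' when the
    layout distinguishes them, else 'indeterminate'.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    groups = _presence_samples(df.columns)
    sets: dict[str, list[CnEvent]] = {s: [] for s in groups}
    for idx, row in df.iterrows():
        cat = str(row["type"]).strip()
        if cat not in VALID_CATEGORIES:
            raise ValueError(f"row {idx + 1}: unknown event category {cat!r}")
        s_mb, e_mb = float(row["start_mb"]), float(row["end_mb"])
        if e_mb <= s_mb:
            raise ValueError(f"row {idx + 1}: end {e_mb} <= start {s_mb}")
        length = float(row["length_mb"])
        if abs(length - (e_mb - s_mb)) > length_warn_mb:
            warnings.warn(
                f"row {idx + 1}: length {length} differs from end-start "
                f"{e_mb - s_mb:.2f} by more than {length_warn_mb} Mb"
            )
        for sample, cols in groups.items():
            marks = [str(row[c]).strip().lower() for c in cols if pd.notna(row[c])]
            present = any(m.startswith("x") for m in marks)
            if not present:
                continue
            clonality = "indeterminate"
            if len(cols) > 1:
                comp = [c for c in cols if c.endswith(" complete")]
                if comp and pd.notna(row[comp[0]]) and str(row[comp[0]]).strip():
                    clonality = "complete"
                else:
                    clonality = "subclonal"
            sets[sample].append(
                CnEvent(
                    chrom=str(row["chrom"]),
                    start=int(round(s_mb * 1e6)),
                    end=int(round(e_mb * 1e6)),
                    category=cat,
                    clonality=clonality,
                    length_mb=length,
                    sample=sample,
                )
            )
    return [SampleEventSet(sample, events) for sample, events in sets.items()]


def write_event_table(sets: list[SampleEventSet], path) -> None:
    """Write per-sample event sets back to the multi-sample TSV layout."""
    keys: list[tuple] = []
    rows: dict[tuple, dict] = {}
    for st in sets:
        for e in st.events:
            key = (e.chrom, e.start, e.end, e.category)
            if key not in rows:
                keys.append(key)
                rows[key] = dict(
                    chrom=e.chrom,
                    start_mb=round(e.start / 1e6, 2),
                    end_mb=round(e.end / 1e6, 2),
                    length_mb=e.length_mb,
                    cytobands="",
                    type=e.category,
                )
            rows[key][st.sample] = "x"
    df = pd.DataFrame([rows[k] for k in keys])
    for st in sets:
        if st.sample not in df.columns:
            df[st.sample] = ""
    df.to_csv(path, sep="\t", index=False)


def write_window_counts(windows: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "n_normal", "n_tumor"]
    extra = [c for c in ("log2", "underfilled", "floored") if c in windows.columns]
    windows[cols + extra].to_csv(path, sep="\t", index=False)


def read_window_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "start", "end", "n_normal", "n_tumor"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_snp_table(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "a_depth_t", "b_depth_t", "a_depth_n", "b_depth_n"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_variant_table(path) -> pd.DataFrame:
    """Multi-sample somatic variant TSV with depth_<s>/alt_<s> columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "depth_normal" not in df.columns:
        raise ValueError(f"{path}: variant table needs a depth_normal column")
    return df


def read_vcf_variants(path, normal_sample: str, tumor_samples: list[str]) -> pd.DataFrame:
    """Adapter: load a VCF with per-sample AD fields into the variant layout.

    Requires cyvcf2.  ``AD`` is read per sample (ref, alt depth ordering);
    population allele frequency is taken from an ``AF``-style INFO field
    when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    idx = {s: samples.index(s) for s in [normal_sample, *tumor_samples]}
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ad = var.format("AD")
        if ad is None:
            continue
        row: dict[str, object] = dict(
            chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=var.ALT[0],
            annotation=var.INFO.get("ANN", "other"),
            known_snp_af=var.INFO.get("AF", float("nan")),
        )
        ref_n, alt_n = int(ad[idx[normal_sample]][0]), int(ad[idx[normal_sample]][1])
        row["depth_normal"] = ref_n + alt_n
        row["alt_normal"] = alt_n
        for s in tumor_samples:
            r, a = int(ad[idx[s]][0]), int(ad[idx[s]][1])
            row[f"depth_{s}"] = r + a
            row[f"alt_{s}"] = a
        rows.append(row)
    return pd.DataFrame(rows)
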