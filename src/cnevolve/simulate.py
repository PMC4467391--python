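"""Synthetic tumor-evolution data generator.

Generates everything the downstream pipeline consumes — paired tumor/normal
window read counts, germline-het SNP allele depths, and somatic variant
tables — from an explicit clone tree over a miniature genome, so every stage
is testable without patient sequencing data.

Model
-----
A sample is a mixture of normal cells and tumor clones.  Clone fractions are
disjoint population shares of *all* cells in the sample; their sum is the
tumor purity ``p``.  A clone inherits every copy-number event and SNV of its
ancestors.  The *carrier fraction* of a clone is the share of cells carrying
its events (the clone plus all descendants).

For a window the expected total copy number is

    E[copy] = 2 (1 - p) + sum_clones f_c * (c_A + c_B)

with per-haplotype copies ``c_A, c_B`` accumulated along each clone's
lineage.  Normal window counts are Poisson around the target depth; tumor
counts are Poisson around ``depth * E[copy] / 2``.  SNP B-allele depths are
binomial around the copy-weighted B-allele share, and somatic-SNV alt depths
are binomial around ``VAF = F/2`` for a variant whose carrier fraction of
all cells is ``F`` (copy-neutral placement).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CloneTree",
    "EventSpec",
    "SnvSpec",
    "Scenario",
    "SimulatedSample",
    "MINI_GENOME",
    "simulate_counts",
    "simulate_snp_counts",
    "simulate_snvs",
    "simulate_filter_candidates",
    "four_stage_scenario",
    "single_event_scenario",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

#: Miniature genome used by default: 5 chromosomes x 40 Mb.
MINI_GENOME: dict[str, int] = {f"chr{i}": 40_000_000 for i in range(1, 6)}

LOSS_KINDS = ("het_loss", "hom_loss")
GAIN_KIND = "gain"


class ConflictError(ValueError):
    """Overlapping events on the same haplotype within one clone lineage."""


@dataclass
class EventSpec:
    """A copy-number event first acquired by one clone.

    ``copies`` is the *total* copy target of the event: 1 for a heterozygous
    loss, 0 for a homozygous loss, >= 3 for a gain.  ``allele`` names the
    parental haplotype (0 or 1) the event hits; homozygous losses hit both.
    Coordinates are 0-based half-open base pairs.
    """

    chrom: str
    start: int
    end: int
    kind: str
    clone: str
    copies: int | None = None
    allele: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"event {self}: start must be < end")
        if self.kind == "het_loss":
            self.copies = 1
        elif self.kind == "hom_loss":
            self.copies = 0
        elif self.kind == GAIN_KIND:
            if self.copies is None or self.copies < 3:
                raise ValueError(f"event {self}: gain requires copies >= 3")
        else:
            raise ValueError(f"event {self}: unknown kind {self.kind!r}")
        if self.allele not in (0, 1):
            raise ValueError(f"event {self}: allele must be 0 or 1")

    @property
    def is_loss(self) -> bool:
        return self.kind in LOSS_KINDS

    def haplotype_copies(self) -> tuple[int, int]:
        """Copies of (affected allele, other allele) after the event."""
        if self.kind == "het_loss":
            return 0, 1
        if self.kind == "hom_loss":
            return 0, 0
        return self.copies - 1, 1  # gain: extra copies on one haplotype


@dataclass
class SnvSpec:
    """A somatic point mutation acquired by one clone (copy-neutral site)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    clone: str


@dataclass
class CloneTree:
    """Clone phylogeny with per-sample population fractions.

    ``parent`` maps each clone to its parent clone (``None`` = germline
    root).  ``fractions[sample][clone]`` is the clone's share of all cells in
    the sample; shares are disjoint, non-negative, and sum to the sample's
    tumor purity (<= 1, remainder = admixed normal cells).
    """

    parent: dict[str, str | None]
    fractions: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def clones(self) -> list[str]:
        return list(self.parent)

    @property
    def samples(self) -> list[str]:
        return list(self.fractions)

    def purity(self, sample: str) -> float:
        return float(sum(self.fractions[sample].values()))

    def lineage(self, clone: str) -> list[str]:
        """Clones from the root down to (and including) ``clone``."""
        path = []
        cur: str | None = clone
        while cur is not None:
            path.append(cur)
            cur = self.parent[cur]
        return path[::-1]

    def descendants(self, clone: str) -> set[str]:
        out = {clone}
        changed = True
        while changed:
            changed = False
            for c, p in self.parent.items():
                if p in out and c not in out:
                    out.add(c)
                    changed = True
        return out

    def carrier_fraction(self, sample: str, clone: str) -> float:
        """Share of *all* cells in ``sample`` carrying ``clone``'s events."""
        fr = self.fractions[sample]
        return float(sum(fr.get(c, 0.0) for c in self.descendants(clone)))

    def validate(self) -> None:
        for c, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"clone {c}: unknown parent {p}")
        for sample, fr in self.fractions.items():
            for c, f in fr.items():
                if c not in self.parent:
                    raise ValueError(f"sample {sample}: unknown clone {c}")
                if f < 0:
                    raise ValueError(f"sample {sample}: negative fraction for {c}")
            if sum(fr.values()) > 1 + 1e-9:
                raise ValueError(f"sample {sample}: clone fractions sum above 1")
            # pigeonhole consistency on carrier fractions
            for c, p in self.parent.items():
                if p is not None:
                    if self.carrier_fraction(sample, c) > self.carrier_fraction(sample, p) + 1e-9:
                        raise ValueError(
                            f"sample {sample}: carrier fraction of {c} exceeds parent {p}"
                        )


def check_conflicts(tree: CloneTree, events: list[EventSpec]) -> None:
    """Reject overlapping events on the same haplotype within one lineage."""
    conflicts = []
    for clone in tree.clones:
        lineage = set(tree.lineage(clone))
        mine = [e for e in events if e.clone in lineage]
        for hap in (0, 1):
            hits = []
            for e in mine:
                on_hap = e.kind == "hom_loss" or e.allele == hap
                if on_hap:
                    hits.append(e)
            hits.sort(key=lambda e: (e.chrom, e.start))
            for a, b in itertools.pairwise(hits):
                if a.chrom == b.chrom and b.start < a.end:
                    conflicts.append((clone, hap, a, b))
    if conflicts:
        lines = [
            f"lineage of {c}, haplotype {h}: "
            f"{a.chrom}:{a.start}-{a.end} ({a.kind}@{a.clone}) overlaps "
            f"{b.chrom}:{b.start}-{b.end} ({b.kind}@{b.clone})"
            for c, h, a, b in conflicts
        ]
        raise ConflictError("conflicting events:\n" + "\n".join(lines))


def _clone_haplotype_copies(
    tree: CloneTree, events: list[EventSpec], clone: str, chrom: str, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-haplotype expected copies of ``clone`` on the window grid.

    ``grid`` holds window edges (len n+1); returns two length-n arrays.
    Event boundaries need not align with windows: a partially overlapped
    window gets the length-weighted mean copy.
    """
    n = len(grid) - 1
    haps = [np.ones(n), np.ones(n)]
    lineage = set(tree.lineage(clone))
    widths = np.diff(grid).astype(float)
    for e in events:
        if e.clone not in lineage or e.chrom != chrom:
            continue
        ov = np.minimum(grid[1:], e.end) - np.maximum(grid[:-1], e.start)
        w = np.clip(ov, 0, None) / widths
        if e.kind == "hom_loss":
            haps[0] -= w
            haps[1] -= w
        else:
            affected_copies, _ = e.haplotype_copies()
            haps[e.allele] += w * (affected_copies - 1)
    return haps[0], haps[1]


@dataclass
class SimulatedSample:
    """Window counts plus per-window truth for one sample."""

    sample: str
    windows: pd.DataFrame  # chrom, start, end, n_normal, n_tumor
    truth_copy: np.ndarray  # expected total copy per window


@dataclass
class Scenario:
    """A full simulation scenario: tree, events, SNVs, genome and stage order."""

    tree: CloneTree
    events: list[EventSpec]
    snvs: list[SnvSpec]
    genome: dict[str, int] = field(default_factory=lambda: dict(MINI_GENOME))
    stages: list[str] | None = None  # progression order; defaults to sample order

    @property
    def stage_order(self) -> list[str]:
        return self.stages or self.tree.samples

    def event_carrier(self, sample: str, event: EventSpec) -> float:
        return self.tree.carrier_fraction(sample, event.clone)

    def truth_events(self, sample: str, min_carrier: float = 1e-9) -> pd.DataFrame:
        """Events present in ``sample`` with their carrier fractions (p*f)."""
        rows = []
        for e in self.events:
            F = self.event_carrier(sample, e)
            if F > min_carrier:
                rows.append(
                    dict(
                        chrom=e.chrom,
                        start=e.start,
                        end=e.end,
                        kind=e.kind,
                        copies=e.copies,
                        clone=e.clone,
                        carrier=F,
                        length_mb=round((e.end - e.start) / 1e6, 2),
                        is_loss=e.is_loss,
                    )
                )
        return pd.DataFrame(rows)

    def truth_totals(self, sample: str) -> dict[str, float]:
        ev = self.truth_events(sample)
        if ev.empty:
            return {"lost_mb": 0.0, "gained_mb": 0.0, "n_loss": 0, "n_gain": 0}
        return {
            "lost_mb": float(ev.length_mb[ev.is_loss].sum()),
            "gained_mb": float(ev.length_mb[~ev.is_loss].sum()),
            "n_loss": int(ev.is_loss.sum()),
            "n_gain": int((~ev.is_loss).sum()),
        }


def _window_grid(genome: dict[str, int], window_bp: int) -> dict[str, np.ndarray]:
    grids = {}
    for chrom, length in genome.items():
        edges = np.arange(0, length + 1, window_bp)
        if edges[-1] != length:
            edges = np.append(edges, length)
        grids[chrom] = edges
    return grids


def expected_copy_profile(
    tree: CloneTree, events: list[EventSpec], sample: str, genome: dict[str, int], window_bp: int
) -> pd.DataFrame:
    """Exact expected total copy per window for one sample (the truth table)."""
    grids = _window_grid(genome, window_bp)
    frames = []
    fr = tree.fractions[sample]
    p = tree.purity(sample)
    for chrom, grid in grids.items():
        n = len(grid) - 1
        total = np.full(n, 2.0 * (1.0 - p))
        for clone, f in fr.items():
            if f <= 0:
                continue
            a, b = _clone_haplotype_copies(tree, events, clone, chrom, grid)
            total += f * (a + b)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": grid[:-1], "end": grid[1:], "expected_copy": total}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_counts(
    tree: CloneTree,
    events: list[EventSpec],
    depth: float = 1000.0,
    window_bp: int = 50_000,
    genome: dict[str, int] | None = None,
    seed: int = 0,
) -> dict[str, SimulatedSample]:
    """Draw paired tumor/normal window counts for every sample in the tree.

    Normal counts are Poisson(depth); tumor counts are Poisson around
    ``depth * E[copy]/2``.  Returns one :class:`SimulatedSample` per sample,
    each carrying the exact expected-copy truth.
    """
    genome = genome or MINI_GENOME
    check_conflicts(tree, events)
    rng = np.random.default_rng(seed)
    out = {}
    for sample in tree.samples:
        truth = expected_copy_profile(tree, events, sample, genome, window_bp)
        n = len(truth)
        n_normal = rng.poisson(depth, size=n)
        n_tumor = rng.poisson(depth * truth.expected_copy.to_numpy() / 2.0, size=n)
        windows = truth[["chrom", "start", "end"]].copy()
        windows["n_normal"] = n_normal
        windows["n_tumor"] = n_tumor
        out[sample] = SimulatedSample(sample, windows, truth.expected_copy.to_numpy())
    return out


def expected_site_baf(
    tree: CloneTree, events: list[EventSpec], sample: str, chrom: str, pos: int, b_hap: int
) -> float:
    """Expected tumor BAF at a germline-het site whose B allele sits on ``b_hap``."""
    fr = tree.fractions[sample]
    p = tree.purity(sample)
    b_copies = 1.0 - p  # normal cells contribute one B copy each
    tot = 2.0 * (1.0 - p)
    grid = np.array([pos, pos + 1])
    for clone, f in fr.items():
        if f <= 0:
            continue
        a, b = _clone_haplotype_copies(tree, events, clone, chrom, grid)
        hap_copies = (a[0], b[0])
        b_copies += f * hap_copies[b_hap]
        tot += f * (hap_copies[0] + hap_copies[1])
    if tot <= 0:
        return float("nan")
    return b_copies / tot


def simulate_snp_counts(
    tree: CloneTree,
    events: list[EventSpec],
    n_sites: int = 4000,
    depth: float = 80.0,
    genome: dict[str, int] | None = None,
    seed: int = 0,
    frac_hom: float = 0.2,
    frac_unknown: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Draw per-sample allele depths at SNP sites.

    Sites are uniform over the genome.  A ``frac_hom`` share is germline
    homozygous and a ``frac_unknown`` share lacks the known-SNP annotation;
    both should be removed by the informative-site filter downstream.  The
    truth expected BAF is recorded per site and sample.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    genome = genome or MINI_GENOME
    check_conflicts(tree, events)
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    ci = rng.choice(len(chroms), size=n_sites, p=probs)
    pos = (rng.random(n_sites) * lengths[ci]).astype(np.int64)
    b_hap = rng.integers(0, 2, size=n_sites)
    hom = rng.random(n_sites) < frac_hom
    known = rng.random(n_sites) >= frac_unknown
    site_df = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in ci],
            "pos": pos,
            "b_hap": b_hap,
            "germline_het": ~hom,
            "known_snp": known,
        }
    ).sort_values(["chrom", "pos"], ignore_index=True)

    out = {}
    for sample in tree.samples:
        ebaf = np.empty(n_sites)
        for i, row in enumerate(site_df.itertuples()):
            if row.germline_het:
                ebaf[i] = expected_site_baf(
                    tree, events, sample, row.chrom, int(row.pos), int(row.b_hap)
                )
            else:
                # homozygous germline: B on both haplotypes or neither
                ebaf[i] = float(row.b_hap)
        dep_n = rng.poisson(depth, size=n_sites)
        germ_baf = np.where(site_df.germline_het, 0.5, site_df.b_hap.astype(float))
        b_n = rng.binomial(dep_n, germ_baf)
        # tumor total depth scales with local copy number
        copy = np.array(
            [
                _site_total_copy(tree, events, sample, row.chrom, int(row.pos))
                for row in site_df.itertuples()
            ]
        )
        dep_t = rng.poisson(depth * copy / 2.0, size=n_sites)
        safe = np.nan_to_num(ebaf, nan=0.0)
        b_t = rng.binomial(dep_t, np.clip(safe, 0, 1))
        df = site_df[["chrom", "pos", "known_snp", "germline_het"]].copy()
        df["a_depth_n"] = dep_n - b_n
        df["b_depth_n"] = b_n
        df["a_depth_t"] = dep_t - b_t
        df["b_depth_t"] = b_t
        df["truth_baf"] = ebaf
        out[sample] = df
    return out


def _site_total_copy(
    tree: CloneTree, events: list[EventSpec], sample: str, chrom: str, pos: int
) -> float:
    fr = tree.fractions[sample]
    p = tree.purity(sample)
    tot = 2.0 * (1.0 - p)
    grid = np.array([pos, pos + 1])
    for clone, f in fr.items():
        if f <= 0:
            continue
        a, b = _clone_haplotype_copies(tree, events, clone, chrom, grid)
        tot += f * (a[0] + b[0])
    return tot


def simulate_snvs(
    tree: CloneTree,
    snvs: list[SnvSpec],
    depth: float = 300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a multi-sample somatic variant table with ref/alt depths.

    Variants sit in copy-neutral territory, so the expected VAF in a sample
    is half the carrier fraction of the variant's clone.  The matched normal
    carries no alt reads.  Columns: chrom, pos, ref, alt, annotation,
    known_snp_af, depth_normal, alt_normal, then depth_<sample>/alt_<sample>
    per tumor sample, plus the truth clone and per-sample expected VAF.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for v in snvs:
        if v.clone not in tree.parent:
            raise ValueError(f"SNV {v.chrom}:{v.pos}: unknown clone {v.clone}")
        row: dict[str, object] = dict(
            chrom=v.chrom,
            pos=v.pos,
            ref=v.ref,
            alt=v.alt,
            annotation="nonsynonymous",
            known_snp_af=np.nan,
            truth_clone=v.clone,
        )
        dn = int(rng.poisson(depth))
        row["depth_normal"] = dn
        row["alt_normal"] = 0
        for sample in tree.samples:
            F = tree.carrier_fraction(sample, v.clone)
            vaf = F / 2.0
            d = int(rng.poisson(depth))
            row[f"depth_{sample}"] = d
            row[f"alt_{sample}"] = int(rng.binomial(d, vaf))
            row[f"truth_vaf_{sample}"] = vaf
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundled scenarios
# ---------------------------------------------------------------------------

def four_stage_scenario() -> Scenario:
    """The default study scenario: DCIS-1 -> DCIS-2 -> primary -> metastasis.

    Seven clones on a mostly linear backbone::

        germline -> A (trunk) -> B -> C -> D -> E -> F
                              \\-> B2 (private to DCIS 2)

    * A: founder clone, clonal in every sample (9 trunk events, 23 SNVs).
    * B: DCIS-2 subclone (carrier 0.5 there) whose events ride to later
      stages; B2 is a side branch carrying the single DCIS-2-private SNV.
    * C: invasive clone of the primary tumor.
    * D: the metastasis-founder subclone — subclonal in the primary
      (carrier 0.20, SNV VAF ~ 0.10) and fully clonal in the metastasis
      (carrier 0.9, VAF ~ 0.45): the purification signature.
    * E: metastasis trunk (one new complete loss, 14 private SNVs).
    * F: metastasis subclone (carrier 0.45) with 17 additional shallow
      (level-1) losses from one catastrophic burst plus one homozygous loss
      whose log2 depth coincides with the clonal het-loss level while its
      BAF stays at 0.5 — the subclonal-homozygous-loss special case.

    Purities: 0.8 for the three breast samples, 0.9 for the metastasis.
    """
    parent = {
        "A": None,
        "B": "A",
        "B2": "B",
        "C": "B",
        "D": "C",
        "E": "D",
        "F": "E",
    }
    fractions = {
        "dcis1": {"A": 0.8},
        "dcis2": {"A": 0.3, "B2": 0.5},
        "primary": {"A": 0.02, "B": 0.03, "C": 0.55, "D": 0.2},
        "metastasis": {"E": 0.45, "F": 0.45},
    }
    tree = CloneTree(parent=parent, fractions=fractions)

    M = 1_000_000

    def ev(chrom, s_mb, e_mb, kind, clone, copies=None):
        return EventSpec(chrom, int(s_mb * M), int(e_mb * M), kind, clone, copies)

    events = [
        # trunk (A)
        ev("chr1", 0, 8, "het_loss", "A"),
        ev("chr1", 20, 26, "het_loss", "A"),
        ev("chr2", 0, 40, "het_loss", "A"),
        ev("chr3", 5, 10, "hom_loss", "A"),
        ev("chr3", 15, 19, "het_loss", "A"),
        ev("chr5", 10, 14, "het_loss", "A"),
        ev("chr4", 0, 6, "gain", "A", 3),
        ev("chr4", 10, 14, "gain", "A", 5),
        ev("chr5", 0, 5, "gain", "A", 8),
        # B (new in DCIS 2)
        ev("chr3", 25, 29, "het_loss", "B"),
        ev("chr4", 18, 22, "het_loss", "B"),
        ev("chr5", 20, 24, "gain", "B", 4),
        # C (new in primary)
        ev("chr1", 30, 33.5, "het_loss", "C"),
        ev("chr3", 33, 36, "het_loss", "C"),
        ev("chr4", 23, 26, "het_loss", "C"),
        ev("chr4", 35, 38, "gain", "C", 3),
        ev("chr5", 28, 31, "gain", "C", 3),
        # D (metastasis founder; subclonal in primary)
        ev("chr4", 27, 31, "het_loss", "D"),
        ev("chr5", 38, 40, "het_loss", "D"),
        # E (metastasis trunk)
        ev("chr1", 36, 40, "het_loss", "E"),
        # F (catastrophic subclone): 17 level-1 losses + 1 homozygous loss
        ev("chr1", 9, 11, "het_loss", "F"),
        ev("chr1", 12, 14, "het_loss", "F"),
        ev("chr1", 15, 17, "het_loss", "F"),
        ev("chr1", 17.8, 19, "het_loss", "F"),
        ev("chr1", 27, 29, "het_loss", "F"),
        ev("chr1", 34.5, 35.5, "het_loss", "F"),
        ev("chr3", 11, 13, "het_loss", "F"),
        ev("chr3", 20, 22, "het_loss", "F"),
        ev("chr3", 30, 32, "het_loss", "F"),
        ev("chr3", 37, 39, "het_loss", "F"),
        ev("chr4", 15, 17, "het_loss", "F"),
        ev("chr4", 32, 34, "het_loss", "F"),
        ev("chr4", 38.5, 40, "het_loss", "F"),
        ev("chr5", 6, 8, "het_loss", "F"),
        ev("chr5", 15, 17, "het_loss", "F"),
        ev("chr5", 25, 27, "het_loss", "F"),
        ev("chr5", 32, 34, "het_loss", "F"),
        ev("chr5", 35, 37, "hom_loss", "F"),
    ]

    # SNVs live in copy-neutral gaps between events
    gaps = [
        ("chr3", 0.2, 4.8),
        ("chr4", 6.2, 9.8),
        ("chr3", 22.2, 24.8),
        ("chr5", 17.2, 19.8),
        ("chr1", 8.2, 8.9),
        ("chr1", 19.2, 19.9),
        ("chr4", 34.2, 34.9),
    ]
    counts = {"A": 23, "B": 4, "B2": 1, "C": 5, "D": 5, "E": 14, "F": 3}
    bases = ["A", "C", "G", "T"]
    snvs: list[SnvSpec] = []
    slots = []
    for chrom, s_mb, e_mb in gaps:
        n_slot = int((e_mb - s_mb) / 0.25)
        for k in range(n_slot):
            slots.append((chrom, int((s_mb + 0.12 + 0.25 * k) * M)))
    it = iter(slots)
    for clone, n in counts.items():
        for j in range(n):
            chrom, pos = next(it)
            ref = bases[pos % 4]
            alt = bases[(pos // 4 + 1 + pos % 3) % 4]
            if alt == ref:
                alt = bases[(bases.index(ref) + 1) % 4]
            snvs.append(SnvSpec(chrom, pos, ref, alt, clone))

    return Scenario(
        tree=tree,
        events=events,
        snvs=snvs,
        genome=dict(MINI_GENOME),
        stages=["dcis1", "dcis2", "primary", "metastasis"],
    )


def single_event_scenario(purity: float, fraction: float, length_mb: float = 5.0) -> Scenario:
    """One sample, one subclone, one heterozygous loss — for recovery sweeps."""
    tree = CloneTree(
        parent={"trunk": None, "sub": "trunk"},
        fractions={"s": {"trunk": purity * (1 - fraction), "sub": purity * fraction}},
    )
    genome = {"chr1": 20_000_000}
    ev = EventSpec("chr1", 5_000_000, int((5 + length_mb) * 1e6), "het_loss", "sub")
    return Scenario(tree=tree, events=[ev], snvs=[], genome=genome, stages=["s"])


def simulate_filter_candidates(n: int = 200, seed: int = 0) -> pd.DataFrame:
    """Labeled candidate variants for exercising the somatic-call filter.

    Builds ``n`` candidates cycling through constructed classes — clean
    clonal somatics, subclonal somatics below the discovery threshold,
    germline heterozygotes, noisy normals, low-depth normals, common
    population SNPs, and boundary cases sitting exactly on the documented
    thresholds — each labeled with the expected filter verdict
    (``expected_pass``).  Labels follow from the construction, with noisy
    quantities kept well clear of the thresholds.
    """
    rng = np.random.default_rng(seed)
    samples = ["t1", "t2"]
    rows = []
    classes = [
        "clonal_pass",
        "subclonal_low_fail",
        "germline_het_fail",
        "noisy_normal_fail",
        "low_normal_depth_fail",
        "common_snp_fail",
        "boundary_pass",
        "low_alt_fail",
    ]
    for i in range(n):
        cls = classes[i % len(classes)]
        chrom = f"chr{1 + i % 5}"
        pos = 100_000 + 7919 * i
        row: dict[str, object] = dict(
            chrom=chrom, pos=pos, ref="A", alt="G", annotation="nonsynonymous",
            known_snp_af=np.nan, truth_class=cls,
        )
        dn = int(rng.integers(60, 120))
        row["depth_normal"], row["alt_normal"] = dn, 0
        d1, d2 = int(rng.integers(80, 160)), int(rng.integers(80, 160))
        if cls == "clonal_pass":
            a1 = int(rng.binomial(d1, 0.42))
            a2 = int(rng.binomial(d2, 0.40))
            passes = True
        elif cls == "subclonal_low_fail":
            # present but never above the 0.15 discovery threshold
            a1 = max(3, int(round(d1 * 0.08)))
            a2 = max(3, int(round(d2 * 0.08)))
            passes = False
        elif cls == "germline_het_fail":
            row["alt_normal"] = int(rng.binomial(dn, 0.5))
            if row["alt_normal"] < 0.1 * dn:  # keep clear of the 0.02 bound
                row["alt_normal"] = int(0.4 * dn)
            a1, a2 = int(rng.binomial(d1, 0.5)), int(rng.binomial(d2, 0.5))
            passes = False
        elif cls == "noisy_normal_fail":
            row["alt_normal"] = max(int(round(dn * 0.05)), int(np.ceil(dn * 0.03)))
            a1, a2 = int(rng.binomial(d1, 0.4)), int(rng.binomial(d2, 0.4))
            passes = False
        elif cls == "low_normal_depth_fail":
            row["depth_normal"], row["alt_normal"] = int(rng.integers(1, 10)), 0
            a1, a2 = int(rng.binomial(d1, 0.4)), int(rng.binomial(d2, 0.4))
            passes = False
        elif cls == "common_snp_fail":
            row["known_snp_af"] = 0.05
            a1, a2 = int(rng.binomial(d1, 0.4)), int(rng.binomial(d2, 0.4))
            passes = False
        elif cls == "boundary_pass":
            # exactly on the documented inclusive bounds
            row["depth_normal"], row["alt_normal"] = 10, 0
            d1, a1 = 18, 3  # BAF 0.1667 > 0.15 with exactly 3 alt reads
            d2, a2 = 100, 4  # BAF 0.04: below presence threshold
            passes = True
        else:  # low_alt_fail: high BAF but < 3 alt reads
            d1, a1 = 10, 2
            d2, a2 = 10, 2
            passes = False
        row["depth_t1"], row["alt_t1"] = d1, a1
        row["depth_t2"], row["alt_t2"] = d2, a2
        row["expected_pass"] = passes
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# YAML scenario round-trip
# ---------------------------------------------------------------------------

def scenario_to_yaml(sc: Scenario, path) -> None:
    doc = {
        "genome": {k: int(v) for k, v in sc.genome.items()},
        "stages": sc.stage_order,
        "tree": {
            "parent": {k: v for k, v in sc.tree.parent.items()},
            "fractions": {s: dict(fr) for s, fr in sc.tree.fractions.items()},
        },
        "events": [
            dict(chrom=e.chrom, start=int(e.start), end=int(e.end), kind=e.kind,
                 clone=e.clone, copies=int(e.copies), allele=int(e.allele))
            for e in sc.events
        ],
        "snvs": [
            dict(chrom=v.chrom, pos=int(v.pos), ref=v.ref, alt=v.alt, clone=v.clone)
            for v in sc.snvs
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path) -> Scenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    tree = CloneTree(parent=doc["tree"]["parent"], fractions=doc["tree"]["fractions"])
    events = [
        EventSpec(d["chrom"], d["start"], d["end"], d["kind"], d["clone"],
                  d.get("copies"), d.get("allele", 0))
        for d in doc["events"]
    ]
    snvs = [SnvSpec(d["chrom"], d["pos"], d["ref"], d["alt"], d["clone"]) for d in doc["snvs"]]
    return Scenario(tree=tree, events=events, snvs=snvs,
                    genome=doc["genome"], stages=doc.get("stages"))
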