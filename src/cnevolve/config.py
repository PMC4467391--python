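"""Pipeline configuration: one YAML document driving every stage."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["SampleInput", "PipelineConfig"]


@dataclass
class SampleInput:
    """Input paths for one progression stage."""

    name: str
    counts: str               # window counts TSV (chrom,start,end,n_normal,n_tumor)
    snps: str | None = None   # SNP allele-count TSV
    purity: float = 1.0


@dataclass
class PipelineConfig:
    """All tunables of a run; round-trips losslessly through YAML."""

    samples: list[SampleInput]
    snv_table: str | None = None
    outdir: str = "results"
    seed: int = 0
    reads_per_window: int = 1000
    min_probes: int = 10
    penalty: float | None = None
    merge_tol: float = 0.1
    min_snp_depth: int = 30
    bp_tol: int = 100_000
    loss_log2: float = -0.1
    gain_log2: float = 0.15
    subclonal_band: tuple[float, float] = (0.05, 0.25)
    clonal_band: tuple[float, float] = (0.35, 0.55)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("config needs at least one sample")
        self.samples = [
            s if isinstance(s, SampleInput) else SampleInput(**s) for s in self.samples
        ]
        for s in self.samples:
            if not 0 <= s.purity <= 1:
                raise ValueError(f"sample {s.name}: purity out of [0, 1]")
        if self.min_probes < 1 or self.reads_per_window < 1:
            raise ValueError("min_probes and reads_per_window must be >= 1")

    @property
    def stage_order(self) -> list[str]:
        return [s.name for s in self.samples]

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["subclonal_band"] = list(self.subclonal_band)
        doc["clonal_band"] = list(self.clonal_band)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("subclonal_band", "clonal_band"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)
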