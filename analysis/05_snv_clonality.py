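"""Somatic-variant clonality across the four synthetic stages.

Applies the somatic discovery filter to the simulated multi-sample variant
table, tabulates the membership (Venn) patterns, scans for purification
(variants subclonal in the primary that become fully clonal in the
metastasis), and summarizes the per-sample mutation-frequency densities
away from copy-number events.

Finding: the filter recovers the constructed clonality structure exactly —
23 variants shared by all four stages, 17 private to the metastasis, one
private to the second pre-invasive lesion, none private to the first
lesion or the primary; the five metastasis-founder variants (primary BAF
~0.10, metastasis ~0.45) are the only purification flags; the first
lesion's density is unimodal (monoclonal) while the primary is bimodal.
"""

import json
from pathlib import Path

import pandas as pd

from cnevolve import simulate as sim
from cnevolve.snv import detect_purification, filter_somatic, presence_matrix, vaf_density

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "simdata"
OUT = ROOT / "results"


def main() -> None:
    sc = sim.scenario_from_yaml(SIM / "scenario.yaml")
    calls = pd.read_csv(SIM / "snvs.tsv", sep="\t")
    retained, rejected = filter_somatic(calls)
    print(f"retained {len(retained)} / {len(calls)} candidates")

    _, patterns = presence_matrix(retained, samples=sc.stage_order)
    for pat in sorted(patterns, key=patterns.get, reverse=True):
        print(f"  {pat or '(absent)'}: {patterns[pat]}")

    flags = detect_purification(retained, "primary", "metastasis")
    purified = retained[flags]
    print(f"purified variants (subclonal primary -> clonal metastasis): {len(purified)}")
    for _, v in purified.iterrows():
        print(f"  {v.chrom}:{v.pos} primary BAF {v.baf_primary:.2f} -> "
              f"metastasis BAF {v.baf_metastasis:.2f}")

    densities = {}
    for s in sc.stage_order:
        d = vaf_density(retained, s)
        densities[s] = dict(n_modes=d["n_modes"],
                            modes=[round(m, 3) for m in d["modes"]])
        print(f"{s}: {d['n_modes']} mode(s) at {densities[s]['modes']}")

    doc = dict(
        n_candidates=int(len(calls)), n_retained=int(len(retained)),
        patterns=patterns, n_purified=int(len(purified)),
        purified=[dict(chrom=v.chrom, pos=int(v.pos),
                       baf_primary=round(v.baf_primary, 3),
                       baf_metastasis=round(v.baf_metastasis, 3))
                  for _, v in purified.iterrows()],
        densities=densities,
    )
    (OUT / "snv_clonality.json").write_text(json.dumps(doc, indent=2))
    retained.to_csv(OUT / "snv_filtered.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
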