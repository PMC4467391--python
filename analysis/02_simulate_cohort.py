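"""Generate the synthetic four-stage cohort used by the downstream analyses.

Materializes the bundled clone-tree scenario (two pre-invasive lesions, a
primary tumor with a metastasis-founder subclone, and a metastasis with a
catastrophic 17-loss subclone) as window counts, SNP allele depths and a
multi-sample somatic variant table under results/simdata/, together with
the scenario YAML and per-sample truth totals.
"""

import json
from pathlib import Path

from cnevolve import simulate as sim
from cnevolve import tables

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "simdata"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 11
DEPTH = 1000          # reads per window
WINDOW_BP = 50_000
N_SITES = 4000
SNP_DEPTH = 80
SNV_DEPTH = 300       # targeted-validation-like depth


def main() -> None:
    sc = sim.four_stage_scenario()
    sim.scenario_to_yaml(sc, OUT / "scenario.yaml")

    counts = sim.simulate_counts(sc.tree, sc.events, depth=DEPTH,
                                 window_bp=WINDOW_BP, genome=sc.genome, seed=SEED)
    snps = sim.simulate_snp_counts(sc.tree, sc.events, n_sites=N_SITES,
                                   depth=SNP_DEPTH, genome=sc.genome, seed=SEED + 1)
    snvs = sim.simulate_snvs(sc.tree, sc.snvs, depth=SNV_DEPTH, seed=SEED + 2)

    for name in sc.stage_order:
        tables.write_window_counts(counts[name].windows, OUT / f"{name}.counts.tsv")
        tables.write_snp_table(snps[name], OUT / f"{name}.snps.tsv")
    snvs.to_csv(OUT / "snvs.tsv", sep="\t", index=False)

    truth = {s: sc.truth_totals(s) for s in sc.stage_order}
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2))

    print(f"wrote {len(sc.stage_order)} samples to {OUT}")
    for s, t in truth.items():
        print(f"  {s}: truth lost {t['lost_mb']:.1f} Mb ({t['n_loss']} events), "
              f"gained {t['gained_mb']:.1f} Mb ({t['n_gain']} events)")


if __name__ == "__main__":
    main()
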