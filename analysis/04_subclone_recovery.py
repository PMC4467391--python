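"""Subclone-fraction recovery and two-level loss clustering.

Part A sweeps a 5 x 4 grid of purity (0.6-1.0) and subclone fraction
(0.25-1.0): each cell simulates a single heterozygous loss at 1000-read
windows, runs the per-sample pipeline and compares the BAF-based p*f
estimate with truth.  Part B takes the metastasis of the four-stage
scenario and checks that two-level clustering isolates the 17
catastrophic-burst losses (level 1) from the clonal background (level 2),
and that the balanced-BAF homozygous loss is resolved with its fraction.

Finding: median |p*f error| ~ 0.008 across the grid; all 17 level-1
losses recovered; the subclonal homozygous loss comes back at p*f ~ 0.45.
"""

import json
from pathlib import Path

import numpy as np

from cnevolve import simulate as sim
from cnevolve.pipeline import analyze_sample

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

PURITY = {"dcis1": 0.8, "dcis2": 0.8, "primary": 0.8, "metastasis": 0.9}


def sweep() -> dict:
    rows = []
    k = 0
    for p in (0.6, 0.7, 0.8, 0.9, 1.0):
        for f in (0.25, 0.5, 0.75, 1.0):
            scn = sim.single_event_scenario(p, f)
            counts = sim.simulate_counts(scn.tree, scn.events, depth=1000,
                                         window_bp=50_000, genome=scn.genome,
                                         seed=100 + k)
            snps = sim.simulate_snp_counts(scn.tree, scn.events, n_sites=800,
                                           depth=100, genome=scn.genome, seed=200 + k)
            _, _, evs = analyze_sample(counts["s"].windows, snps["s"], p)
            losses = [e for e in evs if e.is_loss]
            est = max(losses, key=lambda e: e.n_windows).est_fraction if losses else 0.0
            rows.append(dict(purity=p, fraction=f, truth_pf=round(p * f, 3),
                             est_pf=round(est or 0.0, 3),
                             abs_err=round(abs((est or 0.0) - p * f), 4)))
            k += 1
    errs = [r["abs_err"] for r in rows]
    print(f"fraction recovery: median |err| {np.median(errs):.4f}, "
          f"max {max(errs):.4f} over {len(rows)} scenarios")
    return dict(scenarios=rows, median_abs_err=float(np.median(errs)),
                max_abs_err=float(max(errs)))


def metastasis_levels() -> dict:
    sc = sim.four_stage_scenario()
    counts = sim.simulate_counts(sc.tree, sc.events, depth=1000, window_bp=50_000,
                                 genome=sc.genome, seed=11)
    snps = sim.simulate_snp_counts(sc.tree, sc.events, n_sites=4000, depth=80,
                                   genome=sc.genome, seed=12)
    _, _, evs = analyze_sample(counts["metastasis"].windows, snps["metastasis"],
                               PURITY["metastasis"], sample="metastasis")
    level1 = [e for e in evs if e.loss_level == 1]
    hl_sub = [e for e in evs if e.category == "HL" and e.clonality == "subclonal"]
    truth = sc.truth_events("metastasis")
    burst = truth[(truth.clone == "F") & (truth.kind == "het_loss")]
    hits = sum(
        any(e.chrom == t.chrom and abs(e.start - t.start) <= 100_000
            and abs(e.end - t.end) <= 100_000 for e in level1)
        for _, t in burst.iterrows()
    )
    print(f"two-level clustering: {len(level1)} level-1 losses called, "
          f"{hits}/{len(burst)} burst losses recovered")
    for e in hl_sub:
        print(f"subclonal homozygous loss {e.chrom}:{e.start}-{e.end}: "
              f"p*f {e.est_fraction:.3f} (truth "
              f"{sc.tree.carrier_fraction('metastasis', 'F'):.2f})")
    return dict(
        n_level1=len(level1), n_burst_truth=int(len(burst)),
        burst_recovered=int(hits),
        hl_subclonal=[dict(chrom=e.chrom, start=e.start, end=e.end,
                           est_pf=round(e.est_fraction, 3)) for e in hl_sub],
    )


def main() -> None:
    doc = dict(sweep=sweep(), metastasis=metastasis_levels())
    (OUT / "subclone_recovery.json").write_text(json.dumps(doc, indent=2))


if __name__ == "__main__":
    main()
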