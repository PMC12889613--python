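#!/usr/bin/env python
"""ROC curves and score-binned summaries of the selectivity landscape.

Evaluates how well the (gatekeeper-adjusted) threading score separates
selective from promiscuous kinases at selectivity thresholds 5/10/15 and at
two hit definitions (Kd < 10 uM and Kd < 100 nM); then averages hit rates
within groups of 25 kinases and tabulates strong/average/weak affinity
fractions within bins of 35 kinases for the most promiscuous inhibitors.
Writes results/roc_summary.csv, results/bins_hitrate.csv,
results/bins_affinity.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import pottsthread as pt
from pottsthread.synthetic import load_world


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    world = load_world(args.outdir / "world")
    panel = world.panel
    scores_frame = pd.read_csv(args.outdir / "threading.csv")
    scores = scores_frame.set_index("kinase_id")["adjusted_score"]

    rows = []
    for hit_cutoff in (10000.0, 100.0):
        rates = pt.hit_rates(panel, kd_cutoff_nM=hit_cutoff)
        for thr in (5, 10, 15):
            labels = pt.label_selectivity(rates, thr)
            if labels.nunique() < 2:
                continue
            roc = pt.roc_auc(scores.reindex(rates.index), labels)
            rows.append({
                "hit_cutoff_nM": hit_cutoff, "selectivity_threshold": thr,
                "auc": round(roc.auc, 3),
                "best_score_cutoff": round(roc.best_cutoff, 2),
            })
    roc_summary = pd.DataFrame(rows)
    roc_summary.to_csv(args.outdir / "roc_summary.csv", index=False)
    print("ROC summary (positive class = selective):")
    print(roc_summary.to_string(index=False))

    rates = pt.hit_rates(panel)
    groups = pt.bin_by_score(scores, rates.reindex(scores.index), group_size=25)
    groups.to_csv(args.outdir / "bins_hitrate.csv", index=False)
    print("\ngroups of 25 kinases by descending score "
          f"-> {args.outdir / 'bins_hitrate.csv'}")
    print(groups[["group", "n", "mean_score", "mean_value"]]
          .rename(columns={"mean_value": "mean_hit_rate"})
          .to_string(index=False))

    promiscuous = pt.most_promiscuous(panel, n=4)
    bins = pt.binned_affinity_distribution(panel, scores, promiscuous, bin_size=35)
    bins.to_csv(args.outdir / "bins_affinity.csv", index=False)
    print(f"\naffinity-class fractions for {promiscuous} "
          f"-> {args.outdir / 'bins_affinity.csv'}")
    print(bins.to_string(index=False))


if __name__ == "__main__":
    main()
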