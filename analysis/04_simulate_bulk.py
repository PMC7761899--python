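#!/usr/bin/env python
"""Simulate the bulk tumor cohort: 300 tumors, each a purity-0.8
mixture dominated by one generating cell type's expression profile,
with receptor labels and exponential survival (one type at 3x hazard).

Type profiles are the per-type mean log2 expression of the simulated
single cells, so the bulk cohort is linked to the same ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from mammosig import BulkSimConfig, ExpressionTable, io, simulate_bulk
from mammosig.synthetic import type_log2_profiles, write_ground_truth
from mammosig.workflows import DEFAULT_HAZARD_MULTIPLIERS, DEFAULT_SUBTYPE_RULE

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-tumors", type=int, default=300)
    ap.add_argument("--purity", type=float, default=0.8)
    ap.add_argument("--noise-sd", type=float, default=0.8)
    args = ap.parse_args()

    sc_dir = ROOT / "scratch" / "sim" / "sc"
    umi = io.read_mtx_triplet(sc_dir)
    truth = pd.read_csv(sc_dir / "cell_types.tsv", sep="\t",
                        index_col="barcode")["cell_type"]
    real = truth[truth != "aggregate"]
    keep = [i for i, bc in enumerate(umi.barcodes) if bc in real.index]
    profiles = type_log2_profiles(umi.subset_cells(pd.Index(keep)),
                                  real.reindex([umi.barcodes[i] for i in keep]))

    cfg = BulkSimConfig(
        n_tumors=args.n_tumors, purity=args.purity, noise_sd=args.noise_sd,
        subtype_rule={t: DEFAULT_SUBTYPE_RULE.get(t, ("NA", "NA", "NA"))
                      for t in profiles.columns},
        baseline_hazard=0.02,
        hazard_multipliers={t: DEFAULT_HAZARD_MULTIPLIERS.get(t, 1.0)
                            for t in profiles.columns},
        censor_rate=0.2, seed=args.seed,
    )
    expr, clinical, bulk_truth = simulate_bulk(cfg, profiles)

    out = ROOT / "scratch" / "sim" / "bulk"
    out.mkdir(parents=True, exist_ok=True)
    io.write_expression_tsv(ExpressionTable(expr, scale="log2"),
                            out / "expression.tsv")
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    write_ground_truth(bulk_truth, out)

    by_type = bulk_truth.generating_type_of_tumor.value_counts()
    print(f"simulated {expr.shape[1]} tumors x {expr.shape[0]} genes -> {out}")
    print(f"event rate: {clinical['os_event'].mean():.2f}")
    print(by_type.to_string())


if __name__ == "__main__":
    main()
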