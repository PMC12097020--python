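#!/usr/bin/env python
"""QC-filter the simulated cohort and call antigen positivity.

Applies the strict QC rules (mito fraction > 0.20, detected genes < 200 or
> 2500) to every patient, verifies the planted violators are the cells
removed, then binarizes antigen expression (counts-per-10k, log1p, tau = 0)
and tabulates per-antigen marginal positivity.

Writes results/02_qc_report.tsv and results/02_marginal_positivity.tsv.
"""

from pathlib import Path

import pandas as pd

from covpanel import SimConfig, call_positivity, normalize, qc_filter, simulate_cohort

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = SimConfig(seed=SEED, n_patients=6, cells_per_patient=800)
    cohort, truth = simulate_cohort(cfg)
    qc_rows, marg_rows = [], []
    for pid, adata in cohort.items():
        filtered, rep = qc_filter(adata)
        planted = set(truth.qc_violators[pid]["barcode"])
        qc_rows.append(
            {
                "patient": pid,
                "n_input": rep.n_input,
                "n_retained": rep.n_retained,
                "high_mito": rep.removed_high_mito,
                "low_genes": rep.removed_low_genes,
                "high_genes": rep.removed_high_genes,
                "planted_recovered_exactly": set(rep.removed_barcodes) == planted,
            }
        )
        P = call_positivity(normalize(filtered), cfg.antigen_gene_map)
        marg_rows.append({"patient": pid} | {a: round(float(P.flags[a].mean()), 4)
                                             for a in P.antigens})
    qc_df, marg_df = pd.DataFrame(qc_rows), pd.DataFrame(marg_rows)
    OUT.mkdir(exist_ok=True)
    qc_df.to_csv(OUT / "02_qc_report.tsv", sep="\t", index=False)
    marg_df.to_csv(OUT / "02_marginal_positivity.tsv", sep="\t", index=False)
    print(qc_df.to_string(index=False))
    print()
    print(marg_df.to_string(index=False))
    print(
        f"\nQC removed the planted violator sets exactly in "
        f"{qc_df['planted_recovered_exactly'].sum()}/{len(qc_df)} patients. "
        "No single antigen reaches high coverage alone — the motivation for "
        "combination panels."
    )


if __name__ == "__main__":
    main()
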