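#!/usr/bin/env python
"""Differential expression on both branches, each timepoint vs T1.

miRNA counts: NB Wald test with median-of-ratios normalization and the
padj <= 0.05, |log2FC| >= 1, baseMean >= 10 filters. Microarray
intensities: Welch t-test with p <= 0.05 and |log2FC| >= 0.8. Reports
how many planted features were recovered.
"""

import json
from pathlib import Path

import pandas as pd

from smoltmir.diffexpr import de_mirna, de_mrna

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    counts = pd.read_csv(RUN_DIR / "mirna_counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(RUN_DIR / "samples_smallrna.tsv", sep="\t", index_col=0)
    expr = pd.read_csv(RUN_DIR / "expression.tsv", sep="\t", index_col=0)
    expr_samples = pd.read_csv(RUN_DIR / "samples_array.tsv", sep="\t", index_col=0)
    truth = json.loads((RUN_DIR / "ground_truth.json").read_text())

    mirna_res = de_mirna(counts, samples)
    mirna_res.to_csv(RUN_DIR / "de_mirna.tsv", sep="\t")
    mrna_res = de_mrna(expr, expr_samples)
    mrna_res.to_csv(RUN_DIR / "de_mrna.tsv", sep="\t")

    planted = {m for v in truth["de_mirnas"].values() for m in v}
    called = set(mirna_res.index[mirna_res["de_any"]])
    print(f"DE miRNAs: {len(called)} called, {len(called & planted)}/{len(planted)} planted recovered, "
          f"{len(called - planted)} false calls")
    print(f"DE genes: {int(mrna_res['de_any'].sum())} called")


if __name__ == "__main__":
    main()
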