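#!/usr/bin/env python
"""Overrepresentation analysis of the final target genes and run summary.

Tests every annotation term for enrichment of the pair-table genes
against all annotated genes (one-sided Fisher / hypergeometric, BH,
FDR < 0.05) and rolls significant terms up their parent hierarchy.
The planted term should be the clear positive among the decoys.
"""

from pathlib import Path

import pandas as pd

from smoltmir.enrich import AnnotationTable, filter_significant, fisher_enrich, hierarchical_rollup

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    pair_table = pd.read_csv(RUN_DIR / "pair_table.tsv", sep="\t")
    ann = AnnotationTable.from_frame(pd.read_csv(RUN_DIR / "annotation.tsv", sep="\t"))
    study = set(pair_table["gene"])
    background = set(ann.gene_terms)
    results = fisher_enrich(study, background, ann)
    results.to_csv(RUN_DIR / "enrichment.tsv", sep="\t")
    sig = filter_significant(results)
    rollup = hierarchical_rollup(sig, ann.parents, ann, study)
    print(f"{len(sig)} of {len(results)} terms significant at FDR < 0.05")
    for term, row in sig.iterrows():
        print(f"  {term}: k={row.k}/K={row.K}, fold={row.fold_enrichment:.1f}, fdr={row.fdr:.2e}")
    print(f"hierarchical groups: {list(rollup)}")


if __name__ == "__main__":
    main()
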