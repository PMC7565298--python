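"""Gene-set overrepresentation analysis.

One-sided Fisher's exact test per annotation term (identically the
hypergeometric upper tail) of a study gene set against a background,
BH-adjusted, significant at FDR < 0.05 (strict). An optional
parent-link DAG lets significant terms be rolled up under their most
general significant ancestor, mirroring hierarchy-sorted reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust


@dataclass
class AnnotationTable:
    """gene -> set of term ids, term names, optional parent links (DAG)."""

    gene_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if any(not g for g in self.gene_terms):
            raise ValueError("empty gene id in annotation")
        for term, ps in self.parents.items():
            if term in ps:
                raise ValueError(f"self-loop in parent links at {term}")

    @property
    def terms(self) -> set[str]:
        return set().union(*self.gene_terms.values()) if self.gene_terms else set()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationTable":
        """Long TSV layout: gene, term, optional name, optional parent."""
        gene_terms: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        parents: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            gene_terms.setdefault(str(row.gene), set()).add(str(row.term))
            if hasattr(row, "name") and pd.notna(getattr(row, "name")):
                names[str(row.term)] = str(getattr(row, "name"))
            if hasattr(row, "parent") and pd.notna(getattr(row, "parent")) and getattr(row, "parent"):
                parents.setdefault(str(row.term), set()).add(str(row.parent))
        return cls(gene_terms, names, parents)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(
    study: set[str],
    background: set[str],
    annotation: AnnotationTable,
) -> pd.DataFrame:
    """Per-term overrepresentation of ``study`` within ``background``."""
    stray = study - background
    if stray:
        raise ValueError(f"study genes missing from background: {sorted(stray)[:10]}")
    term_bg: dict[str, set[str]] = {}
    for gene in background:
        for term in annotation.gene_terms.get(gene, ()):  # unannotated genes still count in N
            term_bg.setdefault(term, set()).add(gene)
    N, n = len(background), len(study)
    rows = []
    for term in sorted(term_bg):
        members = term_bg[term]
        K = len(members)
        k = len(members & study)
        p = hypergeom_upper_tail(k, N, K, n) if k > 0 else 1.0
        fold = (k / n) / (K / N) if n and K else 0.0
        rows.append(
            {
                "term": term,
                "name": annotation.term_names.get(term, term),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fold_enrichment": fold,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out = out.set_index("term")
    return out


def filter_significant(results: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Terms with fdr strictly below the threshold, sorted by (fdr, -fold)."""
    if results.empty:
        return results
    sig = results[results["fdr"] < fdr_threshold].copy()
    return sig.sort_values(["fdr", "fold_enrichment"], ascending=[True, False])


def hierarchical_rollup(
    significant: pd.DataFrame,
    parents: dict[str, set[str]],
    annotation: AnnotationTable | None = None,
    study: set[str] | None = None,
) -> dict[str, dict]:
    """Group significant terms under their most general significant ancestor.

    Returns {root term: {"terms": [...], "genes": [...]}}; a gene may
    appear under several roots (terms share genes). Raises on cycles.
    """
    sig_terms = set(significant.index)
    _check_acyclic(parents)

    def ancestors(term: str) -> set[str]:
        seen: set[str] = set()
        stack = [term]
        while stack:
            for p in parents.get(stack.pop(), ()):  # walk the DAG upward
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    roots: dict[str, list[str]] = {}
    for term in sorted(sig_terms):
        sig_anc = ancestors(term) & sig_terms
        # most general = a significant ancestor that itself has no significant ancestor
        candidates = [a for a in sorted(sig_anc) if not (ancestors(a) & sig_terms)]
        root = candidates[0] if candidates else term
        roots.setdefault(root, []).append(term)
    report: dict[str, dict] = {}
    for root, terms in sorted(roots.items()):
        genes: set[str] = set()
        if annotation is not None and study is not None:
            for g in study:
                if annotation.gene_terms.get(g, set()) & set(terms):
                    genes.add(g)
        report[root] = {"terms": sorted(terms), "genes": sorted(genes)}
    return report


def _check_acyclic(parents: dict[str, set[str]]) -> None:
    state: dict[str, int] = {}

    def visit(t: str) -> None:
        state[t] = 1
        for p in parents.get(t, ()):
            if state.get(p) == 1:
                raise ValueError(f"cycle in parent links through {t} -> {p}")
            if state.get(p) != 2:
                visit(p)
        state[t] = 2

    for t in list(parents):
        if state.get(t) != 2:
            visit(t)
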