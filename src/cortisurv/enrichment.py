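"""Over-representation analysis of gene sets against term annotations.

One-sided hypergeometric (upper-tail) test per term with Benjamini–Hochberg
FDR control across terms. Annotations are taken as given (no ontology-graph
propagation); supply them in GMT format.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .expression import bh_fdr

__all__ = ["Annotation", "read_gmt", "write_gmt", "hypergeom_enrich"]


@dataclass(frozen=True)
class Annotation:
    term_id: str
    label: str
    genes: frozenset[str]


def read_gmt(text: str) -> list[Annotation]:
    """Parse GMT: one term per line, tab-separated id, description, genes."""
    terms = []
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs id, description, >=1 gene: {line!r}")
        terms.append(Annotation(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return terms


def write_gmt(terms: list[Annotation]) -> str:
    return "\n".join(
        "\t".join([t.term_id, t.label, *sorted(t.genes)]) for t in terms
    ) + "\n"


def hypergeom_enrich(
    selected_genes,
    universe,
    annotations: list[Annotation],
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of `selected_genes` per term.

    With N genes in the universe, K annotated to a term, and n selected, the
    p-value is P(X >= k) for the observed overlap k under a hypergeometric
    draw. Terms are BH-adjusted and sorted by q then p; ``enriched`` marks
    q <= `fdr_level`.
    """
    universe = set(universe)
    selected = set(selected_genes)
    outside = selected - universe
    if outside:
        raise ValueError(f"selected genes outside the universe: {sorted(outside)[:10]}")
    N, n = len(universe), len(selected)
    rows = []
    for term in annotations:
        ann = term.genes & universe
        K = len(ann)
        if K == 0:
            continue
        k = len(ann & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append(
            {"term_id": term.term_id, "label": term.label, "k": k, "K": K, "n": n,
             "N": N, "p": min(p, 1.0)}
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["q"] = bh_fdr(res["p"].to_numpy())
    res["enriched"] = res["q"] <= fdr_level
    return res.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
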