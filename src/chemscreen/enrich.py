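"""Gene-set over-representation analysis.

A plain hypergeometric upper-tail test of a hit list against term → gene
annotation sets over a fixed gene universe, with Benjamini–Hochberg
adjustment across the tested terms.  No ontology-graph propagation or
conditional testing: the annotation map is taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["AnnotationMap", "hypergeometric_enrichment", "benjamini_hochberg"]


@dataclass
class AnnotationMap:
    """term_id → member gene set over a gene universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        self.universe = frozenset(self.universe)
        for term, genes in self.terms.items():
            outside = genes - self.universe
            if outside:
                raise ValueError(
                    f"term {term!r} has members outside the universe: {sorted(outside)[:5]}"
                )

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        universe: Iterable[str] | None = None,
    ) -> "AnnotationMap":
        """Build from (term_id, gene_id) pairs; the universe defaults to
        the union of all annotated genes."""
        terms: dict[str, set[str]] = {}
        for term, gene in pairs:
            terms.setdefault(term, set()).add(gene)
        if universe is None:
            universe = set().union(*terms.values()) if terms else set()
        return cls({t: frozenset(g) for t, g in terms.items()}, frozenset(universe))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def hypergeometric_enrichment(
    hits: Iterable[str],
    annotation: AnnotationMap,
    *,
    min_term_size: int = 1,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per term.

    With universe size N, term size K, hit-list size n and k hits in the
    term, p = P(X ≥ k) for X ~ Hypergeom(N, K, n).  Hits must lie inside
    the universe.  Returns a frame sorted by p with columns term_id, k, n,
    K, N, p, p_adj (Benjamini–Hochberg over the tested terms).
    """
    hit_set = set(hits)
    outside = hit_set - annotation.universe
    if outside:
        raise ValueError(f"hit genes outside the universe: {sorted(outside)[:10]}")
    N = len(annotation.universe)
    n = len(hit_set)
    rows = []
    for term, genes in annotation.terms.items():
        K = len(genes)
        if K < min_term_size:
            continue
        k = len(hit_set & genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
        df = df.sort_values(["p", "term_id"]).reset_index(drop=True)
    return df
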