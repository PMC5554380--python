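"""Seed + first-neighbor network degree reporting and hypergeometric
over-representation analysis (ORA).

The regulatory network around a miRNA gene and its validated targets is
consumed as an edge list; analysis is limited to the induced first-neighbor
subgraph and its node degrees (hub reporting).  ORA tests each annotation
term for over-representation of the query gene set against an annotated
background universe, reporting GeneRatio = k/n and BgRatio = K/N alongside
the upper-tail hypergeometric p and its Benjamini–Hochberg adjustment
(significance at BH ≤ 0.05 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .multitest import bh_adjust

logger = logging.getLogger(__name__)


def first_neighbor_network(seeds: Iterable[str], interactions: nx.Graph) -> nx.Graph:
    """Induced subgraph on the seed genes and their first neighbors.

    Seeds absent from the interaction table are kept as isolated nodes with a
    warning.  Degrees are those within the subgraph.
    """
    seeds = list(dict.fromkeys(seeds))
    if not seeds:
        raise ValueError("seeds must be non-empty")
    nodes: set[str] = set()
    for seed in seeds:
        nodes.add(seed)
        if seed in interactions:
            nodes.update(interactions.neighbors(seed))
        else:
            logger.warning("seed %r not in interaction table; kept as isolated node", seed)
    sub = nx.Graph(interactions.subgraph(n for n in nodes if n in interactions))
    sub.add_nodes_from(nodes)
    return sub


def degree_table(graph: nx.Graph) -> pd.DataFrame:
    """Node degrees sorted descending (hubs first), ties by name."""
    rows = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["gene", "degree"]).set_index("gene")


@dataclass
class EnrichmentRecord:
    """One term's over-representation result."""

    term: str
    k: int  # query genes annotated to the term
    n: int  # query genes with any annotation
    K: int  # background genes annotated to the term
    N: int  # annotated background size
    p: float
    p_bh: float = float("nan")

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n

    @property
    def bg_ratio(self) -> float:
        return self.K / self.N

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_bh <= alpha


def enrich(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str] | None = None,
) -> list[EnrichmentRecord]:
    """Hypergeometric ORA of ``query`` against every term with overlap ≥ 1.

    The background universe defaults to all genes appearing in the annotation;
    an explicit background is intersected with the annotated genes.  Terms
    with k = 0 are not emitted, and the BH family is the set of emitted terms.
    Records are sorted by adjusted then raw p.
    """
    sets = {term: set(genes) for term, genes in gene_sets.items()}
    if not sets:
        raise ValueError("need at least one gene set")
    annotated = set().union(*sets.values())
    universe = annotated if background is None else set(background) & annotated
    if not universe:
        raise ValueError("empty background universe")
    query = set(query) & universe
    n = len(query)
    N = len(universe)

    records: list[EnrichmentRecord] = []
    for term, genes in sets.items():
        members = genes & universe
        k = len(query & members)
        if k == 0:
            continue
        K = len(members)
        # upper tail: P(X ≥ k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        records.append(EnrichmentRecord(term=term, k=k, n=n, K=K, N=N, p=min(p, 1.0)))
    if records:
        adj = bh_adjust(np.array([r.p for r in records]))
        for rec, q in zip(records, adj):
            rec.p_bh = float(q)
    records.sort(key=lambda r: (r.p_bh, r.p, r.term))
    return records


def enrichment_table(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    """Tabular view mirroring the usual ORA report columns."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "GeneRatio": r.gene_ratio,
                "BgRatio": r.bg_ratio,
                "p": r.p,
                "p_bh": r.p_bh,
            }
            for r in records
        ]
    )


def log2fc_filter(values: Mapping[str, float]) -> tuple[set[str], set[str]]:
    """Split genes by log2 fold change: up = {> 1}, down = {< −1}.

    Boundary values (exactly ±1) are excluded on both sides; non-finite
    values are an error.
    """
    for gene, v in values.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite log2FC for {gene!r}")
    up = {g for g, v in values.items() if v > 1.0}
    down = {g for g, v in values.items() if v < -1.0}
    return up, down
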