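"""Hub-gene selection by network degree and hypergeometric gene-set enrichment.

The interaction network is any user-supplied undirected edge list (e.g., a
pre-exported protein-protein interaction download); no database access
happens here.  Hub genes are the highest-degree nodes of the subgraph
induced on a query gene list — degree is the documented hub criterion, with
ties broken lexicographically by gene id so ranks are reproducible.

Over-representation of a query list in named gene sets uses the upper-tail
hypergeometric test against an explicit background universe (typically the
expressed genes), with Benjamini–Hochberg adjustment across sets.
"""

from __future__ import annotations

import logging
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UsageError
from .io import EdgeList, GeneSetCollection

logger = logging.getLogger(__name__)


def hub_genes(edges: EdgeList, query: Sequence[str], k: int = 10) -> pd.DataFrame:
    """Top-k genes of the query-induced subgraph, ranked by degree.

    Returns a DataFrame with columns ``gene_id``, ``degree``, ``rank``
    (1-based; ties broken lexicographically).  An empty induced subgraph
    returns an empty frame with a logged warning.
    """
    if k < 1:
        raise UsageError("k must be >= 1")
    graph = nx.Graph()
    graph.add_edges_from(edges.pairs)
    nodes = set(query) & set(graph.nodes)
    sub = graph.subgraph(nodes)
    if sub.number_of_nodes() == 0:
        logger.warning("query induces an empty subgraph; no hub genes")
        return pd.DataFrame(columns=["gene_id", "degree", "rank"])
    ranked = sorted(sub.degree, key=lambda item: (-item[1], item[0]))[:k]
    return pd.DataFrame(
        {
            "gene_id": [g for g, _ in ranked],
            "degree": [int(d) for _, d in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )


def enrich(
    query: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    For a universe of N genes containing K members of a set, and a query of
    n genes overlapping the set in k, the p-value is the upper tail
    P(X >= k) of Hypergeometric(N, K, n) — with k = 0 included, so an empty
    overlap gives p = 1.  Query genes outside the universe are dropped with
    a logged count; set memberships are intersected with the universe.
    Rows are sorted by (p, set name); BH adjustment runs across sets.
    """
    universe_set = list(dict.fromkeys(universe))
    if not universe_set:
        raise UsageError("universe must be non-empty")
    uni = set(universe_set)
    query_unique = list(dict.fromkeys(query))
    dropped = [g for g in query_unique if g not in uni]
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", len(dropped))
    q = set(query_unique) & uni
    n, big_n = len(q), len(uni)
    rows = []
    for name, members in sets.sets.items():
        in_uni = [m for m in members if m in uni]
        overlap = sorted(q.intersection(in_uni))
        k, big_k = len(overlap), len(in_uni)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": big_k,
                "query_size": n,
                "universe_size": big_n,
                "p_value": min(p, 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        out["p_adjusted"] = []
    return out
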