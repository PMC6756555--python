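"""Post-switch analyses: gene-set enrichment, set overlaps, TF ranking.

Enrichment is a one-sided hypergeometric test of a query gene list against
GMT gene-set collections (an explicit stand-in for singular enrichment web
services; an optional EASE mode subtracts one from the overlap to match
DAVID's conservative score).  Overlaps between per-region switch lists are
reported both as pairwise totals (Venn semantics) and exclusive
intersections (UpSet semantics).  TF ranking builds the TF-to-target graph
induced by the query genes, after the BETA-minus edge filters, and orders
regulators by degree then betweenness centrality.
"""

from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust

logger = logging.getLogger(__name__)

#: BETA-minus retention bounds for TF->target edges
PEAK_INTENSITY_MAX = 500.0
REGULATORY_POTENTIAL_MAX = 1.0

TF_EDGE_COLUMNS = ["tf", "target", "peak_intensity", "regulatory_potential"]


class DownstreamError(ValueError):
    pass


# ------------------------------------------------------------------ gene sets

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DownstreamError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, _desc, *genes = fields
        genes = {g for g in genes if g}
        if not genes:
            raise DownstreamError(f"{path}:{lineno}: empty gene set {name!r}")
        sets[name] = genes
    if not sets:
        raise DownstreamError(f"{path}: no gene sets found")
    return sets


def hypergeometric_enrichment(
    query: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    p = P[overlap >= observed] drawing |query| genes from the universe;
    ``ease=True`` subtracts 1 from the observed overlap (EASE score).  FDR is
    BH-adjusted across sets; rows sorted by p then name, ``significant``
    flags p < alpha.
    """
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
    query &= universe
    if not query:
        raise DownstreamError("query is empty after intersecting with the universe")
    rows = []
    m_univ, n_query = len(universe), len(query)
    for name, genes in gene_sets.items():
        genes = genes & universe
        if not genes:
            continue
        overlap = len(query & genes)
        k_eff = max(overlap - 1, 0) if ease else overlap
        p = float(hypergeom.sf(k_eff - 1, m_univ, len(genes), n_query)) if k_eff > 0 else 1.0
        fold = (overlap / n_query) / (len(genes) / m_univ)
        rows.append((name, overlap, n_query, len(genes), m_univ, fold, min(p, 1.0)))
    table = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap_count", "query_size", "set_size",
            "universe_size", "fold_enrichment", "p_value",
        ],
    )
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["p_value"] < alpha
    return table.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)


# ------------------------------------------------------------------- overlaps

def overlap_counts(named_sets: dict[str, set[str]]) -> dict[str, pd.DataFrame]:
    """Overlaps among named gene sets, in both common bookkeepings.

    Returns ``{"exclusive": ..., "pairwise": ...}``: exclusive counts assign
    each element of the union to the single combination of sets containing it
    (UpSet semantics, all 2**n - 1 combinations reported); pairwise counts are
    plain intersection sizes |A & B| (Venn-label semantics).
    """
    if len(named_sets) < 2:
        raise DownstreamError("need at least 2 sets to compare")
    names = list(named_sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(
                *(named_sets[n] for n in names if n not in combo), set()
            )
            rows.append(("&".join(combo), len(combo), len(inside - outside)))
    exclusive = pd.DataFrame(rows, columns=["sets", "degree", "exclusive_count"])
    pair_rows = [
        (a, b, len(named_sets[a] & named_sets[b])) for a, b in combinations(names, 2)
    ]
    pairwise = pd.DataFrame(pair_rows, columns=["set_a", "set_b", "overlap"])
    return {"exclusive": exclusive, "pairwise": pairwise}


# ------------------------------------------------------------------ TF ranking

def read_tf_edges(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return _check_tf_schema(table)


def _check_tf_schema(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TF_EDGE_COLUMNS if c not in table.columns]
    if missing:
        raise DownstreamError(f"TF edge table missing columns: {missing}")
    return table


def filter_tf_edges(table: pd.DataFrame) -> pd.DataFrame:
    """BETA-minus retention: peak intensity < 500 and regulatory potential < 1
    (both strict); duplicate (tf, target) pairs collapsed."""
    table = _check_tf_schema(table)
    kept = table[
        (table["peak_intensity"] < PEAK_INTENSITY_MAX)
        & (table["regulatory_potential"] < REGULATORY_POTENTIAL_MAX)
    ]
    return kept.drop_duplicates(subset=["tf", "target"]).reset_index(drop=True)


def rank_tfs(edges: pd.DataFrame, query: set[str] | list[str]) -> pd.DataFrame:
    """Rank transcription factors over the TF-target graph induced by ``query``.

    Degree = number of distinct query-gene targets; betweenness is computed on
    the induced bipartite graph.  Order: degree desc, betweenness desc, then
    symbol; ranks are 1..n.
    """
    query = set(query)
    if not query:
        raise DownstreamError("query gene set is empty")
    edges = _check_tf_schema(edges)
    hits = edges[edges["target"].isin(query)]
    if hits.empty:
        logger.warning("no TF edges touch the query genes; empty ranking")
        return pd.DataFrame(columns=["tf", "degree", "betweenness", "rank"])
    g = nx.Graph()
    for tf, target in hits[["tf", "target"]].itertuples(index=False):
        g.add_edge(f"TF::{tf}", f"G::{target}")
    btw = nx.betweenness_centrality(g, normalized=True)
    tfs = sorted({tf for tf in hits["tf"]})
    table = pd.DataFrame(
        {
            "tf": tfs,
            "degree": [g.degree(f"TF::{t}") for t in tfs],
            "betweenness": [btw[f"TF::{t}"] for t in tfs],
        }
    )
    table = table.sort_values(
        ["degree", "betweenness", "tf"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
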