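"""Signed co-expression network, k-means communities and heat cartography.

The network is built from pooled-sample Pearson correlations (both groups
together, which is what makes case-vs-control anti-correlation visible as
negative edges).  Communities come from k-means on per-gene z-scored profiles
with the community count chosen from an SSE scree.  Each node then gets the
heat-cartography coordinates:

* ``zg`` — within-module degree z-score: the node's link count into its own
  community, standardized (population SD) against its community;
* ``kpi`` — clusterphobic coefficient ``1 - (kappa_in / k)**2``, 0 when all
  links are internal and approaching 1 as links become external;
* ``apcc`` — average (signed) Pearson correlation with the node's neighbors.

Switch genes are the nodes with ``zg < 2.5``, ``kpi > 0.8`` and ``apcc < 0``:
non-hubs of their own cluster, connected mainly outside it, anti-correlated
with their partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

CARTOGRAPHY_COLUMNS = [
    "community", "zg", "kpi", "apcc", "region", "hub_class", "is_hub", "is_switch",
]


class NetworkError(ValueError):
    pass


@dataclass
class CorrelationNetwork:
    """Signed weighted co-expression graph over retained genes."""

    graph: nx.Graph
    r_threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b, d["weight"]) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "r"])


@dataclass
class CommunityAssignment:
    """k-means community labels plus the SSE scree used to choose k."""

    labels: dict[str, int]  # node -> community index in 1..k
    k: int
    scree: list[tuple[int, float]]
    n_replicates: int
    seed: int

    def members(self, community: int) -> list[str]:
        return [n for n, c in self.labels.items() if c == community]


@dataclass(frozen=True)
class CartographyThresholds:
    """Boundaries of the (kpi, zg) role plane and the hub taxonomy."""

    zg_switch_max: float = 2.5
    kpi_switch_min: float = 0.8
    zg_hub: float = 5.0
    party_apcc_min: float = 0.5
    kpi_breaks: tuple[float, float, float] = (0.3, 0.6, 0.8)


def pearson_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Pearson correlation across pooled samples."""
    r = np.corrcoef(m.values.to_numpy())
    return pd.DataFrame(r, index=m.values.index, columns=m.values.index)


def permutation_r_threshold(
    m: ExpressionMatrix,
    seed: int,
    n_pairs: int = 10_000,
    percentile: float = 99.9,
) -> float:
    """Data-driven edge threshold: the ``percentile``-th percentile of |r| over
    ``n_pairs`` random gene pairs after independently permuting one profile of
    each pair (destroys real co-expression, preserves marginals)."""
    rng = np.random.default_rng(seed)
    x = m.values.to_numpy()
    n_genes, n_samples = x.shape
    if n_genes < 2:
        raise NetworkError("need at least 2 genes for permutation thresholding")
    i = rng.integers(0, n_genes, size=n_pairs)
    j = rng.integers(0, n_genes, size=n_pairs)
    a = rng.permuted(x[i], axis=1)
    b = x[j]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(axis=1) / denom, 0.0)
    return float(np.percentile(np.abs(r), percentile))


def build_correlation_network(
    m: ExpressionMatrix,
    r_threshold: float,
) -> CorrelationNetwork:
    """Keep every gene pair with ``|r| >= r_threshold`` as a signed edge;
    isolated nodes are dropped (and logged)."""
    if not 0 < r_threshold < 1:
        raise NetworkError(f"r_threshold must be in (0, 1), got {r_threshold}")
    if m.n_genes < 3:
        raise NetworkError("need at least 3 genes to build a network")
    if m.n_samples < 4:
        raise NetworkError("need at least 4 samples to build a network")
    variances = m.values.var(axis=1)
    zero_var = list(variances.index[variances == 0])
    if zero_var:
        logger.warning("excluding %d zero-variance genes: %s ...", len(zero_var), zero_var[:5])
        m = ExpressionMatrix(m.values.drop(index=zero_var), m.groups.copy())
    corr = pearson_matrix(m).to_numpy()
    genes = m.gene_ids
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = np.abs(corr[iu, ju]) >= r_threshold
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_weighted_edges_from(
        (genes[a], genes[b], float(corr[a, b]))
        for a, b in zip(iu[keep], ju[keep])
    )
    if g.number_of_edges() == 0:
        raise NetworkError(
            f"no gene pair reaches |r| >= {r_threshold}; lower the correlation threshold"
        )
    isolated = [n for n, d in g.degree() if d == 0]
    if isolated:
        logger.info("dropping %d isolated nodes", len(isolated))
        g.remove_nodes_from(isolated)
    return CorrelationNetwork(g, r_threshold)


def kmeans_communities(
    m: ExpressionMatrix,
    net: CorrelationNetwork,
    k_range: range | list[int] = range(2, 16),
    n_replicates: int = 100,
    seed: int = 0,
    sse_drop_tol: float = 0.05,
    k_override: int | None = None,
) -> CommunityAssignment:
    """Cluster network nodes by k-means on z-scored expression profiles.

    For every candidate k the clustering is restarted ``n_replicates`` times
    from fresh centroids and the lowest-SSE replicate kept; the community
    count is the scree elbow — the smallest k whose relative SSE drop to k+1
    falls below ``sse_drop_tol`` — unless ``k_override`` is given.
    """
    nodes = net.nodes
    k_range = [int(k) for k in k_range]
    if not k_range or min(k_range) < 2 or max(k_range) > len(nodes) - 1:
        raise NetworkError(
            f"k_range must be non-empty and within [2, {len(nodes) - 1}], got {k_range}"
        )
    x = m.restrict_genes(nodes).values.to_numpy()
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd

    scree: list[tuple[int, float]] = []
    best_labels: dict[int, np.ndarray] = {}
    for k in sorted(k_range):
        km = KMeans(
            n_clusters=k,
            n_init=n_replicates,
            init="random",
            random_state=seed % (2**32),
            algorithm="lloyd",
        ).fit(z)
        scree.append((k, float(km.inertia_)))
        best_labels[k] = km.labels_

    chosen = k_override if k_override is not None else _scree_elbow(scree, sse_drop_tol)
    if chosen not in best_labels:
        raise NetworkError(f"k_override {chosen} outside k_range {k_range}")
    labels = {node: int(lbl) + 1 for node, lbl in zip(nodes, best_labels[chosen])}
    return CommunityAssignment(labels, chosen, scree, n_replicates, seed)


def _scree_elbow(scree: list[tuple[int, float]], drop_tol: float) -> int:
    """Smallest k whose relative SSE improvement to the next k is below tol."""
    for (k, sse), (_k2, sse2) in zip(scree, scree[1:]):
        if sse <= 0:
            return k
        if (sse - sse2) / sse < drop_tol:
            return k
    return scree[-1][0]


def compute_cartography(
    net: CorrelationNetwork,
    comm: CommunityAssignment,
    m: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Per-node ``community``, ``zg``, ``kpi`` and ``apcc``.

    APCC is read off the signed edge weights (each weight is the Pearson r
    between the node and that neighbor); ``m`` is accepted for interface
    symmetry but not needed.
    """
    g = net.graph
    missing = [n for n in g.nodes if n not in comm.labels]
    if missing:
        raise NetworkError(f"nodes without community assignment: {missing[:5]}")
    nodes = sorted(g.nodes)
    community = np.array([comm.labels[n] for n in nodes])
    kappa_in = np.array(
        [
            sum(1 for nb in g.neighbors(n) if comm.labels[nb] == comm.labels[n])
            for n in nodes
        ],
        dtype=float,
    )
    degree = np.array([g.degree(n) for n in nodes], dtype=float)
    if (degree == 0).any():
        raise NetworkError("every node must have at least one neighbor")

    zg = np.zeros(len(nodes))
    for c in np.unique(community):
        idx = community == c
        mu, sd = kappa_in[idx].mean(), kappa_in[idx].std()  # population sd
        zg[idx] = 0.0 if sd == 0 else (kappa_in[idx] - mu) / sd
    kpi = 1.0 - (kappa_in / degree) ** 2
    apcc = np.array(
        [np.mean([g[n][nb]["weight"] for nb in g.neighbors(n)]) for n in nodes]
    )
    return pd.DataFrame(
        {"community": community, "zg": zg, "kpi": kpi, "apcc": apcc},
        index=pd.Index(nodes, name="gene"),
    )


def classify_nodes(
    cart: pd.DataFrame,
    thresholds: CartographyThresholds = CartographyThresholds(),
) -> pd.DataFrame:
    """Fill ``region`` (R1–R7), ``hub_class``, ``is_hub`` and ``is_switch``.

    The hub taxonomy follows the APCC sign/magnitude: negative APCC makes a
    fight-club hub, APCC at or above ``party_apcc_min`` a party hub, the
    non-negative remainder date hubs.  ``is_hub`` marks local hubs
    (``zg > zg_hub``).  Switch genes are exactly the nodes with
    ``zg < zg_switch_max``, ``kpi > kpi_switch_min`` and ``apcc < 0``.
    """
    t = thresholds
    out = cart.copy()
    zg, kpi, apcc = out["zg"], out["kpi"], out["apcc"]

    b1, b2, b3 = t.kpi_breaks
    low = zg < t.zg_switch_max
    region = np.select(
        [
            low & (kpi <= b1),
            low & (kpi <= b2),
            low & (kpi <= b3),
            low,
            ~low & (kpi <= b1),
            ~low & (kpi <= b3),
        ],
        ["R1", "R2", "R3", "R4", "R5", "R6"],
        default="R7",
    )
    hub_class = np.select(
        [apcc < 0, apcc >= t.party_apcc_min],
        ["fight-club", "party"],
        default="date",
    )
    out["region"] = region
    out["hub_class"] = hub_class
    out["is_hub"] = zg > t.zg_hub
    out["is_switch"] = (zg < t.zg_switch_max) & (kpi > t.kpi_switch_min) & (apcc < 0)
    return out


def switch_genes(cart: pd.DataFrame) -> list[str]:
    """Sorted list of switch-gene ids from a classified cartography table."""
    return sorted(cart.index[cart["is_switch"]])
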