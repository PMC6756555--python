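"""Network robustness under cumulative, typed node removal.

After switch genes are called, the network's tolerance to their loss is
compared with the loss of hubs of each flavor and of random nodes: the same
number of nodes as there are switch genes is deleted in batches (within a
category, in decreasing-degree order) and the average shortest path is
recomputed after every batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .network import CorrelationNetwork

logger = logging.getLogger(__name__)

CATEGORIES = (
    "total hubs",
    "party hubs",
    "date hubs",
    "fight-club hubs",
    "switch genes",
    "random",
)


class RobustnessError(ValueError):
    pass


@dataclass
class RobustnessCurve:
    category: str
    points: list[tuple[float, float]]  # (fraction_removed, avg shortest path)
    n_random_repeats: int = 1
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.category,
                "fraction_removed": [p[0] for p in self.points],
                "avg_shortest_path": [p[1] for p in self.points],
            }
        )

    def auc(self) -> float:
        """Trapezoidal area under the curve over fraction removed."""
        xs = np.array([p[0] for p in self.points])
        ys = np.array([p[1] for p in self.points])
        return float(np.trapezoid(ys, xs))


def average_shortest_path(graph: nx.Graph | CorrelationNetwork) -> float:
    """Mean unweighted shortest-path length over all connected node pairs.

    Pairs in different components are excluded from the average, which keeps
    the statistic finite as removal fragments the graph; a graph with no
    connected pair (single node, edgeless) yields 0.
    """
    g = graph.graph if isinstance(graph, CorrelationNetwork) else graph
    n = g.number_of_nodes()
    if n == 0:
        raise RobustnessError("empty network")
    if n == 1 or g.number_of_edges() == 0:
        return 0.0
    adj = nx.to_scipy_sparse_array(g, weight=None, format="csr")
    dist = shortest_path(adj, unweighted=True, directed=False)
    finite = np.isfinite(dist) & ~np.eye(n, dtype=bool)
    if not finite.any():
        return 0.0
    return float(dist[finite].mean())


def _removal_order(members: list[str], graph: nx.Graph) -> list[str]:
    # decreasing degree, ties broken by node id for determinism
    return sorted(members, key=lambda n: (-graph.degree(n), n))


def _batch_sizes(total: int, n_steps: int) -> list[int]:
    n_steps = min(n_steps, total)
    base, extra = divmod(total, n_steps)
    return [base + (1 if i < extra else 0) for i in range(n_steps)]


def _curve_for_order(graph: nx.Graph, order: list[str], n_steps: int) -> list[tuple[float, float]]:
    n0 = graph.number_of_nodes()
    g = graph.copy()
    points = [(0.0, average_shortest_path(g))]
    removed = 0
    for size in _batch_sizes(len(order), n_steps):
        batch, order = order[:size], order[size:]
        g.remove_nodes_from(batch)
        removed += size
        points.append((removed / n0, average_shortest_path(g)))
    return points


def removal_curve(
    net: CorrelationNetwork,
    cart: pd.DataFrame,
    category: str,
    n_steps: int = 20,
    seed: int = 0,
    n_random_repeats: int = 20,
) -> RobustnessCurve:
    """Average-shortest-path curve under cumulative removal of one node type.

    The total number of removed nodes equals the number of switch genes;
    within a category nodes fall in decreasing-degree order.  The ``random``
    category removes uniformly drawn nodes and averages the curve over
    ``n_random_repeats`` draws (deterministic given ``seed``).
    """
    if category not in CATEGORIES:
        raise RobustnessError(f"unknown category {category!r}; one of {CATEGORIES}")
    if n_steps < 1:
        raise RobustnessError("n_steps must be >= 1")
    g = net.graph
    cart = cart.loc[[n for n in cart.index if n in g]]
    n_remove = int(cart["is_switch"].sum())
    if n_remove == 0:
        logger.warning("no switch genes in network; robustness curve is the baseline only")
        return RobustnessCurve(category, [(0.0, average_shortest_path(g))], seed=seed)

    if category == "random":
        rng = np.random.default_rng(seed)
        nodes = sorted(g.nodes)
        curves = []
        for _ in range(n_random_repeats):
            order = list(rng.choice(nodes, size=n_remove, replace=False))
            curves.append(_curve_for_order(g, order, n_steps))
        fractions = [p[0] for p in curves[0]]
        mean_asp = np.mean([[p[1] for p in c] for c in curves], axis=0)
        return RobustnessCurve(
            category,
            list(zip(fractions, mean_asp.tolist())),
            n_random_repeats=n_random_repeats,
            seed=seed,
        )

    members = _category_members(cart, category)
    if not members:
        logger.warning("category %r has no members; baseline only", category)
        return RobustnessCurve(category, [(0.0, average_shortest_path(g))], seed=seed)
    if len(members) < n_remove:
        logger.warning(
            "category %r has %d members; truncating removal to all of them",
            category, len(members),
        )
    order = _removal_order(members, g)[:n_remove]
    return RobustnessCurve(category, _curve_for_order(g, order, n_steps), seed=seed)


def _category_members(cart: pd.DataFrame, category: str) -> list[str]:
    if category == "total hubs":
        mask = cart["is_hub"]
    elif category == "switch genes":
        mask = cart["is_switch"]
    else:
        mask = cart["hub_class"] == category.removesuffix(" hubs")
    return list(cart.index[mask])


def all_removal_curves(
    net: CorrelationNetwork,
    cart: pd.DataFrame,
    n_steps: int = 20,
    seed: int = 0,
    n_random_repeats: int = 20,
) -> pd.DataFrame:
    """Long-format table of removal curves for every category."""
    frames = []
    for cat in CATEGORIES:
        curve = removal_curve(
            net, cart, cat, n_steps=n_steps, seed=seed, n_random_repeats=n_random_repeats
        )
        frames.append(curve.to_frame())
    return pd.concat(frames, ignore_index=True)
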