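"""End-to-end orchestration: expression -> differential -> network ->
cartography -> robustness, with a JSON run manifest for reproducibility.

One seed governs every stochastic stage; per-stage substreams are derived
from it with fixed labels (``kmeans``, ``permutation``, ``random_removal``)
so stages cannot perturb each other's draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import differential_table, select_genes
from .downstream import overlap_counts
from .expression import ExpressionMatrix, filter_low_expression
from .network import (
    CartographyThresholds,
    build_correlation_network,
    classify_nodes,
    compute_cartography,
    kmeans_communities,
    permutation_r_threshold,
    switch_genes,
)
from .robustness import all_removal_curves

logger = logging.getLogger(__name__)

_STAGE_LABELS = ("kmeans", "permutation", "random_removal")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage substream seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGE_LABELS))
    return {label: int(s % (2**31)) for label, s in zip(_STAGE_LABELS, state)}


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the package's reference
    settings (fold-change 2, FDR 0.05, permutation-derived edge threshold,
    k scanned over 2..15 with 100 k-means restarts)."""

    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    floor_percentile: float = 20.0
    r_threshold: float | str = "permutation"  # "permutation" or a fixed value
    k_min: int = 2
    k_max: int = 15
    n_replicates: int = 100
    k_override: int | None = None
    n_removal_steps: int = 20
    n_random_repeats: int = 20
    seed: int = 1
    thresholds: CartographyThresholds = field(default_factory=CartographyThresholds)

    def validate(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError(f"fc_threshold must be >= 1, got {self.fc_threshold}")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError(f"fdr_threshold must be in (0, 1], got {self.fdr_threshold}")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError(f"invalid k range [{self.k_min}, {self.k_max}]")
        if isinstance(self.r_threshold, str) and self.r_threshold != "permutation":
            raise ValueError(f"r_threshold must be 'permutation' or a number")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    differential: pd.DataFrame
    retained_genes: list[str]
    r_threshold: float
    edge_table: pd.DataFrame
    scree: list[tuple[int, float]]
    k: int
    cartography: pd.DataFrame
    robustness: pd.DataFrame
    switch_genes: list[str]
    manifest: dict


def run_pipeline(
    matrix: ExpressionMatrix,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full switch-gene discovery pipeline on one expression matrix.

    Stages: low-expression filter, differential filter (fold-change + FDR),
    signed Pearson network, k-means communities, heat cartography and switch
    calls, typed-removal robustness curves.  Identical matrix + config + seed
    give identical outputs.
    """
    config = config or RunConfig()
    config.validate()
    seeds = stage_seeds(config.seed)
    t0 = time.perf_counter()

    expressed = filter_low_expression(matrix, config.floor_percentile)
    dt = differential_table(expressed, config.fc_threshold, config.fdr_threshold)
    retained = select_genes(dt, config.fc_threshold, config.fdr_threshold)
    sub = expressed.restrict_genes(retained)

    if config.r_threshold == "permutation":
        r_thr = permutation_r_threshold(sub, seed=seeds["permutation"])
        logger.info("permutation-derived |r| threshold: %.4f", r_thr)
    else:
        r_thr = float(config.r_threshold)
    net = build_correlation_network(sub, r_thr)

    comm = kmeans_communities(
        sub,
        net,
        k_range=range(config.k_min, config.k_max + 1),
        n_replicates=config.n_replicates,
        seed=seeds["kmeans"],
        k_override=config.k_override,
    )
    cart = classify_nodes(compute_cartography(net, comm), config.thresholds)
    switches = switch_genes(cart)
    if not switches:
        logger.warning(
            "no switch genes found — consider lowering fc_threshold or the edge threshold"
        )
    curves = all_removal_curves(
        net,
        cart,
        n_steps=config.n_removal_steps,
        seed=seeds["random_removal"],
        n_random_repeats=config.n_random_repeats,
    )

    manifest = {
        "switchnet_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "counts": {
            "genes_in": matrix.n_genes,
            "samples": matrix.n_samples,
            "genes_expressed": expressed.n_genes,
            "genes_retained": len(retained),
            "network_nodes": net.graph.number_of_nodes(),
            "network_edges": net.graph.number_of_edges(),
            "communities": comm.k,
            "switch_genes": len(switches),
        },
        "r_threshold": r_thr,
        "runtime_s": round(time.perf_counter() - t0, 3),
    }
    result = PipelineResult(
        config=config,
        differential=dt,
        retained_genes=retained,
        r_threshold=r_thr,
        edge_table=net.edge_table(),
        scree=comm.scree,
        k=comm.k,
        cartography=cart,
        robustness=curves,
        switch_genes=switches,
        manifest=manifest,
    )
    if out_dir is not None:
        write_run(result, out_dir)
    return result


def write_run(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dt = result.differential.copy()
    dt.index.name = "gene"
    dt.to_csv(out / "differential.tsv", sep="\t", float_format="%.10g")
    result.edge_table.to_csv(
        out / "network_edges.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.DataFrame(result.scree, columns=["k", "sse"]).to_csv(
        out / "scree.tsv", sep="\t", index=False, float_format="%.10g"
    )
    cart = result.cartography.copy()
    cart.index.name = "gene"
    cart.to_csv(out / "cartography.tsv", sep="\t", float_format="%.10g")
    result.robustness.to_csv(
        out / "robustness.tsv", sep="\t", index=False, float_format="%.10g"
    )
    (out / "switch_genes.txt").write_text("".join(g + "\n" for g in result.switch_genes))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


def compare_regions(run_dirs: list[str | Path]) -> dict[str, pd.DataFrame]:
    """Overlap report over the switch-gene lists of several completed runs."""
    if len(run_dirs) < 2:
        raise ValueError("need at least 2 run directories to compare")
    sets: dict[str, set[str]] = {}
    for d in run_dirs:
        d = Path(d)
        path = d / "switch_genes.txt"
        if not path.exists():
            raise FileNotFoundError(f"run {d} has no switch_genes.txt")
        sets[d.name] = {line.strip() for line in path.read_text().splitlines() if line.strip()}
    return overlap_counts(sets)
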