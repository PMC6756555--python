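"""Synthetic two-group expression data with planted network structure.

The generator emulates a log2-intensity microarray experiment in which

* genes fall into correlated modules driven by per-sample latent factors,
* module members are differentially expressed between disease and control, and
* a set of planted "switch" genes is anti-correlated with every module.

Generative model (the documented contract of :func:`generate_dataset`):
for each module ``m`` a latent factor ``f_m ~ N(0, 1)`` is drawn per sample.

* module-member gene ``g`` in module ``m``:
  ``x = baseline_mean + loading * f_m + de_log2_effect * 1[disease] + eps``
* planted switch gene (no home module):
  ``x = baseline_mean - switch_negative_loading * sum_m f_m
  - de_log2_effect * 1[disease] + eps``
* background noise gene: ``x = baseline_mean + eps``

with ``eps ~ N(0, noise_sd)`` i.i.d. per gene and sample.  All module members
carry the disease shift (they are all differentially expressed), so whole
modules survive a fold-change filter; switch genes carry the shift in the
*opposite* direction, which both lets them pass the symmetric fold-change
filter and reinforces their anti-correlation with module members across the
pooled samples.  The single RNG stream is consumed in a documented order —
all module factors first, then per-gene noise — so adding genes to a spec
never perturbs the factor draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CONTROL, DISEASE, ExpressionMatrix


class SyntheticSpecError(ValueError):
    """A synthetic-data parameter is out of its valid range."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Defaults are the package's reference study conditions: 3 modules of 60
    genes, 10 switch genes, 50 background genes, 20 samples per group, a
    2-log2-unit disease shift, module loading 0.9, switch anti-loading 0.7,
    and noise SD 0.4 log2 units.
    """

    n_modules: int = 3
    genes_per_module: int = 60
    n_switch: int = 10
    n_noise_genes: int = 50
    n_samples_per_group: int = 20
    de_log2_effect: float = 2.0
    loading: float = 0.9
    switch_negative_loading: float = 0.7
    noise_sd: float = 0.4
    baseline_mean: float = 8.0
    seed: int = 1

    def __post_init__(self) -> None:
        def _require(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise SyntheticSpecError(f"{name}: {msg} (got {getattr(self, name)!r})")

        _require(self.n_modules >= 1, "n_modules", "must be a positive integer")
        _require(self.genes_per_module >= 1, "genes_per_module", "must be a positive integer")
        _require(self.n_switch >= 0, "n_switch", "must be non-negative")
        _require(self.n_noise_genes >= 0, "n_noise_genes", "must be non-negative")
        _require(self.n_samples_per_group >= 1, "n_samples_per_group", "must be positive")
        _require(self.de_log2_effect >= 0, "de_log2_effect", "must be non-negative")
        _require(0 < self.loading <= 1, "loading", "must be in (0, 1]")
        _require(
            0 < self.switch_negative_loading <= 1,
            "switch_negative_loading",
            "must be in (0, 1]",
        )
        _require(self.noise_sd >= 0, "noise_sd", "must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.n_modules * self.genes_per_module + self.n_switch + self.n_noise_genes


@dataclass
class PlantedTruth:
    """Ground-truth labels for a generated dataset."""

    module_of_gene: dict[str, int | None]
    de_genes: set[str] = field(default_factory=set)
    switch_genes: set[str] = field(default_factory=set)
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_of_gene": self.module_of_gene,
            "de_genes": sorted(self.de_genes),
            "switch_genes": sorted(self.switch_genes),
            "spec": asdict(self.spec),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            module_of_gene=payload["module_of_gene"],
            de_genes=set(payload["de_genes"]),
            switch_genes=set(payload["switch_genes"]),
            spec=SyntheticSpec(**payload["spec"]),
        )


def _gene_ids(spec: SyntheticSpec) -> tuple[list[str], dict[str, int | None], list[str], list[str]]:
    module_of: dict[str, int | None] = {}
    module_genes: list[str] = []
    for m in range(spec.n_modules):
        for g in range(spec.genes_per_module):
            gid = f"M{m + 1}_G{g + 1:03d}"
            module_of[gid] = m
            module_genes.append(gid)
    switch_genes = [f"SW_{s + 1:02d}" for s in range(spec.n_switch)]
    noise_genes = [f"BG_{b + 1:03d}" for b in range(spec.n_noise_genes)]
    for gid in switch_genes + noise_genes:
        module_of[gid] = None
    return module_genes + switch_genes + noise_genes, module_of, switch_genes, noise_genes


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Draw one dataset from the generative model; deterministic given ``spec.seed``.

    Returns the genes x (2 * n_samples_per_group) matrix (control samples
    first, then disease) and the planted truth labels.
    """
    rng = np.random.default_rng(spec.seed)
    n_per = spec.n_samples_per_group
    n_samples = 2 * n_per
    # RNG consumption order: (1) module factors, (2) gene noise, row by row.
    factors = rng.standard_normal((spec.n_modules, n_samples))
    gene_ids, module_of, switch_genes, noise_genes = _gene_ids(spec)
    noise = rng.standard_normal((spec.n_genes, n_samples)) * spec.noise_sd

    disease = np.zeros(n_samples)
    disease[n_per:] = 1.0
    x = np.full((spec.n_genes, n_samples), spec.baseline_mean)
    for i, gid in enumerate(gene_ids):
        m = module_of[gid]
        if m is not None:
            x[i] += spec.loading * factors[m] + spec.de_log2_effect * disease
        elif gid in set(switch_genes):
            x[i] += (
                -spec.switch_negative_loading * factors.sum(axis=0)
                - spec.de_log2_effect * disease
            )
    x += noise

    sample_ids = [f"CTRL_{j + 1:02d}" for j in range(n_per)] + [
        f"AD_{j + 1:02d}" for j in range(n_per)
    ]
    groups = pd.Series(
        [CONTROL] * n_per + [DISEASE] * n_per, index=sample_ids, dtype=object
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(x, index=pd.Index(gene_ids, name="gene"), columns=sample_ids),
        groups,
    )
    de_genes = {g for g, m in module_of.items() if m is not None} | set(switch_genes)
    truth = PlantedTruth(
        module_of_gene=dict(module_of),
        de_genes=de_genes,
        switch_genes=set(switch_genes),
        spec=spec,
    )
    return matrix, truth


def write_dataset(
    matrix: ExpressionMatrix,
    truth: PlantedTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write matrix TSV, sample-group TSV and truth JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "expression.tsv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.json",
    }
    matrix.to_tsv(paths["matrix"], paths["groups"])
    truth.to_json(paths["truth"])
    return paths
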