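"""Expression-matrix container and input/output.

Handles GEO series-matrix and plain TSV expression tables, probe-to-symbol
collapsing, and low-expression filtering.  Values are kept on the log2 scale
throughout; a heuristic (any value > 50) detects linear-scale input and applies
``log2(x + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE = "disease"
CONTROL = "control"

#: maximum plausible log2 intensity; anything above this is taken as linear scale
_LINEAR_SCALE_CUTOFF = 50.0


class ExpressionIOError(ValueError):
    """Malformed expression input (parse errors carry the offending line number)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-intensity matrix with a group label per sample.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    groups
        Mapping (or Series) sample id -> ``"disease"`` | ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate sample ids: {dupes[:5]}")
        if isinstance(self.groups, Mapping):
            self.groups = pd.Series(self.groups)
        if self.groups is None:
            raise ExpressionIOError("every sample needs a group label")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ExpressionIOError(f"samples without group label: {missing[:5]}")
        self.groups = self.groups.reindex(self.values.columns)
        bad = sorted(set(self.groups.unique()) - {DISEASE, CONTROL})
        if bad:
            raise ExpressionIOError(f"unknown group labels: {bad}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ExpressionIOError("matrix contains non-finite values")

    # ------------------------------------------------------------------ views
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix restricted to one group's samples."""
        return self.values[self.samples_in_group(group)]

    def restrict_genes(self, gene_ids) -> "ExpressionMatrix":
        """Sub-matrix with only the given genes, in their given order."""
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.groups.copy())

    # -------------------------------------------------------------------- io
    def to_tsv(self, path: str | Path, groups_path: str | Path | None = None) -> None:
        """Write the matrix as TSV (first column ``gene``), optionally plus a
        two-column sample/group TSV."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")
        if groups_path is not None:
            g = self.groups.rename("group").rename_axis("sample")
            g.to_csv(groups_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        groups: str | Path | Mapping[str, str] | pd.Series,
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        return cls(values, _load_groups(groups))


def _load_groups(groups) -> pd.Series:
    if isinstance(groups, pd.Series):
        return groups
    if isinstance(groups, Mapping):
        return pd.Series(groups)
    table = pd.read_csv(groups, sep="\t", index_col=0)
    return table.iloc[:, 0].astype(str)


# ---------------------------------------------------------------- series matrix

def read_series_matrix(
    path: str | Path,
    group_assignment: str | Path | Mapping[str, str] | pd.Series,
    scale: str = "auto",
) -> ExpressionMatrix:
    """Parse a GEO series-matrix file into an :class:`ExpressionMatrix`.

    Only the data block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is read; metadata headers are ignored.

    Parameters
    ----------
    scale
        ``"auto"`` (default): if any value exceeds 50 the matrix is taken to be
        on the linear scale and ``log2(x+1)`` is applied.  ``"log2"`` / ``"linear"``
        force the interpretation.
    """
    if scale not in ("auto", "log2", "linear"):
        raise ValueError(f"scale must be auto/log2/linear, got {scale!r}")
    path = Path(path)
    header: list[str] | None = None
    rows: list[list[str]] = []
    in_table = saw_end = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if line.lower().startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.lower().startswith("!series_matrix_table_end"):
                saw_end = True
                break
            if not in_table or not line:
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ExpressionIOError(
                    f"{path.name}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {len(header)})"
                )
            rows.append(fields)
    if header is None:
        raise ExpressionIOError(f"{path.name}: no !series_matrix_table_begin marker found")
    if not saw_end:
        raise ExpressionIOError(f"{path.name}: missing !series_matrix_table_end marker")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ExpressionIOError(f"{path.name}: duplicate sample ids in table header")
    values = pd.DataFrame(
        [[float(v) for v in r[1:]] for r in rows],
        index=pd.Index([r[0] for r in rows], name="gene"),
        columns=sample_ids,
        dtype=float,
    )
    groups = _load_groups(group_assignment)
    missing = [s for s in sample_ids if s not in groups.index]
    if missing:
        raise ExpressionIOError(f"samples absent from group assignment: {missing[:5]}")
    is_linear = scale == "linear" or (
        scale == "auto" and float(values.to_numpy().max()) > _LINEAR_SCALE_CUTOFF
    )
    if is_linear:
        logger.info("detected linear-scale values; applying log2(x+1)")
        values = np.log2(values + 1.0)
    return ExpressionMatrix(values, groups)


# ---------------------------------------------------------------- probe collapse

def collapse_probes(
    m: ExpressionMatrix,
    probe_map: Mapping[str, str],
    keep_unmapped: bool = False,
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    Among probes sharing a symbol the probe with the highest mean expression is
    kept (standard microarray convention).  Unmapped probes are dropped unless
    ``keep_unmapped``, in which case they are retained under their probe id.
    """
    mapped = [p for p in m.gene_ids if p in probe_map]
    if not mapped:
        raise ExpressionIOError("probe map covers no probes in the matrix")
    means = m.values.mean(axis=1)
    best: dict[str, str] = {}  # symbol -> winning probe
    for probe in mapped:
        sym = probe_map[probe]
        if sym not in best or means[probe] > means[best[sym]]:
            best[sym] = probe
    keep_rows, new_ids = [], []
    for probe in m.gene_ids:  # preserve input order
        if probe in probe_map:
            sym = probe_map[probe]
            if best[sym] == probe and sym not in new_ids:
                keep_rows.append(probe)
                new_ids.append(sym)
        elif keep_unmapped:
            keep_rows.append(probe)
            new_ids.append(probe)
    out = m.values.loc[keep_rows].copy()
    out.index = pd.Index(new_ids, name="gene")
    return ExpressionMatrix(out, m.groups.copy())


# ------------------------------------------------------------ expression filter

def filter_low_expression(m: ExpressionMatrix, floor_percentile: float = 20.0) -> ExpressionMatrix:
    """Drop genes that are not, or only slightly, expressed.

    A gene is removed when its maximum expression across samples falls below
    the ``floor_percentile``-th percentile of all matrix values.
    """
    if not 0 <= floor_percentile < 100:
        raise ValueError(f"floor_percentile must be in [0, 100), got {floor_percentile}")
    floor = float(np.percentile(m.values.to_numpy(), floor_percentile))
    keep = m.values.max(axis=1) >= floor
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ExpressionIOError(
            f"expression filter at percentile {floor_percentile} removed all genes; "
            "lower expression.floor_percentile"
        )
    logger.info("expression filter removed %d of %d genes", n_removed, m.n_genes)
    return ExpressionMatrix(m.values.loc[keep], m.groups.copy())
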