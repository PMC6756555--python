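"""Group means, fold-change, Welch p-values, BH-FDR and gene retention.

These are the filtering steps applied before any network is built: genes are
kept only when both the magnitude of their linear fold-change and their FDR
clear user thresholds.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import CONTROL, DISEASE, ExpressionMatrix

logger = logging.getLogger(__name__)

COLUMNS = ["mean_disease", "mean_control", "linear_fc", "p_value", "fdr", "retained"]


class DifferentialError(ValueError):
    pass


def _check_group_sizes(m: ExpressionMatrix) -> None:
    for grp in (DISEASE, CONTROL):
        n = len(m.samples_in_group(grp))
        if n < 2:
            raise DifferentialError(f"group {grp!r} has {n} samples; need at least 2")


def group_stats(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene group means (log2) and linear fold-change ``2**(mean_d - mean_c)``.

    Up/down symmetry is handled at filter time via ``max(fc, 1/fc)``.
    """
    _check_group_sizes(m)
    mean_d = m.group_values(DISEASE).mean(axis=1)
    mean_c = m.group_values(CONTROL).mean(axis=1)
    return pd.DataFrame(
        {
            "mean_disease": mean_d,
            "mean_control": mean_c,
            "linear_fc": np.power(2.0, mean_d - mean_c),
        }
    )


def welch_pvalues(m: ExpressionMatrix) -> pd.Series:
    """Two-sided Welch (unequal-variance) t-test per gene on log2 values.

    Convention for degenerate genes with zero variance in both groups:
    equal group means -> p = 1; unequal means -> p = 0.
    """
    _check_group_sizes(m)
    d = m.group_values(DISEASE).to_numpy()
    c = m.group_values(CONTROL).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(d, c, axis=1, equal_var=False).pvalue
    zero_var = (d.var(axis=1) == 0) & (c.var(axis=1) == 0)
    equal_means = d.mean(axis=1) == c.mean(axis=1)
    p = np.where(zero_var, np.where(equal_means, 1.0, 0.0), p)
    # t = 0 with well-defined variance yields p = 1 from scipy already
    return pd.Series(np.clip(p, 0.0, 1.0), index=m.values.index, name="p_value")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1, original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DifferentialError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    m: ExpressionMatrix,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full differential table: means, fold-change, p, FDR and retained flag."""
    dt = group_stats(m)
    dt["p_value"] = welch_pvalues(m)
    dt["fdr"] = bh_adjust(dt["p_value"].to_numpy())
    dt["retained"] = _retained_mask(dt, fc_threshold, fdr_threshold)
    return dt


def _retained_mask(dt: pd.DataFrame, fc_threshold: float, fdr_threshold: float) -> pd.Series:
    if fc_threshold < 1:
        raise DifferentialError(f"fc_threshold must be >= 1, got {fc_threshold}")
    if not 0 < fdr_threshold <= 1:
        raise DifferentialError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    fc = dt["linear_fc"]
    sym_fc = np.maximum(fc, 1.0 / fc)
    return (sym_fc >= fc_threshold) & (dt["fdr"] <= fdr_threshold)


def select_genes(
    dt: pd.DataFrame,
    fc_threshold: float,
    fdr_threshold: float,
) -> list[str]:
    """Genes passing the symmetric fold-change and FDR thresholds, order preserved."""
    mask = _retained_mask(dt, fc_threshold, fdr_threshold)
    retained = list(dt.index[mask])
    logger.info(
        "retained %d of %d genes at fc>=%g, fdr<=%g",
        len(retained), len(dt), fc_threshold, fdr_threshold,
    )
    if not retained:
        raise DifferentialError(
            "no genes pass the differential filter; consider lowering fc_threshold "
            "or raising fdr_threshold"
        )
    return retained
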