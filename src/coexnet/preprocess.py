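"""Reduce a probe- or gene-level matrix to the analysis gene set.

Mirrors a standard microarray preprocessing chain: collapse probe sets that
map to the same gene (arithmetic mean), express signals as (log2) ratios to a
control, keep genes that differ between the two conditions by a Welch t-test,
and finally restrict to the most connected genes for module detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError

__all__ = [
    "FilterReport",
    "collapse_probes",
    "ratio_to_control",
    "filter_by_ttest",
    "select_most_connected",
]


@dataclass
class FilterReport:
    """Outcome of the differential-expression gene filter."""

    n_input_genes: int
    n_retained: int
    alpha: float
    p_values: pd.Series


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Average the rows of probes mapping to the same gene.

    Probes absent from ``probe_map`` are dropped with a warning.  Output rows
    are ordered lexicographically by gene ID.
    """
    probe_map = dict(probe_map)
    mapped = [p for p in probe_matrix.index if p in probe_map]
    n_dropped = probe_matrix.shape[0] - len(mapped)
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} probes absent from the probe map", stacklevel=2)
    if not mapped:
        raise InputError("no probe IDs in the matrix are present in the probe map")
    genes = pd.Series({p: probe_map[p] for p in mapped}, name="gene_id")
    collapsed = probe_matrix.loc[mapped].groupby(genes).mean()
    collapsed = collapsed.sort_index()
    collapsed.index.name = "gene_id"
    return collapsed


def ratio_to_control(
    signal_matrix: pd.DataFrame, control_vector: pd.Series, log2: bool = True
) -> pd.DataFrame:
    """Per-gene ratio of each sample's signal to the control signal.

    ``control_vector`` must be strictly positive for every gene; with
    ``log2=True`` (default) the ratios are log2-transformed, putting the
    matrix on the centred log-ratio scale used for correlation networks.
    """
    control = control_vector.reindex(signal_matrix.index)
    bad = control.index[~(control > 0) | control.isna()]
    if len(bad):
        raise InputError(
            f"control signal must be strictly positive; offending genes: {list(bad[:5])}"
        )
    ratios = signal_matrix.div(control, axis=0)
    return np.log2(ratios) if log2 else ratios


def _welch_by_gene(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t, p = stats.ttest_ind(a.to_numpy(), b.to_numpy(), axis=1, equal_var=False)
    return np.asarray(t), np.asarray(p)


def filter_by_ttest(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], FilterReport]:
    """Keep genes whose expression differs between conditions (Welch t-test).

    Both matrices must share gene IDs; the test is two-sided, unequal
    variance, pooling all samples per condition.  Returns the retained gene
    IDs (input order) and a :class:`FilterReport` with all p-values.  No
    multiple-testing correction is applied: the raw ``p < alpha`` rule is the
    published filter.
    """
    if list(matrix_a.index) != list(matrix_b.index):
        common = matrix_a.index.intersection(matrix_b.index)
        if len(common) == 0:
            raise InputError("matrices share no gene IDs")
        matrix_a, matrix_b = matrix_a.loc[common], matrix_b.loc[common]
    if matrix_a.shape[1] < 2 or matrix_b.shape[1] < 2:
        raise InputError("need at least 2 samples per condition for the t-test")
    _, p = _welch_by_gene(matrix_a, matrix_b)
    p_series = pd.Series(p, index=matrix_a.index, name="p_value")
    keep = p_series.index[np.nan_to_num(p, nan=1.0) < alpha].tolist()
    report = FilterReport(
        n_input_genes=matrix_a.shape[0],
        n_retained=len(keep),
        alpha=alpha,
        p_values=p_series,
    )
    return keep, report


def select_most_connected(
    expr_matrix: pd.DataFrame, power: int = 6, k_target: int | None = None
) -> list[str]:
    """Return the ``k_target`` genes with highest whole-network connectivity.

    Connectivity is k_i = sum_{j != i} |cor(i, j)|^power on the supplied
    matrix.  Ties are broken by descending k then lexicographic gene ID, so
    the selection is deterministic.
    """
    n_genes = expr_matrix.shape[0]
    if k_target is None:
        k_target = n_genes
    if k_target > n_genes:
        raise InputError(f"k_target={k_target} exceeds the {n_genes} available genes")
    x = expr_matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = expr_matrix.index[sd == 0]
        raise InputError(f"constant expression rows: {list(bad[:5])}")
    corr = np.corrcoef(x)
    adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    order = sorted(range(n_genes), key=lambda i: (-k[i], str(expr_matrix.index[i])))
    chosen = sorted(order[:k_target])
    return [expr_matrix.index[i] for i in chosen]
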