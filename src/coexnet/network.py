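"""Weighted co-expression network construction for one condition.

Pipeline: Pearson correlation of all gene pairs -> unsigned power adjacency
a_ij = |r_ij|^beta -> topological overlap

    t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,   k_i = sum_{j != i} a_ij,

where the soft-threshold exponent beta is either fixed (default 6) or chosen
as the smallest power whose connectivity distribution satisfies the
scale-free topology criterion (log-log linearity of p(k) vs k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateFitError, InputError

__all__ = [
    "GeneNetwork",
    "ScaleFreeFit",
    "pearson_correlation_matrix",
    "adjacency_from_correlation",
    "topological_overlap",
    "scale_free_fit",
    "pick_soft_threshold",
    "build_network",
]

_SYM_TOL = 1e-10


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit for one candidate soft power."""

    power: int
    r_squared: float
    slope: float


@dataclass
class GeneNetwork:
    """Correlation, adjacency (connection strength) and TOM for one condition."""

    gene_ids: list[str]
    correlation: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    soft_power: int

    @property
    def connectivity(self) -> pd.Series:
        """Whole-network connectivity k_i (adjacency row sums, self excluded)."""
        return self.adjacency.sum(axis=1).rename("k")


def _as_frame(matrix: np.ndarray, index) -> pd.DataFrame:
    return pd.DataFrame(matrix, index=index, columns=index)


def pearson_correlation_matrix(expr_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of gene expression profiles (rows)."""
    if expr_matrix.shape[1] < 3:
        raise InputError("need at least 3 samples to correlate gene profiles")
    x = expr_matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = expr_matrix.index[sd == 0]
        raise InputError(f"constant expression rows cannot be correlated: {list(bad[:5])}")
    corr = np.corrcoef(x)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return _as_frame(corr, expr_matrix.index)


def adjacency_from_correlation(correlation: pd.DataFrame, power: int) -> pd.DataFrame:
    """Unsigned power adjacency a_ij = |r_ij|^power with zero diagonal."""
    if int(power) != power or power < 1:
        raise InputError(f"soft power must be a positive integer, got {power!r}")
    adj = np.abs(correlation.to_numpy(dtype=float)) ** int(power)
    np.fill_diagonal(adj, 0.0)
    return _as_frame(adj, correlation.index)


def _validate_adjacency(adj: np.ndarray) -> None:
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise InputError("adjacency must be a square matrix")
    if not np.allclose(adj, adj.T, atol=_SYM_TOL):
        raise InputError("adjacency must be symmetric")
    if adj.min() < -_SYM_TOL or adj.max() > 1.0 + _SYM_TOL:
        raise InputError("adjacency entries must lie in [0, 1]")
    if np.abs(np.diag(adj)).max() > _SYM_TOL:
        raise InputError("adjacency diagonal must be zero")


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency with zero diagonal.

    t_ij combines the direct connection strength a_ij with the strength of
    the genes' shared neighbours; t_ii = 1 by convention.
    """
    index = adjacency.index
    a = adjacency.to_numpy(dtype=float)
    _validate_adjacency(a)
    k = a.sum(axis=1)
    shared = a @ a  # zero diagonal excludes u = i and u = j from the sum
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return _as_frame(tom, index)


def scale_free_fit(connectivity: Sequence[float], n_bins: int = 10) -> ScaleFreeFit:
    """Fit log10 p(k) vs log10 k over equal-count connectivity bins.

    The connectivity vector is split into ``n_bins`` quantile bins; within
    each bin the empirical density (bin count / (N * bin width)) is regressed
    on the mean connectivity, both on log10 scales.  R^2 is forced to 0 when
    the slope is non-negative, since scale-free topology requires p(k) to
    decay with k.
    """
    k = np.asarray(list(connectivity), dtype=float)
    if k.size < 2 * n_bins:
        raise InputError(f"need at least {2 * n_bins} genes for {n_bins} bins, got {k.size}")
    if np.ptp(k) < 1e-12:
        raise DegenerateFitError("all connectivities are (numerically) equal")
    order = np.sort(k)
    chunks = np.array_split(order, n_bins)
    xs, ys = [], []
    n = k.size
    for chunk in chunks:
        width = chunk.max() - chunk.min()
        mean_k = chunk.mean()
        if width <= 0 or mean_k <= 0 or chunk.size == 0:
            continue  # ties or zero connectivity: bin carries no density information
        xs.append(np.log10(mean_k))
        ys.append(np.log10(chunk.size / (n * width)))
    if len(xs) < 3:
        raise DegenerateFitError("too few informative connectivity bins for a fit")
    fit = stats.linregress(xs, ys)
    r2 = float(fit.rvalue**2)
    slope = float(fit.slope)
    if slope >= 0:
        r2 = 0.0
    return ScaleFreeFit(power=0, r_squared=r2, slope=slope)


def pick_soft_threshold(
    expr_matrix: pd.DataFrame,
    candidate_powers: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.85,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest power meeting the scale-free topology criterion.

    Returns the selected power and a table of (power, r_squared, slope) for
    every candidate.  If no candidate reaches ``r2_target`` the power with
    the highest R^2 is returned with a warning.
    """
    candidates = [int(p) for p in candidate_powers]
    if not candidates:
        raise InputError("candidate_powers must be non-empty")
    if not (0 < r2_target <= 1) and r2_target != 0:
        raise InputError("r2_target must lie in [0, 1]")
    corr = pearson_correlation_matrix(expr_matrix)
    rows = []
    for p in candidates:
        adj = adjacency_from_correlation(corr, p)
        fit = scale_free_fit(adj.sum(axis=1).to_numpy(), n_bins=n_bins)
        rows.append({"power": p, "r_squared": fit.r_squared, "slope": fit.slope})
    fits = pd.DataFrame(rows).set_index("power")
    passing = fits.index[fits["r_squared"] >= r2_target]
    if len(passing):
        return int(passing[0]), fits
    best = int(fits["r_squared"].idxmax())
    warnings.warn(
        f"no candidate power reached R^2 >= {r2_target}; "
        f"using argmax power {best} (R^2 = {fits.loc[best, 'r_squared']:.3f})",
        stacklevel=2,
    )
    return best, fits


def build_network(expr_matrix: pd.DataFrame, power: int | str = 6, **pick_kwargs) -> GeneNetwork:
    """Construct the full GeneNetwork for one condition.

    ``power`` may be an integer soft threshold or ``"auto"`` to select it via
    the scale-free topology criterion.
    """
    if power == "auto":
        power, _ = pick_soft_threshold(expr_matrix, **pick_kwargs)
    corr = pearson_correlation_matrix(expr_matrix)
    adj = adjacency_from_correlation(corr, int(power))
    tom = topological_overlap(adj)
    return GeneNetwork(
        gene_ids=list(expr_matrix.index),
        correlation=corr,
        adjacency=adj,
        tom=tom,
        soft_power=int(power),
    )
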