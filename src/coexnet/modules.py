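"""Module detection: TOM clustering, dynamic tree cut, eigengenes and kME.

Genes are clustered by average-linkage (UPGMA) on the topological-overlap
dissimilarity 1 - TOM.  Branches of the dendrogram below a cut height become
modules via a dynamic tree cut: a branch is recursively split when a
sufficiently large sub-branch is markedly tighter than the merge that created
it, with the ``deep_split`` setting controlling how small a height gap
justifies a split.  Each module is summarized by its eigengene (first right
singular vector of the standardized module block), membership is measured by
kME (correlation of each gene with each eigengene), and genes are finally
reassigned to the module of maximal |kME|, with genes below ``kme_min`` for
every eigengene left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .exceptions import InputError

__all__ = [
    "UNASSIGNED",
    "ModulePartition",
    "ModuleEigengenes",
    "ReassignmentResult",
    "hierarchical_cluster",
    "dynamic_tree_cut",
    "module_eigengene",
    "module_eigengenes",
    "module_membership",
    "reassign_by_kme",
    "detect_modules",
]

UNASSIGNED = "unassigned"

# Color-style module labels in the field's conventional order (largest module
# first); overflow falls back to module_<n>.
_MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
)

# deep_split -> minimal height gap (on the 1-TOM scale) between a branch's
# merge and a large sub-branch that triggers splitting; higher deep_split
# splits more aggressively.
_DEEP_SPLIT_GAP = {0: 0.25, 1: 0.15, 2: 0.10, 3: 0.05, 4: 0.02}


@dataclass
class ModulePartition:
    """Gene -> module label assignment plus dendrogram provenance."""

    labels: pd.Series
    linkage_matrix: Optional[np.ndarray] = None
    parameters: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list[str]:
        """Module labels, largest first, excluding the unassigned pool."""
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        return [str(m) for m in counts.sort_values(ascending=False).index]

    def genes_in(self, module_id: str) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()


@dataclass
class ModuleEigengenes:
    """Per-module eigengene profiles, variance explained, and the kME matrix."""

    eigengenes: pd.DataFrame  # modules x samples, unit-norm rows
    variance_explained: pd.Series
    kme: pd.DataFrame  # genes x modules


@dataclass
class ReassignmentResult:
    partition: ModulePartition
    eigengenes: ModuleEigengenes
    n_iterations: int
    objective_path: list[float]  # sum over genes of max |kME| per iteration


def hierarchical_cluster(dissimilarity: pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) merge tree of a dissimilarity matrix.

    Returns a scipy linkage matrix; a single gene yields an empty (0, 4)
    matrix.
    """
    d = dissimilarity.to_numpy(dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("dissimilarity must be a square matrix")
    if np.isnan(d).any():
        raise InputError("dissimilarity contains NaN entries")
    if not np.allclose(d, d.T, atol=1e-10):
        raise InputError("dissimilarity must be symmetric")
    if np.abs(np.diag(d)).max(initial=0.0) > 1e-10:
        raise InputError("dissimilarity diagonal must be zero")
    if d.shape[0] < 2:
        return np.empty((0, 4))
    condensed = squareform((d + d.T) / 2.0, checks=False)
    return linkage(condensed, method="average")


def _leaves_of(node: int, n: int, left: np.ndarray, right: np.ndarray) -> list[int]:
    out: list[int] = []
    stack = [node]
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.append(left[v - n])
            stack.append(right[v - n])
    return out


def dynamic_tree_cut(
    linkage_matrix: np.ndarray,
    gene_ids,
    deep_split: int = 2,
    cut_height: float = 0.995,
    min_module_size: int = 30,
) -> ModulePartition:
    """Cut a dendrogram into modules by recursive branch splitting.

    Merges above ``cut_height`` never join genes into a module.  Below it, a
    branch is split when one of its sub-branches of at least
    ``min_module_size`` genes sits at least a ``deep_split``-dependent height
    gap below the branch's own merge height; sub-branches too small to be
    modules become unassigned.  Remaining intact branches of sufficient size
    become modules, labelled by color in decreasing size order.
    """
    if not (0.0 < cut_height <= 1.0):
        raise InputError(f"cut_height must lie in (0, 1], got {cut_height}")
    if min_module_size < 3:
        raise InputError(f"min_module_size must be >= 3, got {min_module_size}")
    if deep_split not in _DEEP_SPLIT_GAP:
        raise InputError(f"deep_split must be in {sorted(_DEEP_SPLIT_GAP)}, got {deep_split}")
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    labels = pd.Series(UNASSIGNED, index=pd.Index(gene_ids, name="gene_id"), name="module")
    params = {
        "deep_split": deep_split,
        "cut_height": cut_height,
        "min_module_size": min_module_size,
    }
    if n < 2 or linkage_matrix.shape[0] == 0:
        return ModulePartition(labels=labels, linkage_matrix=linkage_matrix, parameters=params)
    if linkage_matrix.shape[0] != n - 1:
        raise InputError("linkage matrix does not match the number of genes")

    left = linkage_matrix[:, 0].astype(int)
    right = linkage_matrix[:, 1].astype(int)
    height = linkage_matrix[:, 2]
    size = np.ones(2 * n - 1, dtype=int)
    node_h = np.zeros(2 * n - 1)
    for i in range(n - 1):
        size[n + i] = size[left[i]] + size[right[i]]
        node_h[n + i] = height[i]

    gap_min = _DEEP_SPLIT_GAP[deep_split]
    modules: list[list[int]] = []
    root = 2 * n - 2
    stack = [root]
    while stack:
        node = stack.pop()
        if size[node] < min_module_size:
            continue  # leaves stay unassigned
        if node < n:
            continue
        children = (left[node - n], right[node - n])
        h = node_h[node]
        must_split = h > cut_height
        gap_split = any(
            size[c] >= min_module_size and (h - node_h[c]) >= gap_min for c in children
        )
        if must_split or gap_split:
            stack.extend(children)
        else:
            modules.append(_leaves_of(node, n, left, right))

    modules.sort(key=lambda lv: (-len(lv), min(lv)))
    for rank, leaves in enumerate(modules):
        name = _MODULE_COLORS[rank] if rank < len(_MODULE_COLORS) else f"module_{rank + 1}"
        labels.iloc[leaves] = name
    return ModulePartition(labels=labels, linkage_matrix=linkage_matrix, parameters=params)


def _standardize_rows(x: np.ndarray, gene_ids) -> np.ndarray:
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = [gene_ids[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise InputError(f"constant expression rows in module block: {bad}")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def module_eigengene(expr_submatrix: pd.DataFrame) -> tuple[np.ndarray, float]:
    """First right singular vector of a standardized module block.

    Returns ``(me, variance_explained)`` where ``me`` is the unit-norm
    sample-length eigengene, sign-oriented so that it correlates positively
    with the module's average standardized expression (ties broken toward
    the first gene).
    """
    if expr_submatrix.shape[0] < 2 or expr_submatrix.shape[1] < 2:
        raise InputError("module eigengene needs at least 2 genes and 2 samples")
    x = _standardize_rows(expr_submatrix.to_numpy(dtype=float), list(expr_submatrix.index))
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    me = vt[0]
    variance_explained = float(s[0] ** 2 / np.sum(s**2))
    orient = float(me @ x.mean(axis=0))
    if abs(orient) < 1e-12:
        orient = float(me @ x[0])
    if orient < 0:
        me = -me
    return me, variance_explained


def module_eigengenes(expr_matrix: pd.DataFrame, partition: ModulePartition) -> ModuleEigengenes:
    """Eigengene profile, variance explained and kME for every module."""
    profiles = {}
    var_exp = {}
    for m in partition.module_ids:
        genes = partition.genes_in(m)
        me, ve = module_eigengene(expr_matrix.loc[genes])
        profiles[m] = me
        var_exp[m] = ve
    if not profiles:
        raise InputError("partition contains no modules")
    me_df = pd.DataFrame(profiles, index=expr_matrix.columns).T
    me_df.index.name = "module"
    kme = module_membership(expr_matrix, me_df)
    return ModuleEigengenes(
        eigengenes=me_df,
        variance_explained=pd.Series(var_exp, name="variance_explained"),
        kme=kme,
    )


def module_membership(expr_matrix: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME matrix: Pearson correlation of every gene with every eigengene."""
    if list(expr_matrix.columns) != list(eigengenes.columns):
        raise InputError("expression matrix and eigengenes must share samples")
    x = expr_matrix.to_numpy(dtype=float)
    e = eigengenes.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=1, keepdims=True)
    x_sd = np.linalg.norm(xc, axis=1)
    e_sd = np.linalg.norm(ec, axis=1)
    if np.any(x_sd == 0) or np.any(e_sd == 0):
        raise InputError("constant profiles cannot be correlated for kME")
    kme = (xc @ ec.T) / np.outer(x_sd, e_sd)
    kme = np.clip(kme, -1.0, 1.0)
    return pd.DataFrame(kme, index=expr_matrix.index, columns=eigengenes.index)


def reassign_by_kme(
    expr_matrix: pd.DataFrame,
    partition: ModulePartition,
    kme_min: float = 0.3,
    max_iterations: int = 10,
) -> ReassignmentResult:
    """Iteratively reassign genes to the module of maximal |kME|.

    Genes whose |kME| is below ``kme_min`` for every eigengene become
    unassigned.  Assignment and eigengene recomputation alternate until the
    labels reach a fixed point or ``max_iterations`` is hit.  The module set
    is fixed by the input partition; modules left with fewer than two genes
    are dropped from subsequent eigengene computation.
    """
    current = partition.labels.copy()
    objective_path: list[float] = []
    eg: Optional[ModuleEigengenes] = None
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        work = ModulePartition(labels=current, linkage_matrix=partition.linkage_matrix)
        active = [m for m in work.module_ids if len(work.genes_in(m)) >= 2]
        if not active:
            raise InputError("reassignment lost all modules; nothing left to compute")
        trimmed = current.where(current.isin(active), UNASSIGNED)
        eg = module_eigengenes(expr_matrix, ModulePartition(labels=trimmed))
        abs_kme = eg.kme.abs()
        best = abs_kme.max(axis=1)
        objective_path.append(float(best.sum()))
        new = abs_kme.idxmax(axis=1).where(best >= kme_min, UNASSIGNED)
        new.name = current.name
        if new.equals(current):
            break
        current = new
    params = dict(partition.parameters)
    params.update({"kme_min": kme_min, "reassignment_iterations": n_iter})
    final = ModulePartition(
        labels=current, linkage_matrix=partition.linkage_matrix, parameters=params
    )
    assert eg is not None
    return ReassignmentResult(
        partition=final, eigengenes=eg, n_iterations=n_iter, objective_path=objective_path
    )


def detect_modules(
    expr_matrix: pd.DataFrame,
    tom: pd.DataFrame,
    deep_split: int = 2,
    cut_height: float = 0.995,
    min_module_size: int = 30,
    kme_min: float = 0.3,
) -> ReassignmentResult:
    """Full detection chain: cluster 1 - TOM, cut, and kME-reassign."""
    if list(expr_matrix.index) != list(tom.index):
        raise InputError("expression matrix and TOM must share gene IDs and order")
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    dissim = pd.DataFrame(d, index=tom.index, columns=tom.columns)
    z = hierarchical_cluster(dissim)
    partition = dynamic_tree_cut(
        z, tom.index, deep_split=deep_split, cut_height=cut_height,
        min_module_size=min_module_size,
    )
    if not partition.module_ids:
        return ReassignmentResult(
            partition=partition,
            eigengenes=ModuleEigengenes(
                eigengenes=pd.DataFrame(columns=expr_matrix.columns),
                variance_explained=pd.Series(dtype=float),
                kme=pd.DataFrame(index=expr_matrix.index),
            ),
            n_iterations=0,
            objective_path=[],
        )
    return reassign_by_kme(expr_matrix, partition, kme_min=kme_min)
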