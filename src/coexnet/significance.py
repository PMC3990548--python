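"""Gene significance, hub-gene calling and edge-list export.

Gene significance (GS) is the absolute Welch t-statistic of differential
expression between the two conditions — a trait-free measure of how strongly
a gene responds to the perturbation.  Hubs are the genes of maximal |kME|
within each module (GS breaks ties), and thresholded edge lists with node
attributes are exported for external network viewers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .modules import UNASSIGNED, ModulePartition

__all__ = ["HubCall", "gene_significance", "hub_genes", "export_edge_list"]


@dataclass
class HubCall:
    """The most central gene of one module."""

    module_id: str
    gene_id: str
    kme_own: float
    gs: float
    p_value: float
    runner_up: Optional[str]


def gene_significance(expr_test: pd.DataFrame, expr_ref: pd.DataFrame) -> pd.DataFrame:
    """Per-gene GS = |Welch t| between test and reference conditions.

    Returns a DataFrame indexed by gene with columns ``t``, ``GS`` and
    two-sided ``p_value``.
    """
    if list(expr_test.index) != list(expr_ref.index):
        common = expr_test.index.intersection(expr_ref.index)
        if len(common) == 0:
            raise InputError("conditions share no gene IDs")
        expr_test, expr_ref = expr_test.loc[common], expr_ref.loc[common]
    if expr_test.shape[1] < 2 or expr_ref.shape[1] < 2:
        raise InputError("need at least 2 samples per condition for gene significance")
    t, p = stats.ttest_ind(
        expr_test.to_numpy(), expr_ref.to_numpy(), axis=1, equal_var=False
    )
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    p = np.nan_to_num(np.asarray(p), nan=1.0)
    return pd.DataFrame(
        {"t": t, "GS": np.abs(t), "p_value": p}, index=expr_test.index
    )


def hub_genes(
    partition: ModulePartition, kme: pd.DataFrame, scores: pd.DataFrame
) -> list[HubCall]:
    """Call one hub per module: maximal |kME|, ties broken by GS then gene ID.

    ``kme`` is the gene x module membership matrix; ``scores`` must carry
    ``GS`` and ``p_value`` columns from :func:`gene_significance`.
    """
    calls: list[HubCall] = []
    for module_id in partition.module_ids:
        genes = [g for g in partition.genes_in(module_id) if g in kme.index]
        if not genes:
            warnings.warn(f"module {module_id!r} is empty; skipped", stacklevel=2)
            continue
        if module_id not in kme.columns:
            warnings.warn(f"module {module_id!r} has no kME column; skipped", stacklevel=2)
            continue
        ranked = sorted(
            genes,
            key=lambda g: (
                -abs(float(kme.loc[g, module_id])),
                -float(scores.loc[g, "GS"]) if g in scores.index else 0.0,
                str(g),
            ),
        )
        hub = ranked[0]
        calls.append(
            HubCall(
                module_id=module_id,
                gene_id=hub,
                kme_own=float(kme.loc[hub, module_id]),
                gs=float(scores.loc[hub, "GS"]) if hub in scores.index else float("nan"),
                p_value=float(scores.loc[hub, "p_value"]) if hub in scores.index else float("nan"),
                runner_up=ranked[1] if len(ranked) > 1 else None,
            )
        )
    return calls


def hub_table(calls: list[HubCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": c.module_id,
                "hub": c.gene_id,
                "kME": c.kme_own,
                "GS": c.gs,
                "p_value": c.p_value,
                "runner_up": c.runner_up,
            }
            for c in calls
        ],
        columns=["module", "hub", "kME", "GS", "p_value", "runner_up"],
    ).set_index("module")


def export_edge_list(
    weight_matrix: pd.DataFrame,
    threshold: float = 0.3,
    partition: Optional[ModulePartition] = None,
    module: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edges with weight strictly above ``threshold`` plus node attributes.

    Returns ``(edges, nodes)``: edges as (gene_a, gene_b, weight) with
    gene_a < gene_b, nodes with module label (if a partition is given) and
    connectivity (off-diagonal row sum of the weight matrix) — suitable for
    import into Cytoscape-style viewers where node size tracks connectivity.
    ``module`` restricts the export to one module's genes.
    """
    if not (0.0 <= threshold < 1.0):
        raise InputError(f"edge threshold must lie in [0, 1), got {threshold}")
    w = weight_matrix.to_numpy(dtype=float)
    if w.shape[0] != w.shape[1] or not np.allclose(w, w.T, atol=1e-10):
        raise InputError("weight matrix must be square and symmetric")
    if w.min() < -1e-10 or w.max() > 1.0 + 1e-10:
        raise InputError("weights must lie in [0, 1]")
    genes = list(weight_matrix.index)
    if module is not None:
        if partition is None:
            raise InputError("restricting to a module requires a partition")
        keep = set(partition.genes_in(module))
        sel = [g for g in genes if g in keep]
        weight_matrix = weight_matrix.loc[sel, sel]
        w = weight_matrix.to_numpy(dtype=float)
        genes = sel
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    connectivity = off.sum(axis=1)
    iu, ju = np.triu_indices(len(genes), k=1)
    mask = off[iu, ju] > threshold
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[mask]],
            "gene_b": [genes[j] for j in ju[mask]],
            "weight": off[iu[mask], ju[mask]],
        }
    )
    labels = (
        partition.labels.reindex(genes).fillna(UNASSIGNED)
        if partition is not None
        else pd.Series(UNASSIGNED, index=genes)
    )
    nodes = pd.DataFrame(
        {"gene_id": genes, "module": labels.to_numpy(), "connectivity": connectivity}
    ).set_index("gene_id")
    return edges, nodes
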