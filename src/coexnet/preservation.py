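"""Permutation-based module preservation between two networks.

A module detected in a *reference* network is preserved in a *test* network
when its genes remain densely interconnected there (density statistic: mean
intramodular adjacency) and keep their relative connectivity pattern
(connectivity statistic: correlation of within-module connectivity, kIM,
between the two networks).  Each observed statistic is standardized against a
permutation null built from random gene sets of the same size drawn from
genes outside the module, giving Zdensity and Zconnectivity; their mean is
Zsummary.  Conventional thresholds: Zsummary > 10 strong evidence of
preservation, 2-10 weak evidence, < 2 no evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .modules import UNASSIGNED, ModulePartition
from .network import adjacency_from_correlation, pearson_correlation_matrix
from .simulate import STAGES, ExpressionStudy

__all__ = [
    "PreservationResult",
    "density_statistic",
    "connectivity_statistic",
    "permutation_null",
    "z_summary",
    "classify_preservation",
    "module_preservation",
    "stagewise_preservation",
]

Z_STRONG = 10.0
Z_NONE = 2.0


@dataclass
class PreservationResult:
    """Preservation evidence for one module."""

    module_id: str
    module_size: int
    observed_density: float
    observed_connectivity: float
    z_density: float
    z_connectivity: float
    z_summary: float
    evidence_class: str
    specific: bool
    n_permutations: int
    rng_seed: int


def _module_indices(gene_index: pd.Index, module_genes: Sequence[str]) -> np.ndarray:
    idx = gene_index.get_indexer(list(module_genes))
    if np.any(idx < 0):
        missing = [g for g, i in zip(module_genes, idx) if i < 0]
        raise InputError(f"module genes absent from the network: {missing[:5]}")
    return idx


def density_statistic(adjacency: pd.DataFrame, module_genes: Sequence[str]) -> float:
    """Mean off-diagonal adjacency within the module (intramodular density)."""
    idx = _module_indices(adjacency.index, module_genes)
    m = idx.size
    if m < 3:
        raise InputError(f"density statistic needs >= 3 module genes, got {m}")
    sub = adjacency.to_numpy()[np.ix_(idx, idx)]
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def connectivity_statistic(
    ref_adjacency: pd.DataFrame,
    test_adjacency: pd.DataFrame,
    module_genes: Sequence[str],
) -> float:
    """Correlation of within-module connectivity (kIM) across networks.

    kIM_i is the row sum of the module submatrix for gene i.  A zero-variance
    kIM vector in either network makes the correlation undefined; it is
    reported as 0 with a warning.
    """
    if len(module_genes) < 4:
        raise InputError(f"connectivity statistic needs >= 4 module genes, got {len(module_genes)}")
    k_ref = _module_kim(ref_adjacency, module_genes)
    k_test = _module_kim(test_adjacency, module_genes)
    return _safe_corr(k_ref, k_test)


def _module_kim(adjacency: pd.DataFrame, module_genes: Sequence[str]) -> np.ndarray:
    idx = _module_indices(adjacency.index, module_genes)
    sub = adjacency.to_numpy()[np.ix_(idx, idx)]
    return sub.sum(axis=1)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn(
            "zero-variance intramodular connectivity; connectivity statistic set to 0",
            stacklevel=3,
        )
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def permutation_null(
    test_adjacency: pd.DataFrame,
    module_genes: Sequence[str],
    n_perm: int,
    seed: int,
    statistic_kind: str = "density",
    ref_adjacency: Optional[pd.DataFrame] = None,
) -> tuple[float, float, np.ndarray]:
    """Null distribution of a preservation statistic from random gene sets.

    Gene sets of the module's size are drawn uniformly without replacement
    from genes *outside* the module; the statistic is recomputed for each.
    Returns ``(null_mean, null_sd, draws)``; deterministic given ``seed``.
    """
    if n_perm < 50:
        raise InputError(f"n_perm must be >= 50, got {n_perm}")
    if statistic_kind not in ("density", "connectivity"):
        raise InputError(f"unknown statistic_kind {statistic_kind!r}")
    if statistic_kind == "connectivity" and ref_adjacency is None:
        raise InputError("connectivity null requires ref_adjacency")
    gene_index = test_adjacency.index
    module = set(module_genes)
    pool = np.array([g for g in gene_index if g not in module])
    m = len(module_genes)
    if m >= len(gene_index):
        raise InputError("module size must be smaller than the gene universe")
    if len(pool) < m:
        raise InputError(
            f"only {len(pool)} genes outside the module; cannot draw sets of size {m}"
        )
    rng = np.random.default_rng(seed)
    a_test = test_adjacency.to_numpy()
    pool_idx = gene_index.get_indexer(pool)
    a_ref = ref_adjacency.to_numpy() if ref_adjacency is not None else None
    ref_pool_idx = (
        ref_adjacency.index.get_indexer(pool) if ref_adjacency is not None else None
    )
    draws = np.empty(n_perm)
    for b in range(n_perm):
        pick = rng.choice(len(pool), size=m, replace=False)
        ti = pool_idx[pick]
        sub_t = a_test[np.ix_(ti, ti)]
        if statistic_kind == "density":
            draws[b] = (sub_t.sum() - np.trace(sub_t)) / (m * (m - 1))
        else:
            ri = ref_pool_idx[pick]
            sub_r = a_ref[np.ix_(ri, ri)]
            k_t = sub_t.sum(axis=1)
            k_r = sub_r.sum(axis=1)
            st, sr = k_t.std(), k_r.std()
            draws[b] = 0.0 if (st == 0 or sr == 0) else float(np.corrcoef(k_r, k_t)[0, 1])
    mean = float(draws.mean())
    sd = float(draws.std(ddof=1))
    if sd < 1e-12 * max(1.0, abs(mean)):  # numerically constant null
        sd = 0.0
    return mean, sd, draws


def _z_score(observed: float, null_mean: float, null_sd: float) -> float:
    if null_sd == 0:
        warnings.warn("degenerate permutation null (sd = 0); Z reported as sentinel", stacklevel=3)
        if observed > null_mean:
            return float("inf")
        if observed < null_mean:
            return float("-inf")
        return 0.0
    return (observed - null_mean) / null_sd


def z_summary(z_density: float, z_connectivity: float) -> float:
    """Composite preservation statistic: mean of the two Z components."""
    return (z_density + z_connectivity) / 2.0


def classify_preservation(zsum: float) -> str:
    """Map Zsummary to an evidence class (strong / weak / none).

    Zsummary > 10 is strong evidence of preservation, < 2 is no evidence;
    everything between — boundaries included — is weak evidence.
    """
    if np.isnan(zsum):
        raise InputError("Zsummary is NaN; cannot classify")
    if zsum > Z_STRONG:
        return "strong"
    if zsum < Z_NONE:
        return "none"
    return "weak"


def module_preservation(
    ref_network,
    test_network,
    partition: ModulePartition,
    n_perm: int = 200,
    seed: int = 0,
) -> list[PreservationResult]:
    """Preservation of every reference-network module in the test network.

    ``ref_network``/``test_network`` may be GeneNetwork objects or adjacency
    DataFrames.  The partition comes from the reference network; unassigned
    genes are ignored.  Modules whose Zsummary shows no evidence of
    preservation (< 2) are flagged ``specific`` — present in the reference
    condition only, the hallmark of a condition-specific module.
    """
    ref_adj = getattr(ref_network, "adjacency", ref_network)
    test_adj = getattr(test_network, "adjacency", test_network)
    shared = test_adj.index.intersection(ref_adj.index)
    results: list[PreservationResult] = []
    for i, module_id in enumerate(partition.module_ids):
        genes = [g for g in partition.genes_in(module_id) if g in shared]
        if len(genes) < 4:
            warnings.warn(
                f"module {module_id!r} has fewer than 4 genes in the shared universe; skipped",
                stacklevel=2,
            )
            continue
        obs_density = density_statistic(test_adj, genes)
        obs_conn = connectivity_statistic(ref_adj, test_adj, genes)
        mod_seed = seed + 1000 * i
        mu_d, sd_d, _ = permutation_null(
            test_adj, genes, n_perm, mod_seed, statistic_kind="density"
        )
        mu_c, sd_c, _ = permutation_null(
            test_adj, genes, n_perm, mod_seed + 1,
            statistic_kind="connectivity", ref_adjacency=ref_adj,
        )
        z_d = _z_score(obs_density, mu_d, sd_d)
        z_c = _z_score(obs_conn, mu_c, sd_c)
        zsum = z_summary(z_d, z_c)
        cls = classify_preservation(zsum)
        results.append(
            PreservationResult(
                module_id=module_id,
                module_size=len(genes),
                observed_density=obs_density,
                observed_connectivity=obs_conn,
                z_density=z_d,
                z_connectivity=z_c,
                z_summary=zsum,
                evidence_class=cls,
                specific=cls == "none",
                n_permutations=n_perm,
                rng_seed=mod_seed,
            )
        )
    return results


def preservation_table(results: list[PreservationResult]) -> pd.DataFrame:
    rows = [
        {
            "module": r.module_id,
            "size": r.module_size,
            "Zdensity": r.z_density,
            "Zconnectivity": r.z_connectivity,
            "Zsummary": r.z_summary,
            "class": r.evidence_class,
            "specific": r.specific,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["module", "size", "Zdensity", "Zconnectivity", "Zsummary", "class", "specific"]
    ).set_index("module")


def stagewise_preservation(
    study: ExpressionStudy,
    partition: ModulePartition,
    n_perm: int = 200,
    seed: int = 0,
    condition: str = "test",
    soft_power: int = 6,
    min_stage_samples: int = 4,
) -> pd.DataFrame:
    """Zsummary of each module within each regeneration stage.

    Modules are fixed from the full ``condition`` network; for every stage a
    network is rebuilt from that stage's samples of the same condition and
    each module's preservation is measured against it.  Stages with fewer
    than ``min_stage_samples`` samples are skipped with a warning.  Returns a
    module x stage DataFrame of Zsummary values (NaN for skipped stages).
    """
    expr = study.condition_matrix(condition)
    ann = study.samples[study.samples["condition"] == condition]
    if list(ann.index) != list(expr.columns):
        raise InputError("sample annotations do not match the expression columns")
    missing = ann.index[~ann["stage"].isin(STAGES)]
    if len(missing):
        raise InputError(f"samples without a valid stage annotation: {list(missing[:5])}")

    genes = [g for g in expr.index if partition.labels.get(g, UNASSIGNED) != UNASSIGNED]
    if not genes:
        raise InputError("partition assigns no genes present in the study")
    universe = list(expr.index)
    full_adj = adjacency_from_correlation(
        pearson_correlation_matrix(expr.loc[universe]), soft_power
    )

    table = pd.DataFrame(
        np.nan, index=pd.Index(partition.module_ids, name="module"), columns=list(STAGES)
    )
    for s_i, stage in enumerate(STAGES):
        cols = ann.index[ann["stage"] == stage]
        if len(cols) < min_stage_samples:
            warnings.warn(
                f"stage {stage!r} has only {len(cols)} samples (< {min_stage_samples}); skipped",
                stacklevel=2,
            )
            continue
        stage_adj = adjacency_from_correlation(
            pearson_correlation_matrix(expr.loc[universe, cols]), soft_power
        )
        results = module_preservation(
            full_adj, stage_adj, partition, n_perm=n_perm, seed=seed + 10_000 * s_i
        )
        for r in results:
            table.loc[r.module_id, stage] = r.z_summary
    return table
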