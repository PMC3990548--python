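"""End-to-end orchestration: preprocess -> networks -> modules -> preservation -> hubs.

``run_pipeline`` executes the whole two-condition analysis on either a
synthetic study (a :class:`~coexnet.simulate.SimulationConfig`) or real
tab-delimited expression matrices, and writes every result table plus a
machine-readable run manifest into an output directory.  All randomness is
seeded, and reruns with an identical configuration produce byte-identical
outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from . import __version__
from .exceptions import ConfigError
from .io import (
    PathLike,
    read_expression,
    read_probe_map,
    read_samples,
    read_study,
    write_study,
)
from .modules import detect_modules
from .network import build_network
from .preprocess import collapse_probes, filter_by_ttest, select_most_connected
from .preservation import module_preservation, preservation_table, stagewise_preservation
from .significance import export_edge_list, gene_significance, hub_genes, hub_table
from .simulate import ExpressionStudy, SimulationConfig

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed for a full run.

    Exactly one of ``simulation`` or ``expression_dir`` must be provided;
    ``expression_dir`` names a directory holding reference_expr.tsv,
    test_expr.tsv and samples.tsv (see :func:`coexnet.io.write_study`).
    """

    simulation: Optional[SimulationConfig] = None
    expression_dir: Optional[str] = None
    probe_map: Optional[str] = None
    alpha: float = 0.05
    soft_power: Union[int, str] = 6
    n_top_genes: int = 3600
    deep_split: int = 2
    cut_height: float = 0.995
    min_module_size: int = 30
    kme_min: float = 0.3
    n_perm: int = 200
    edge_threshold: float = 0.3
    stagewise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.expression_dir is None):
            raise ConfigError(
                "configure exactly one input source: 'simulation' or 'expression_dir'"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None and not isinstance(sim, SimulationConfig):
            sim = SimulationConfig.from_dict(sim)
        return cls(simulation=sim, **d)


def _load_study(config: PipelineConfig) -> ExpressionStudy:
    if config.simulation is not None:
        from .simulate import simulate_two_condition_dataset

        return simulate_two_condition_dataset(config.simulation)
    study = read_study(config.expression_dir)
    if config.probe_map is not None:
        pm = read_probe_map(config.probe_map)
        study = ExpressionStudy(
            reference=collapse_probes(study.reference, pm),
            test=collapse_probes(study.test, pm),
            samples=study.samples,
            truth_labels=None,
        )
    return study


def run_pipeline(config: Union[PipelineConfig, Mapping, PathLike], out_dir: PathLike) -> Path:
    """Run the complete analysis and write results under ``out_dir``.

    Stages: load/simulate the study, Welch-t gene filter, most-connected gene
    selection, per-condition network construction, module detection on the
    test condition, kME reassignment, cross-condition preservation (test
    modules evaluated in the reference network), stage-wise preservation,
    gene significance, hub calling and edge-list export.  Any stage failure
    aborts with the stage name and cause.  Returns the run directory.
    """
    if isinstance(config, (str, Path)):
        from .io import read_config

        config = read_config(config)
    if isinstance(config, Mapping):
        config = PipelineConfig.from_dict(config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    stage = "load-study"
    try:
        study = _load_study(config)
        log(f"loaded study: {len(study.gene_ids)} genes, "
            f"{study.reference.shape[1]}+{study.test.shape[1]} samples")
        if config.simulation is not None:
            write_study(study, out / "study")

        stage = "gene-filter"
        kept, report = filter_by_ttest(study.test, study.reference, alpha=config.alpha)
        if len(kept) < max(10, config.min_module_size):
            warnings.warn(
                f"only {len(kept)} genes pass the t-test filter; "
                "continuing with the unfiltered gene set"
            )
            kept = study.gene_ids
        log(f"t-test filter (alpha={config.alpha}): {report.n_retained}/{report.n_input_genes} "
            f"genes retained, analysing {len(kept)}")

        stage = "select-most-connected"
        pooled = pd.concat([study.test[study.test.columns], study.reference], axis=1)
        base_power = 6 if config.soft_power == "auto" else int(config.soft_power)
        k_target = min(config.n_top_genes, len(kept))
        selected = select_most_connected(pooled.loc[kept], power=base_power, k_target=k_target)
        log(f"selected {len(selected)} most-connected genes (power {base_power})")

        stage = "network-construction"
        test_net = build_network(study.test.loc[selected], power=config.soft_power)
        ref_net = build_network(study.reference.loc[selected], power=test_net.soft_power)
        log(f"built test and reference networks at soft power {test_net.soft_power}")

        stage = "module-detection"
        detection = detect_modules(
            study.test.loc[selected],
            test_net.tom,
            deep_split=config.deep_split,
            cut_height=config.cut_height,
            min_module_size=config.min_module_size,
            kme_min=config.kme_min,
        )
        partition = detection.partition
        sizes = partition.sizes()
        log(f"detected {len(sizes)} modules (sizes {sizes.to_dict()}), "
            f"{int((partition.labels == 'unassigned').sum())} unassigned")

        stage = "module-preservation"
        results = module_preservation(
            test_net, ref_net, partition, n_perm=config.n_perm, seed=config.seed
        )
        pres = preservation_table(results)
        log("preservation (test modules in reference network):\n" + pres.to_string())

        stage = "stagewise-preservation"
        if config.stagewise:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stage_table = stagewise_preservation(
                    ExpressionStudy(
                        reference=study.reference.loc[selected],
                        test=study.test.loc[selected],
                        samples=study.samples,
                        truth_labels=None,
                    ),
                    partition,
                    n_perm=config.n_perm,
                    seed=config.seed + 1,
                    soft_power=test_net.soft_power,
                )
        else:
            stage_table = None

        stage = "gene-significance"
        scores = gene_significance(study.test.loc[selected], study.reference.loc[selected])

        stage = "hub-genes"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hubs = hub_genes(partition, detection.eigengenes.kme, scores)

        stage = "exports"
        assigned = [g for g in selected if partition.labels[g] != "unassigned"]
        edges, nodes = export_edge_list(
            test_net.adjacency.loc[assigned, assigned],
            threshold=config.edge_threshold,
            partition=partition,
        )
    except Exception as exc:  # re-raise with the failing stage named
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    modules_df = partition.labels.to_frame("module")
    own_kme = [
        detection.eigengenes.kme.loc[g, m] if m != "unassigned" and m in detection.eigengenes.kme.columns else float("nan")
        for g, m in partition.labels.items()
    ]
    modules_df["kME_own_module"] = own_kme
    modules_df.to_csv(out / "modules.tsv", sep="\t", index_label="gene_id")
    detection.eigengenes.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="module")
    pres.to_csv(out / "preservation.tsv", sep="\t")
    if stage_table is not None:
        stage_table.to_csv(out / "stage_preservation.tsv", sep="\t")
    scores.to_csv(out / "gene_scores.tsv", sep="\t", index_label="gene_id")
    hub_table(hubs).to_csv(out / "hubs.tsv", sep="\t")
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    nodes.to_csv(out / "nodes.tsv", sep="\t")

    manifest = {
        "coexnet_version": __version__,
        "parameters": {
            "alpha": config.alpha,
            "soft_power_requested": config.soft_power,
            "soft_power_used": test_net.soft_power,
            "n_top_genes": config.n_top_genes,
            "deep_split": config.deep_split,
            "cut_height": config.cut_height,
            "min_module_size": config.min_module_size,
            "kme_min": config.kme_min,
            "n_perm": config.n_perm,
            "edge_threshold": config.edge_threshold,
            "seed": config.seed,
        },
        "simulation": config.simulation.to_dict() if config.simulation else None,
        "expression_dir": config.expression_dir,
        "n_genes_input": len(study.gene_ids),
        "n_genes_analysed": len(selected),
        "n_modules": len(partition.module_ids),
        "module_sizes": {m: int(sizes[m]) for m in partition.module_ids},
        "preservation": {
            r.module_id: {
                "Zsummary": r.z_summary,
                "class": r.evidence_class,
                "specific": r.specific,
            }
            for r in results
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
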