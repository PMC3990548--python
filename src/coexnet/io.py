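"""Tab-delimited readers and writers for studies, matrices and results."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .exceptions import InputError
from .simulate import ExpressionStudy, SimulationConfig

PathLike = Union[str, Path]

__all__ = [
    "read_expression",
    "write_expression",
    "read_probe_map",
    "read_samples",
    "write_study",
    "read_study",
    "read_config",
    "write_config",
]


def read_expression(path: PathLike) -> pd.DataFrame:
    """Gene x sample TSV with gene IDs in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise InputError(f"{path}: no sample columns found")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df.columns.name = "sample_id"
    return df


def write_expression(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_probe_map(path: PathLike) -> dict[str, str]:
    """Two-column TSV (probe_id, gene_id) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: probe map needs two columns (probe_id, gene_id)")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        dupes = probes[probes.duplicated()].tolist()
        raise InputError(f"{path}: probes mapped more than once: {dupes[:5]}")
    return dict(zip(probes, genes))


def read_samples(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    required = {"condition", "time_h", "replicate", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: sample annotation misses columns {sorted(missing)}")
    return df


def write_study(study: ExpressionStudy, out_dir: PathLike) -> dict[str, Path]:
    """Persist a study as four TSVs; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference_expr.tsv",
        "test": out / "test_expr.tsv",
        "samples": out / "samples.tsv",
    }
    write_expression(study.reference, paths["reference"])
    write_expression(study.test, paths["test"])
    study.samples.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    if study.truth_labels is not None:
        paths["truth"] = out / "truth_labels.tsv"
        study.truth_labels.to_frame().to_csv(paths["truth"], sep="\t", index_label="gene_id")
    return paths


def read_study(directory: PathLike) -> ExpressionStudy:
    d = Path(directory)
    truth_path = d / "truth_labels.tsv"
    truth = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col="gene_id")["module_id"]
    return ExpressionStudy(
        reference=read_expression(d / "reference_expr.tsv"),
        test=read_expression(d / "test_expr.tsv"),
        samples=read_samples(d / "samples.tsv"),
        truth_labels=truth,
    )


def read_config(path: PathLike) -> dict:
    """YAML (or JSON — valid YAML) configuration file -> dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise InputError(f"{path}: configuration must be a mapping")
    return dict(cfg)


def write_config(config: Union[dict, SimulationConfig], path: PathLike) -> None:
    data = config.to_dict() if isinstance(config, SimulationConfig) else dict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
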