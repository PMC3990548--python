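"""Synthetic two-condition expression studies with planted co-expression modules.

The generator follows the single-latent-factor model that weighted
co-expression analysis itself assumes: every planted module is driven by one
smooth "eigengene" time profile, and each member gene is that profile scaled
by a per-gene loading plus i.i.d. Gaussian noise.  Two matched condition
matrices are produced — a *test* condition (the perturbed group, e.g.
regenerating liver after partial hepatectomy) containing all planted modules,
and a *reference* condition (the sham-operated control) in which each module
is either preserved (same profile and loadings), weakly preserved (loadings
halved), or entirely absent (genes replaced by independent noise).  Values
are on a log-ratio-to-control scale, hence centred around zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError

__all__ = [
    "DEFAULT_TIME_POINTS",
    "STAGES",
    "ModuleSpec",
    "SimulationConfig",
    "ExpressionStudy",
    "stage_of_time",
    "make_eigenprofile",
    "plant_module",
    "simulate_two_condition_dataset",
    "restrict_module_to_stages",
]

#: Post-control sampling times (hours) of the emulated liver-regeneration
#: time course; the 0 h control is consumed by the ratio transform upstream.
DEFAULT_TIME_POINTS: tuple[float, ...] = (2.0, 6.0, 12.0, 24.0, 30.0, 36.0, 72.0, 168.0)

STAGES = ("priming", "proliferative", "termination")

PRESERVATION_KINDS = ("preserved", "weak", "specific_to_test")


def stage_of_time(time_h: float, boundaries: tuple[float, float] = (6.0, 72.0)) -> str:
    """Map an hour to a regeneration stage.

    Stages are priming (2-6 h), proliferative (6-72 h) and termination
    (72-168 h); a time point sitting exactly on a boundary belongs to the
    earlier stage (6 h -> priming, 72 h -> proliferative).
    """
    lo, hi = boundaries
    if time_h <= lo:
        return "priming"
    if time_h <= hi:
        return "proliferative"
    return "termination"


@dataclass(frozen=True)
class ModuleSpec:
    """Description of one planted co-expression module.

    ``membership_low``/``membership_high`` bound the per-gene loadings on the
    module eigenprofile; ``preservation`` controls how the module appears in
    the reference condition.
    """

    module_id: str
    size: int
    membership_low: float
    membership_high: float
    preservation: str = "preserved"
    eigenprofile_seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ConfigError(f"module {self.module_id!r}: size must be >= 3, got {self.size}")
        if not (0.0 < self.membership_low <= self.membership_high <= 1.0):
            raise ConfigError(
                f"module {self.module_id!r}: need 0 < membership_low <= membership_high <= 1, "
                f"got ({self.membership_low}, {self.membership_high})"
            )
        if self.preservation not in PRESERVATION_KINDS:
            raise ConfigError(
                f"module {self.module_id!r}: preservation must be one of {PRESERVATION_KINDS}, "
                f"got {self.preservation!r}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Full design of a synthetic two-condition study."""

    modules: tuple[ModuleSpec, ...] = ()
    n_background_genes: int = 0
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    replicates_per_timepoint: int = 3
    noise_sd: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))
        object.__setattr__(self, "time_points", tuple(float(t) for t in self.time_points))
        if self.n_background_genes < 0:
            raise ConfigError("n_background_genes must be >= 0")
        if self.replicates_per_timepoint < 1:
            raise ConfigError("replicates_per_timepoint must be >= 1")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be > 0")
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate module_ids in config: {sorted(ids)}")

    @property
    def n_samples_per_condition(self) -> int:
        return len(self.time_points) * self.replicates_per_timepoint

    def to_dict(self) -> dict:
        return {
            "modules": [
                {
                    "module_id": m.module_id,
                    "size": m.size,
                    "membership_low": m.membership_low,
                    "membership_high": m.membership_high,
                    "preservation": m.preservation,
                    "eigenprofile_seed": m.eigenprofile_seed,
                }
                for m in self.modules
            ],
            "n_background_genes": self.n_background_genes,
            "time_points": list(self.time_points),
            "replicates_per_timepoint": self.replicates_per_timepoint,
            "noise_sd": self.noise_sd,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        modules = tuple(ModuleSpec(**m) for m in d.pop("modules", []))
        return cls(modules=modules, **d)


@dataclass
class ExpressionStudy:
    """Two condition-matched gene x sample matrices plus annotations.

    ``reference`` and ``test`` share identical gene IDs and row order;
    ``samples`` maps every sample to its condition, time, replicate and
    regeneration stage; ``truth_labels`` (synthetic studies only) maps each
    gene to its planted module or ``"background"``.
    """

    reference: pd.DataFrame
    test: pd.DataFrame
    samples: pd.DataFrame
    truth_labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if list(self.reference.index) != list(self.test.index):
            raise ConfigError("reference and test matrices must share gene IDs and row order")
        if self.reference.isna().any().any() or self.test.isna().any().any():
            raise ConfigError("expression matrices must not contain missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.test.index)

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        if condition == "reference":
            return self.reference
        if condition == "test":
            return self.test
        raise ConfigError(f"unknown condition {condition!r}")


def make_eigenprofile(
    time_points: Sequence[float], replicates: int, seed: int
) -> np.ndarray:
    """Draw a smooth, standardized module expression profile over samples.

    The profile is a random sinusoid plus a low-order polynomial in (rank-
    scaled) time, repeated across replicates of each time point, then
    standardized to mean 0, sd 1.  Deterministic given ``seed``.
    """
    t = np.asarray(list(time_points), dtype=float)
    n = t.size * replicates
    if n < 2:
        raise ConfigError(f"need at least 2 samples for an eigenprofile, got {n}")
    rng = np.random.default_rng(seed)
    # rank-scaled time keeps early, densely sampled hours from being squashed
    x = np.linspace(0.0, 1.0, t.size) if t.size > 1 else np.zeros(1)
    for _ in range(16):
        amp = rng.uniform(0.5, 1.5)
        freq = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        c1, c2 = rng.normal(0.0, 1.0, size=2)
        y = amp * np.sin(2.0 * np.pi * freq * x + phase) + c1 * x + c2 * x**2
        profile = np.repeat(y, replicates)
        sd = profile.std()
        if sd > 1e-8:
            return (profile - profile.mean()) / sd
    raise ConfigError(
        "could not draw a non-constant eigenprofile; "
        "supply at least two distinct time points"
    )


def plant_module(
    spec: ModuleSpec,
    eigenprofile: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    loadings: Optional[np.ndarray] = None,
    loading_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one gene block: gene_i = u_i * eigenprofile + noise.

    Returns ``(block, loadings)`` where ``block`` is (size x n_samples) and
    ``loadings`` the per-gene u_i drawn uniformly in
    [membership_low, membership_high] (or reused if supplied).
    """
    profile = np.asarray(eigenprofile, dtype=float)
    if loadings is None:
        loadings = rng.uniform(spec.membership_low, spec.membership_high, size=spec.size)
    loadings = np.asarray(loadings, dtype=float)
    noise = rng.normal(0.0, noise_sd, size=(spec.size, profile.size))
    block = (loading_scale * loadings)[:, None] * profile[None, :] + noise
    return block, loadings


def _orthogonal_profile(
    spec: ModuleSpec, config: SimulationConfig, basis: list[np.ndarray]
) -> np.ndarray:
    """Eigenprofile for one module, decorrelated from earlier modules' drivers.

    Distinct planted modules represent distinct latent processes, so their
    driving profiles are made mutually orthogonal by projecting out the
    profiles of previously planted modules (fresh deterministic redraws are
    used when a draw is nearly collinear with the existing drivers).
    """
    for attempt in range(12):
        seed = spec.eigenprofile_seed if attempt == 0 else spec.eigenprofile_seed + 7919 * attempt
        p = make_eigenprofile(config.time_points, config.replicates_per_timepoint, seed)
        r = p.copy()
        for b in basis:
            r -= (r @ b) / (b @ b) * b
        if r.std() > 0.1:
            return (r - r.mean()) / r.std()
    raise ConfigError(
        f"module {spec.module_id!r}: cannot plant another independent eigenprofile; "
        "too many modules for the number of distinct time points"
    )


def _sample_frame(config: SimulationConfig, condition: str) -> pd.DataFrame:
    rows = []
    for t in config.time_points:
        for r in range(1, config.replicates_per_timepoint + 1):
            rows.append(
                {
                    "sample_id": f"{condition}_{t:g}h_r{r}",
                    "condition": condition,
                    "time_h": t,
                    "replicate": r,
                    "stage": stage_of_time(t),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_two_condition_dataset(config: SimulationConfig) -> ExpressionStudy:
    """Simulate a matched reference/test study with planted modules.

    The test matrix contains every planted module.  In the reference matrix a
    ``preserved`` module reuses the same eigenprofile and loadings (fresh
    noise), a ``weak`` module has its loadings halved, and a
    ``specific_to_test`` module is replaced by pure i.i.d. noise.  Background
    genes are i.i.d. noise in both conditions.  Fully reproducible from
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_samples_per_condition
    if n < 2:
        raise ConfigError("need at least 2 samples per condition")

    gene_ids: list[str] = []
    labels: list[str] = []
    test_blocks: list[np.ndarray] = []
    ref_blocks: list[np.ndarray] = []

    basis: list[np.ndarray] = []
    for spec in config.modules:
        profile = _orthogonal_profile(spec, config, basis)
        basis.append(profile)
        test_block, loadings = plant_module(spec, profile, config.noise_sd, rng)
        if spec.preservation == "preserved":
            ref_block, _ = plant_module(spec, profile, config.noise_sd, rng, loadings=loadings)
        elif spec.preservation == "weak":
            ref_block, _ = plant_module(
                spec, profile, config.noise_sd, rng, loadings=loadings, loading_scale=0.5
            )
        else:  # specific_to_test: mutually independent noise in the reference
            ref_block = rng.normal(0.0, config.noise_sd, size=(spec.size, n))
        test_blocks.append(test_block)
        ref_blocks.append(ref_block)
        width = max(3, len(str(spec.size)))
        gene_ids.extend(f"{spec.module_id}_g{i:0{width}d}" for i in range(1, spec.size + 1))
        labels.extend([spec.module_id] * spec.size)

    if config.n_background_genes:
        ref_blocks.append(rng.normal(0.0, config.noise_sd, size=(config.n_background_genes, n)))
        test_blocks.append(rng.normal(0.0, config.noise_sd, size=(config.n_background_genes, n)))
        width = max(4, len(str(config.n_background_genes)))
        gene_ids.extend(f"noise_g{i:0{width}d}" for i in range(1, config.n_background_genes + 1))
        labels.extend(["background"] * config.n_background_genes)

    if not gene_ids:
        raise ConfigError("config produces zero genes; add modules or background genes")

    ref_samples = _sample_frame(config, "reference")
    test_samples = _sample_frame(config, "test")
    reference = pd.DataFrame(np.vstack(ref_blocks), index=gene_ids, columns=ref_samples.index)
    test = pd.DataFrame(np.vstack(test_blocks), index=gene_ids, columns=test_samples.index)
    reference.index.name = test.index.name = "gene_id"
    samples = pd.concat([ref_samples, test_samples])
    truth = pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"), name="module_id")
    return ExpressionStudy(reference=reference, test=test, samples=samples, truth_labels=truth)


def restrict_module_to_stages(
    study: ExpressionStudy,
    module_id: str,
    active_stages: Sequence[str],
    membership_low: float = 0.7,
    membership_high: float = 0.95,
    noise_sd: float = 0.3,
    seed: int = 0,
    condition: str = "test",
) -> ExpressionStudy:
    """Re-plant a module so it is co-expressed only within chosen stages.

    The module's genes are replaced (in the given condition, in place) by
    pure noise everywhere except the ``active_stages``, where they follow a
    shared driver profile standardized within the stage's samples.  This
    emulates a process switched on during specific regeneration stages —
    e.g. a cell-cycle module active only while hepatocytes proliferate.
    """
    if study.truth_labels is None:
        raise ConfigError("stage restriction requires truth labels (synthetic study)")
    bad = [s for s in active_stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages {bad}; valid stages: {STAGES}")
    genes = study.truth_labels.index[study.truth_labels == module_id]
    if len(genes) == 0:
        raise ConfigError(f"no genes carry truth label {module_id!r}")
    expr = study.condition_matrix(condition)
    ann = study.samples[study.samples["condition"] == condition]
    rng = np.random.default_rng(seed)
    loadings = rng.uniform(membership_low, membership_high, size=len(genes))
    block = rng.normal(0.0, noise_sd, size=(len(genes), expr.shape[1]))
    driver = rng.normal(size=expr.shape[1])
    col_pos = {c: j for j, c in enumerate(expr.columns)}
    for stage in active_stages:
        cols = [c for c in ann.index[ann["stage"] == stage] if c in col_pos]
        if len(cols) < 2:
            raise ConfigError(f"stage {stage!r} has fewer than 2 samples in {condition!r}")
        j = np.array([col_pos[c] for c in cols])
        z = driver[j]
        z = (z - z.mean()) / z.std()
        block[:, j] += loadings[:, None] * z[None, :]
    expr.loc[genes, :] = block
    return study
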