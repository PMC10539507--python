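"""Synthetic cohorts with planted invasion-deterministic TF programs.

The generator emulates the statistical structure the analysis assumes: a
quantile-normalized, log-scale expression matrix of ~20,000 genes over a
two-group cohort of ~23 tumorspheres; several partially overlapping
target sets per TF (as in motif-based regulon collections); a handful of
planted invasion-promoting and invasion-suppressing TFs whose targets —
and own genes — are shifted concordantly with group membership; paired
3D-assay and MRI invasion indices driven by one latent invasiveness per
sample; and exponential survival whose hazard tracks the invasion group.

Every generator is a pure function of (config, seed): each stage draws
from its own seeded stream, so regenerating any one output is
reproducible and independent of the others.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .enrichment import RegulonCollection
from .errors import ParameterError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_regulons",
    "generate_expression",
    "generate_invasion_measurements",
    "generate_survival",
    "write_ground_truth",
    "read_ground_truth",
]

# geometric means of the invasion indices per group and log-scale noise;
# the shared latent couples the paired 3D-assay and MRI indices
_TS_INDEX_GEOMEAN = {"low": 0.6, "high": 2.2}
_MRI_INDEX_GEOMEAN = {"low": 0.4, "high": 1.2}
_SHARED_LATENT_SD = 0.25
_IDIOSYNCRATIC_SD = 0.15

# per-stage stream tags so the generators draw from independent streams
_STREAM_REGULONS, _STREAM_EXPRESSION, _STREAM_INVASION, _STREAM_SURVIVAL = 1, 2, 3, 4


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort structure and planted-effect parameters.

    Defaults mirror a desk-scale glioblastoma tumorsphere study: 23
    samples (11 low- / 12 high-invasion), 20,000 genes, 50 TFs with three
    20-gene target sets each (30% within-TF overlap), 3 promoting and 2
    suppressing TFs planted at a 1.5-SD log-expression shift over a 0.5-SD
    residual, and a 3-fold group hazard ratio with 15% censoring.
    """

    n_genes: int = 20_000
    n_tfs: int = 50
    sets_per_tf: int = 3
    targets_per_set: int = 20
    target_overlap: float = 0.3
    n_low: int = 11
    n_high: int = 12
    effect_size: float = 1.5
    noise_sd: float = 0.5
    n_promoting: int = 3
    n_suppressing: int = 2
    hazard_ratio: float = 3.0
    censor_rate: float = 0.15
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    median_survival_low: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_tfs": self.n_tfs,
            "sets_per_tf": self.sets_per_tf, "targets_per_set": self.targets_per_set,
            "n_low": self.n_low, "n_high": self.n_high,
        }
        for name, value in counts.items():
            if value < 1:
                raise ParameterError(f"{name} must be >= 1, got {value}")
        if self.n_tfs > self.n_genes:
            raise ParameterError("n_tfs cannot exceed n_genes")
        if not 0.0 <= self.target_overlap <= 1.0:
            raise ParameterError("target_overlap must lie in [0, 1]")
        if self.n_promoting < 0 or self.n_suppressing < 0:
            raise ParameterError("planted TF counts must be >= 0")
        if self.n_promoting + self.n_suppressing > self.n_tfs:
            raise ParameterError("n_promoting + n_suppressing cannot exceed n_tfs")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.hazard_ratio <= 0:
            raise ParameterError("hazard_ratio must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ParameterError("censor_rate must lie in [0, 1)")
        if self.sets_per_tf * self.targets_per_set > self.n_genes:
            raise ParameterError("sets_per_tf * targets_per_set exceeds n_genes")

    @property
    def n_samples(self) -> int:
        return self.n_low + self.n_high

    def gene_ids(self) -> list[str]:
        """Gene universe; the first n_tfs genes are the TFs' own genes."""
        wt = max(2, len(str(self.n_tfs)))
        wg = max(4, len(str(self.n_genes)))
        tfs = [f"TF{i + 1:0{wt}d}" for i in range(self.n_tfs)]
        rest = [f"G{j + 1:0{wg}d}" for j in range(self.n_genes - self.n_tfs)]
        return tfs + rest

    def tf_ids(self) -> list[str]:
        return self.gene_ids()[: self.n_tfs]

    def sample_ids(self) -> list[str]:
        w = max(2, len(str(self.n_samples)))
        return [f"S{i + 1:0{w}d}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    """Planted structure for recovery scoring.

    ``gene_shift`` records the planted high-minus-low log-expression
    difference per gene: positive for targets (and own genes) of promoting
    TFs, negative for those of suppressing TFs.
    """

    promoting_tfs: list[str]
    suppressing_tfs: list[str]
    gene_shift: dict[str, float] = field(default_factory=dict)
    sample_groups: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.promoting_tfs) & set(self.suppressing_tfs):
            raise ParameterError("promoting and suppressing TF lists overlap")

    @property
    def planted_tfs(self) -> list[str]:
        return list(self.promoting_tfs) + list(self.suppressing_tfs)

    def labels(self) -> pd.Series:
        return pd.Series(self.sample_groups, name="label")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def generate_regulons(config: SimulationConfig) -> tuple[RegulonCollection, GroundTruth]:
    """Draw TF target sets and the planted ground truth.

    Each TF owns ``sets_per_tf`` sets of ``targets_per_set`` genes sharing
    a common core of ``round(target_overlap * targets_per_set)`` genes; a
    TF's own gene never appears among its targets.  Target pools of the
    planted TFs are kept disjoint from each other and from every other
    regulon, so each planted shift is attributable to exactly one TF.
    """
    rng = _rng(config.seed, _STREAM_REGULONS)
    genes = config.gene_ids()
    tfs = config.tf_ids()

    core = round(config.target_overlap * config.targets_per_set)
    per_set_extra = config.targets_per_set - core
    needed = core + config.sets_per_tf * per_set_extra
    if needed > config.n_genes - 1:
        raise ParameterError(
            f"infeasible overlap: {needed} distinct targets needed per TF but "
            f"only {config.n_genes - 1} genes are available")

    perm = rng.permutation(config.n_tfs)
    promoting = sorted(tfs[i] for i in perm[: config.n_promoting])
    suppressing = sorted(
        tfs[i] for i in perm[config.n_promoting: config.n_promoting + config.n_suppressing]
    )
    planted = set(promoting) | set(suppressing)

    groups = np.array(["high"] * config.n_samples, dtype=object)
    groups[rng.choice(config.n_samples, size=config.n_low, replace=False)] = "low"
    sample_groups = dict(zip(config.sample_ids(), groups))

    sets: dict[str, list[str]] = {}
    tf_of: dict[str, str] = {}
    targets_of: dict[str, set[str]] = {}
    reserved: set[str] = set(planted)  # planted own genes are never targets
    draw_order = sorted(planted) + [tf for tf in tfs if tf not in planted]
    for tf in draw_order:
        pool = np.array([g for g in genes if g not in reserved and g != tf])
        if len(pool) < needed:
            raise ParameterError("gene universe too small for disjoint planted regulons")
        draw = rng.choice(pool, size=needed, replace=False)
        core_genes = list(draw[:core])
        targets_of[tf] = set(draw)
        for k in range(config.sets_per_tf):
            start = core + k * per_set_extra
            members = sorted(core_genes + list(draw[start: start + per_set_extra]))
            name = f"{tf}_S{k + 1}"
            sets[name] = members
            tf_of[name] = tf
        if tf in planted:
            reserved |= set(draw)

    gene_shift: dict[str, float] = {}
    for tf in promoting:
        for g in targets_of[tf] | {tf}:
            gene_shift[g] = config.effect_size
    for tf in suppressing:
        for g in targets_of[tf] | {tf}:
            gene_shift[g] = -config.effect_size

    # present sets in TF-id order regardless of the planted-first draw order
    ordered_names = [f"{tf}_S{k + 1}" for tf in tfs for k in range(config.sets_per_tf)]
    regulons = RegulonCollection(
        sets={name: sets[name] for name in ordered_names},
        tf_of={name: tf_of[name] for name in ordered_names},
    )
    truth = GroundTruth(
        promoting_tfs=promoting,
        suppressing_tfs=suppressing,
        gene_shift=gene_shift,
        sample_groups=sample_groups,
        seed=config.seed,
    )
    return regulons, truth


def generate_expression(
    config: SimulationConfig,
    regulons: RegulonCollection,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the log-scale expression matrix and the sample phenotype table.

    Each gene g has a fixed baseline mu_g ~ Normal(baseline_mean,
    baseline_sd); samples add Normal(0, noise_sd) residuals.  The planted
    shift of ``truth.gene_shift`` is added to high-group samples when
    positive and (negated) to low-group samples when negative.
    """
    rng = _rng(config.seed, _STREAM_EXPRESSION)
    genes = config.gene_ids()
    samples = config.sample_ids()
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    x = mu[:, None] + rng.normal(0.0, config.noise_sd,
                                 size=(config.n_genes, config.n_samples))
    groups = np.array([truth.sample_groups[s] for s in samples])
    shift = np.array([truth.gene_shift.get(g, 0.0) for g in genes])
    x[:, groups == "high"] += np.clip(shift, 0.0, None)[:, None]
    x[:, groups == "low"] += np.clip(-shift, 0.0, None)[:, None]
    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=samples)
    phenotype = pd.DataFrame({"sample_id": samples, "group": groups})
    return expr, phenotype


def generate_invasion_measurements(
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Draw paired 3D-assay and MRI areas from a shared latent invasiveness.

    Indices are log-normal around group-specific geometric means; the two
    modalities share one latent normal per sample, which makes the paired
    TS and MRI indices positively correlated by construction.  Areas are
    back-computed so the index formulas reproduce the drawn indices.
    """
    rng = _rng(config.seed, _STREAM_INVASION)
    samples = config.sample_ids()
    rows = []
    for s in samples:
        group = truth.sample_groups[s]
        z = rng.normal()
        ts_index = math.exp(math.log(_TS_INDEX_GEOMEAN[group])
                            + _SHARED_LATENT_SD * z
                            + _IDIOSYNCRATIC_SD * rng.normal())
        mri_index = math.exp(math.log(_MRI_INDEX_GEOMEAN[group])
                             + _SHARED_LATENT_SD * z
                             + _IDIOSYNCRATIC_SD * rng.normal())
        area_0h = rng.uniform(0.05, 0.15)  # mm^2, spheroid footprint at seeding
        ce_area = rng.uniform(2.0, 8.0)    # cm^2, contrast-enhancing core
        rows.append({
            "sample_id": s,
            "group": group,
            "area_0h": area_0h,
            "area_72h": area_0h * (1.0 + ts_index),
            "ts_index": ts_index,
            "ce_area": ce_area,
            "flair_area": ce_area * (1.0 + mri_index),
            "mri_index": mri_index,
        })
    return pd.DataFrame(rows)


def generate_survival(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Draw exponential survival with group-proportional hazards.

    The low-invasion group has median ``median_survival_low`` (months);
    the high group's hazard is ``hazard_ratio`` times larger.  Censoring
    times are independent exponentials whose rate is chosen per group so
    the expected censored fraction equals ``censor_rate``.
    """
    rng = _rng(config.seed, _STREAM_SURVIVAL)
    lam = {"low": math.log(2.0) / config.median_survival_low}
    lam["high"] = lam["low"] * config.hazard_ratio
    c = config.censor_rate
    rows = []
    for s, group in truth.sample_groups.items():
        t_event = rng.exponential(1.0 / lam[group])
        if c == 0.0:
            time, event = t_event, 1
        else:
            mu = lam[group] * c / (1.0 - c)
            t_censor = rng.exponential(1.0 / mu)
            time = min(t_event, t_censor)
            event = int(t_event <= t_censor)
        rows.append({"sample_id": s, "time": time, "event": event, "group": group})
    return pd.DataFrame(rows)


def write_ground_truth(truth: GroundTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)


def read_ground_truth(path: str | os.PathLike) -> GroundTruth:
    with open(path) as fh:
        data = json.load(fh)
    return GroundTruth(**data)
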