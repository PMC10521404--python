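"""Synthetic cohorts with the statistical structure the analysis assumes.

No raw MRI data are available for this kind of study design, so the
generator emulates the analysis inputs directly at the vertex-thickness
level: 65 subjects by default, the 32 retained Yeo-7 parcels with their
bundled atlas vertex counts, plausible cortical-thickness distributions
(~2-4 mm), a covariate set (age, sex, education, intracranial volume) with
a realistic negative age-education correlation, and 14 MHC-SF item responses driven
by a latent well-being factor.

Generative model
----------------
* Each parcel draws vertex thickness from a two-component Gaussian location
  mixture. Background parcels get mildly heterogeneous, subject-stable shape
  parameters (mean offset, spread multiplier, component separation), plus a
  small per-subject jitter, so similarity matrices have realistic spread.
* An optional *planted effect*: one effect parcel plus a neighbour set
  (default: the parcels sharing its hemisphere and Yeo network) form a
  strongly bimodal cluster, and two "gate" parcels carry narrow
  distributions at the extreme peak positions. The effect parcel's
  component separation moves with the subject's latent well-being factor,
  sliding its peaks from the gates (low latent: its network neighbours are
  the mutually dissimilar gates, so local efficiency collapses) onto the
  cluster (high latent: triangle-rich neighbourhood, high local
  efficiency). ``effect_size`` is the *target* partial correlation between
  the planted parcel's topology and the total well-being score; the
  internal gain mapping was calibrated by pilot simulation at the default
  operating point (|r| ~ 0.4, n = 65).
* Item responses arise by thresholding latent + noise at five equally
  spaced ordered cut points (a graded-response discretisation onto the
  6-point frequency scale).
* Covariates come from a Gaussian copula hitting the target correlations;
  sex is an independent binary draw.

A single global seed feeds a hierarchical stream per subject, so enlarging
the cohort never changes already-generated subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .behavior import ITEM_COLUMNS
from .thickness import ParcelTable, SubjectThickness, default_parcel_table

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_covariates",
    "simulate_parcel_thickness",
    "simulate_behavior",
    "simulate_cohort",
    "write_cohort",
    "effect_cluster",
    "effect_gates",
    "parcel_parameters",
]

#: gain per unit of target partial correlation in the latent->separation link;
#: calibrated once by pilot simulation at effect_size 0.4, n = 65.
EFFECT_GAIN_PER_UNIT_R = 2.4


@dataclass(frozen=True)
class CovariateSpec:
    """Means/SDs and target correlations for age, education and ICV."""

    age_mean: float = 37.29  # years
    age_sd: float = 13.11
    education_mean: float = 15.37  # years
    education_sd: float = 3.19
    icv_mean: float = 1.45e6  # mm^3
    icv_sd: float = 1.5e5
    corr_age_education: float = -0.401
    corr_age_icv: float = 0.0
    corr_education_icv: float = 0.0
    male_proportion: float = 0.48

    def validate(self) -> None:
        for name in ("age_sd", "education_sd", "icv_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.male_proportion <= 1:
            raise ValueError("male_proportion must lie in [0, 1]")
        for name in ("corr_age_education", "corr_age_icv", "corr_education_icv"):
            if not -1 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [-1, 1]")

    def correlation_matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.corr_age_education, self.corr_age_icv],
                [self.corr_age_education, 1.0, self.corr_education_icv],
                [self.corr_age_icv, self.corr_education_icv, 1.0],
            ]
        )


@dataclass
class SimulationConfig:
    n_subjects: int = 65
    parcel_spec: list[tuple[str, int]] | None = None  # default: bundled 32 parcels
    thickness_mean: float = 2.5  # mm
    thickness_sd: float = 0.3  # mm
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    effect_parcel: str | None = None
    effect_neighbors: list[str] | None = None  # default: same hemisphere + network
    effect_size: float = 0.0  # target partial correlation, in [-1, 1]
    latent_noise_sd: float = 1.0  # per-item noise on the latent scale
    item_cut_center: float = -1.1  # middle ordered cut point
    item_cut_spacing: float = 0.75
    response_min: int = 0  # numeric coding of 'never'
    parcel_mean_jitter_sd: float = 0.06  # mm, between-parcel baseline spread
    parcel_sd_range: tuple[float, float] = (0.85, 1.15)  # spread multipliers
    parcel_sep_max: float = 0.12  # mm, background bimodality
    subject_jitter_sd: float = 0.02  # mm, per subject x parcel
    cluster_sep: float = 0.8  # mm, bimodal separation of the planted cluster
    cluster_component_sd: float = 0.15  # mm, within-component spread of the cluster
    gate_offset: float = 0.7  # mm, extra separation at the low-latent extreme
    gate_sd: float = 0.10  # mm, spread of the two anchor ("gate") parcels
    effect_gates: list[str] | None = None  # default: two largest background parcels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parcel_spec is None:
            table = default_parcel_table()
            self.parcel_spec = list(
                zip(table.names, table.frame["vertex_count"].astype(int))
            )
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 8:  # 6 GLM covariates + slope + intercept estimable
            raise ValueError("n_subjects must be at least 8 for the GLM to be estimable")
        names = [p for p, _ in self.parcel_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parcel names in parcel_spec")
        if any(c <= 0 for _, c in self.parcel_spec):
            raise ValueError("every vertex count must be positive")
        if not -1.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [-1, 1]")
        if self.effect_parcel is not None and self.effect_parcel not in names:
            raise ValueError(f"effect_parcel {self.effect_parcel!r} not in parcel_spec")
        if self.effect_neighbors is not None:
            unknown = set(self.effect_neighbors) - set(names)
            if unknown:
                raise ValueError(f"effect_neighbors not in parcel_spec: {sorted(unknown)}")
        if self.latent_noise_sd < 0 or self.thickness_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        self.covariates.validate()

    @property
    def parcel_names(self) -> list[str]:
        return [p for p, _ in self.parcel_spec]

    @property
    def vertex_counts(self) -> dict[str, int]:
        return dict(self.parcel_spec)

    def parcel_table(self) -> ParcelTable:
        rows = []
        for name, count in self.parcel_spec:
            parts = name.split("_")
            hemi = parts[0] if parts[0] in ("LH", "RH") else "NA"
            net = parts[1] if hemi != "NA" and len(parts) > 1 else "NA"
            rows.append(
                {
                    "parcel_name": name,
                    "hemisphere": hemi,
                    "network": net,
                    "vertex_count": int(count),
                }
            )
        return ParcelTable(pd.DataFrame(rows))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        data = dict(mapping)
        if "covariates" in data and isinstance(data["covariates"], dict):
            data["covariates"] = CovariateSpec(**data["covariates"])
        if "parcel_spec" in data and data["parcel_spec"] is not None:
            data["parcel_spec"] = [(str(p), int(c)) for p, c in data["parcel_spec"]]
        return cls(**data)

    def to_mapping(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class SyntheticCohort:
    thickness: list[SubjectThickness]
    behavior: pd.DataFrame  # subject_id + item_01..item_14
    covariates: pd.DataFrame  # subject_id, age, sex, education_years, icv_mm3
    latent: np.ndarray  # ground-truth well-being factor
    parcel_table: ParcelTable
    config: SimulationConfig

    def __post_init__(self) -> None:
        n = len(self.thickness)
        if not (len(self.behavior) == len(self.covariates) == len(self.latent) == n):
            raise ValueError("per-subject containers must have identical length")
        lo = self.config.response_min
        items = self.behavior[ITEM_COLUMNS].to_numpy()
        if items.min() < lo or items.max() > lo + 5:
            raise ValueError("item responses outside the configured response range")

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.thickness]


# ---------------------------------------------------------------------------
# random-stream plumbing: one hierarchical stream per subject


def _subject_streams(config: SimulationConfig):
    root = np.random.SeedSequence(config.seed)
    parcel_ss, pool = root.spawn(2)
    subjects = pool.spawn(config.n_subjects)
    return parcel_ss, [s.spawn(3) for s in subjects]  # (cov, behavior, thickness)


def parcel_parameters(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """Subject-stable per-parcel shape parameters (seeded from the config)."""
    parcel_ss, _ = _subject_streams(config)
    rng = np.random.default_rng(parcel_ss)
    lo, hi = config.parcel_sd_range
    params = {}
    for name in config.parcel_names:
        params[name] = {
            "mean": config.thickness_mean
            + rng.normal(0.0, config.parcel_mean_jitter_sd),
            "sd": config.thickness_sd * rng.uniform(lo, hi),
            "sep": rng.uniform(0.0, config.parcel_sep_max),
        }
    return params


def effect_cluster(config: SimulationConfig) -> tuple[str | None, list[str]]:
    """(effect parcel, neighbour set) of the planted cluster."""
    if config.effect_parcel is None:
        return None, []
    if config.effect_neighbors is not None:
        return config.effect_parcel, list(config.effect_neighbors)
    parts = config.effect_parcel.split("_")
    prefix = "_".join(parts[:2]) + "_" if len(parts) > 1 else config.effect_parcel
    neighbors = [
        p
        for p in config.parcel_names
        if p != config.effect_parcel
        and (p.startswith(prefix) or p == prefix.rstrip("_"))
    ]
    return config.effect_parcel, neighbors


def _effect_active(config: SimulationConfig) -> bool:
    return config.effect_parcel is not None and config.effect_size != 0.0


def effect_gates(config: SimulationConfig) -> list[str]:
    """The two anchor parcels of the planted effect.

    At the low-latent extreme the effect parcel's mixture components land on
    the two gates' (narrow, extreme-mean) distributions; because the gates
    are mutually dissimilar, the effect parcel's network neighbours are then
    unconnected and its local efficiency collapses. Defaults to the two
    largest parcels outside the cluster (low histogram sampling noise).
    """
    if not _effect_active(config):
        return []
    if config.effect_gates is not None:
        return list(config.effect_gates)
    _, neighbors = effect_cluster(config)
    excluded = set(neighbors) | {config.effect_parcel}
    candidates = [(c, p) for p, c in config.parcel_spec if p not in excluded]
    candidates.sort(reverse=True)
    return [p for _, p in candidates[:2]]


# ---------------------------------------------------------------------------
# component simulators


def simulate_covariates(
    config: SimulationConfig, rng_streams=None
) -> pd.DataFrame:
    """Covariate table: age, sex, education, ICV with target correlations.

    Age, education and ICV come from a Gaussian copula (here: correlated
    normals) matched to the configured means, SDs and pairwise correlations;
    sex is an independent Bernoulli draw. Deterministic given the seed.
    """
    config.validate()
    if rng_streams is None:
        _, subj = _subject_streams(config)
        rng_streams = [s[0] for s in subj]
    corr = config.covariates.correlation_matrix()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariate correlation matrix is not positive definite") from exc
    cs = config.covariates
    means = np.array([cs.age_mean, cs.education_mean, cs.icv_mean])
    sds = np.array([cs.age_sd, cs.education_sd, cs.icv_sd])
    rows = []
    for i, ss in enumerate(rng_streams):
        rng = np.random.default_rng(ss)
        x = means + sds * (chol @ rng.standard_normal(3))
        sex = "M" if rng.random() < cs.male_proportion else "F"
        rows.append(
            {
                "subject_id": f"sub-{i + 1:03d}",
                "age": x[0],
                "sex": sex,
                "education_years": x[1],
                "icv_mm3": x[2],
            }
        )
    return pd.DataFrame(rows)


def _parcel_shape(
    parcel: str, config: SimulationConfig, params: dict, latent: float
) -> tuple[float, float, float]:
    """(mean, component sd, separation) of a parcel's mixture for one subject.

    With an active planted effect the cluster parcels share the global
    baseline mean and a fixed strong separation; the effect parcel's
    separation slides from ``cluster_sep + gate_offset`` (low latent, peaks
    on the two gates) down to ``cluster_sep`` (high latent, aligned with the
    cluster); the gates are narrow unimodal distributions at the extreme
    peak positions. Everything else keeps its subject-stable background
    shape.
    """
    if _effect_active(config):
        effect_parcel, neighbors = effect_cluster(config)
        gates = effect_gates(config)
        if parcel == effect_parcel:
            gain = EFFECT_GAIN_PER_UNIT_R * config.effect_size
            sep = config.cluster_sep + config.gate_offset * (
                1.0 - float(ndtr(gain * latent))
            )
            return config.thickness_mean, config.cluster_component_sd, sep
        if parcel in neighbors:
            return config.thickness_mean, config.cluster_component_sd, config.cluster_sep
        if parcel in gates:
            side = 1.0 if gates.index(parcel) else -1.0
            mean = config.thickness_mean + side * (
                config.cluster_sep + config.gate_offset
            ) / 2.0
            return mean, config.gate_sd, 0.0
    p = params[parcel]
    return p["mean"], p["sd"], p["sep"]


def simulate_parcel_thickness(
    parcel: str,
    subject_latent: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    parcel_params: dict | None = None,
    subject_jitter: float = 0.0,
) -> np.ndarray:
    """Vertex thickness vector (mm) for one parcel of one subject.

    A balanced two-component Gaussian location mixture with component means
    at parcel mean +/- separation/2; see :func:`_parcel_shape` for how the
    planted effect moves the effect parcel's separation with the latent
    factor between the gate-aligned and cluster-aligned configurations.
    """
    counts = config.vertex_counts
    if parcel not in counts:
        raise ValueError(f"unknown parcel {parcel!r}")
    params = parcel_params if parcel_params is not None else parcel_parameters(config)
    mean, sd, sep = _parcel_shape(parcel, config, params, subject_latent)
    n = counts[parcel]
    comp = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    values = mean + subject_jitter + comp * (sep / 2.0) + rng.standard_normal(n) * sd
    return np.clip(values, 0.05, None)  # thickness is physically positive


def simulate_behavior(
    latent: np.ndarray,
    config: SimulationConfig,
    rng_streams=None,
) -> pd.DataFrame:
    """14 ordinal item responses per subject by thresholding latent + noise.

    Five equally spaced ordered cut points map the continuous propensity
    onto the 6-point frequency scale; higher latent gives stochastically
    higher responses.
    """
    latent = np.asarray(latent, dtype=float)
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent values must be finite")
    if rng_streams is None:
        _, subj = _subject_streams(config)
        rng_streams = [s[1] for s in subj[: len(latent)]]
    cuts = config.item_cut_center + config.item_cut_spacing * np.arange(-2, 3)
    rows = []
    for i, (z, ss) in enumerate(zip(latent, rng_streams)):
        rng = np.random.default_rng(ss)
        noise = rng.standard_normal(14) * config.latent_noise_sd
        resp = (z + noise)[:, None] > cuts[None, :]
        scores = resp.sum(axis=1) + config.response_min
        row = {"subject_id": f"sub-{i + 1:03d}"}
        row.update({col: int(s) for col, s in zip(ITEM_COLUMNS, scores)})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Compose covariate, behavior and thickness simulators into a cohort."""
    config.validate()
    _, subj_streams = _subject_streams(config)
    params = parcel_parameters(config)
    table = config.parcel_table()

    covariates = simulate_covariates(config, [s[0] for s in subj_streams])

    latent = np.empty(config.n_subjects)
    beh_rngs = []
    for i, (_, beh_ss, _) in enumerate(subj_streams):
        # the behavior stream provides the latent first, then item noise
        rng = np.random.default_rng(beh_ss)
        latent[i] = rng.standard_normal()
        beh_rngs.append(rng)

    cuts = config.item_cut_center + config.item_cut_spacing * np.arange(-2, 3)
    beh_rows = []
    for i, rng in enumerate(beh_rngs):
        noise = rng.standard_normal(14) * config.latent_noise_sd
        scores = ((latent[i] + noise)[:, None] > cuts[None, :]).sum(axis=1)
        row = {"subject_id": f"sub-{i + 1:03d}"}
        row.update(
            {col: int(s) + config.response_min for col, s in zip(ITEM_COLUMNS, scores)}
        )
        beh_rows.append(row)
    behavior = pd.DataFrame(beh_rows)

    thickness = []
    names = config.parcel_names
    for i, (_, _, thick_ss) in enumerate(subj_streams):
        rng = np.random.default_rng(thick_ss)
        jitters = rng.normal(0.0, config.subject_jitter_sd, len(names))
        cluster_jitter = rng.normal(0.0, config.subject_jitter_sd)
        effect_parcel, neighbors = effect_cluster(config)
        values = {}
        for k, name in enumerate(names):
            in_cluster = _effect_active(config) and (
                name == effect_parcel or name in neighbors
            )
            jit = cluster_jitter if in_cluster else jitters[k]
            values[name] = simulate_parcel_thickness(
                name, latent[i], config, rng, parcel_params=params, subject_jitter=jit
            )
        subject = SubjectThickness(f"sub-{i + 1:03d}", values)
        thickness.append(subject.validate(table))

    return SyntheticCohort(
        thickness=thickness,
        behavior=behavior,
        covariates=covariates,
        latent=latent,
        parcel_table=table,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the cohort in the pipeline's interchange formats.

    ``thickness/<subject_id>.tsv`` per subject, ``behavior.csv`` (items plus
    covariates) and ``latent.csv`` (ground truth for recovery tests).
    """
    import os

    from .thickness import write_subject_thickness

    os.makedirs(os.path.join(outdir, "thickness"), exist_ok=True)
    for subject in cohort.thickness:
        write_subject_thickness(
            subject, os.path.join(outdir, "thickness", f"{subject.subject_id}.tsv")
        )
    behavior = cohort.behavior.merge(cohort.covariates, on="subject_id")
    behavior.to_csv(os.path.join(outdir, "behavior.csv"), index=False)
    pd.DataFrame(
        {"subject_id": cohort.subject_ids, "latent": cohort.latent}
    ).to_csv(os.path.join(outdir, "latent.csv"), index=False)
    cohort.parcel_table.frame.to_csv(
        os.path.join(outdir, "parcels.tsv"), sep="\t", index=False
    )
    return {
        "n_subjects": len(cohort.thickness),
        "n_parcels": cohort.parcel_table.n_parcels,
    }
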