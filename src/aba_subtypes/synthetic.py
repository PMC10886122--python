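"""Synthetic multimodal cohorts with planted accelerated-aging subtypes.

The generator emulates the statistical structure the downstream analysis
assumes, without attempting to reproduce any real biobank's marginal
distributions: each imaging-derived phenotype (IDP) drifts linearly with
age, noise is correlated within a modality block, and a configurable
fraction of subjects ("accelerated" agers) carries one of K subtype
offsets — mutually orthogonal unit directions in standardized IDP space,
scaled to a chosen effect size.  Cognitive scores decline with subtype
severity; the two duration-valued scores are generated on a positive
scale so the log-transform path is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import Cohort, CohortSchema, default_schema

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "GroundTruth",
    "plant_subtypes",
    "generate_cohort",
    "null_cohort",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


DEFAULT_BLOCK_SIZES = {"sMRI": 207, "dMRI": 144, "rsfMRI": 210}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    Effects are expressed in per-IDP standard-deviation (SD) units and
    mapped back through each IDP's own scale, so ``subtype_effect_size``
    is the Euclidean length, in SD units, of the multivariate offset an
    accelerated-aging subject receives.

    Parameters
    ----------
    n_subjects : total cohort size.
    age_range : uniform sampling range for chronological age, years.
    n_networks : resting-state networks; the rsfMRI block has
        n(n-1)/2 edge columns (21 networks -> 210 edges).
    age_slope_scale : mean magnitude of the per-IDP age effect,
        SD units per year.  0.02 SD/yr over a ~38-year age span gives
        each IDP a modest but learnable age signal.
    noise_sd : subject-level noise SD on the standardized scale.  The
        default 1/3 makes the default 1.5-SD subtype offsets strongly
        separated (pairwise centroid separation ~6 noise SDs), so planted
        structure is recoverable by construction; the generator is a
        testbed for algorithmic correctness, not a model of real-world
        effect sizes.
    block_noise_corr : share of noise variance common to a modality
        block (a shared per-subject block factor).
    n_subtypes : number of planted accelerated-aging subtypes K.
    subtype_effect_size : length of each subtype's offset vector, SD units.
    subtype_fractions : mixing proportions over subtypes (default equal).
    aba_fraction : fraction of subjects flagged as accelerated agers.
    covariate_effects : (sex, education) effects on IDPs, SD units.
    orthogonal_subtypes : orthonormalize the subtype directions
        (identifiable planted structure); disable for robustness tests.
    confounded_covariates : couple sex/education to subtype membership,
        to exercise covariate residualization.
    """

    n_subjects: int = 3000
    age_range: tuple[float, float] = (45.0, 83.0)
    n_networks: int = 21
    block_sizes: Mapping[str, int] | None = None
    age_slope_scale: float = 0.02
    noise_sd: float = 1.0 / 3.0
    block_noise_corr: float = 0.1
    n_subtypes: int = 3
    subtype_effect_size: float = 1.5
    subtype_fractions: tuple[float, ...] | None = None
    aba_fraction: float = 1.0 / 3.0
    covariate_effects: tuple[float, float] = (0.1, 0.02)
    cognitive_severity_slope: float = 0.5
    orthogonal_subtypes: bool = True
    confounded_covariates: bool = False
    seed: int = 0

    def resolved_block_sizes(self) -> dict[str, int]:
        if self.block_sizes is not None:
            return dict(self.block_sizes)
        sizes = dict(DEFAULT_BLOCK_SIZES)
        sizes["rsfMRI"] = self.n_networks * (self.n_networks - 1) // 2
        return sizes

    def resolved_fractions(self) -> np.ndarray:
        if self.subtype_fractions is None:
            return np.full(self.n_subtypes, 1.0 / self.n_subtypes)
        f = np.asarray(self.subtype_fractions, dtype=float)
        return f

    def validate(self) -> None:
        if self.n_subjects < 2 * self.n_subtypes:
            raise ConfigError(
                f"n_subjects={self.n_subjects} < 2*n_subtypes={2 * self.n_subtypes}"
            )
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0 < self.aba_fraction < 1:
            raise ConfigError("aba_fraction must lie in (0, 1)")
        if not 0 <= self.block_noise_corr < 1:
            raise ConfigError("block_noise_corr must lie in [0, 1)")
        f = self.resolved_fractions()
        if len(f) != self.n_subtypes:
            raise ConfigError("subtype_fractions length != n_subtypes")
        if not np.all(f > 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ConfigError("subtype_fractions must be positive and sum to 1")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigError("age_range must be increasing")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    ``subtype_label`` maps subject ID -> subtype index in 1..K for
    flagged accelerated agers only.  ``offset_directions`` has unit rows
    (one per subtype) in standardized IDP space; ``age_slopes`` are the
    planted per-IDP slopes in raw units per year.
    """

    subtype_label: dict
    aba_flag: pd.Series
    offset_directions: np.ndarray
    age_slopes: np.ndarray
    idp_scale: np.ndarray | None = None  # per-IDP raw scale (SD-unit -> raw map)

    def labels_for(self, ids) -> np.ndarray:
        """Subtype labels (1..K) aligned to ``ids``; 0 for unflagged subjects."""
        return np.array([self.subtype_label.get(i, 0) for i in ids], dtype=int)


def plant_subtypes(
    n_subtypes: int, n_features: int, seed: int, orthogonal: bool = True
) -> np.ndarray:
    """K unit offset directions in feature space, orthonormalized by default.

    Draws Gaussian vectors and QR-orthonormalizes them, with a sign
    convention (first nonzero coordinate positive) for determinism.
    """
    if n_subtypes > n_features:
        raise ConfigError(
            f"n_subtypes={n_subtypes} exceeds n_features={n_features}"
        )
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_features, n_subtypes))
    if orthogonal:
        q, _ = np.linalg.qr(raw)
        directions = q[:, :n_subtypes].T
    else:
        directions = raw.T / np.linalg.norm(raw.T, axis=1, keepdims=True)
    for row in directions:
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if len(nz) and row[nz[0]] < 0:
            row *= -1.0
    return directions


def _build_schema(config: GeneratorConfig) -> CohortSchema:
    sizes = config.resolved_block_sizes()
    base = default_schema(n_networks=config.n_networks)
    if sizes == {k: len(v) for k, v in base.modality_blocks.items()}:
        return replace(base, age_range=config.age_range)
    # custom block sizes: generic column names
    blocks = {
        m: tuple(f"{m.lower()}_idp_{i:03d}" for i in range(1, n + 1))
        for m, n in sizes.items()
    }
    return replace(base, modality_blocks=blocks, age_range=config.age_range)


def generate_cohort(
    config: GeneratorConfig, schema: CohortSchema | None = None
) -> tuple[Cohort, GroundTruth]:
    """Draw a full synthetic cohort and its planted ground truth.

    Each IDP is ``baseline + scale * z`` where, on the standardized scale,

        z = slope*(age - midpoint) + sex_eff*(sex - 1/2)
            + edu_eff*(edu - mean_edu) + subtype offset + noise,

    noise combining an independent term with a shared modality-block
    factor.  Identical seeds yield bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    schema = schema if schema is not None else _build_schema(config)
    n = config.n_subjects
    k = config.n_subtypes
    idp_cols = schema.idp_columns
    p = len(idp_cols)

    ids = np.array([f"S{i:06d}" for i in range(1, n + 1)])
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    mid_age = 0.5 * (lo + hi)

    # planted accelerated-aging flags and subtype labels
    n_aba = int(round(config.aba_fraction * n))
    aba_idx = rng.choice(n, size=n_aba, replace=False)
    aba_flag = np.zeros(n, dtype=bool)
    aba_flag[aba_idx] = True
    labels = np.zeros(n, dtype=int)  # 0 = none, 1..K = subtype
    labels[aba_idx] = rng.choice(k, size=n_aba, p=config.resolved_fractions()) + 1
    severity = np.where(
        aba_flag, config.subtype_effect_size * labels / max(k, 1), 0.0
    )

    if config.confounded_covariates:
        # severity shifts sex balance and depresses education
        sex = (rng.random(n) < 0.5 + 0.1 * (severity > 0)).astype(int)
        edu = np.clip(np.round(rng.normal(16.0 - severity, 3.0)), 7, 22)
    else:
        sex = (rng.random(n) < 0.5).astype(int)
        edu = np.clip(np.round(rng.normal(16.0, 3.0, size=n)), 7, 22)

    # planted per-IDP structure (standardized scale)
    directions = plant_subtypes(
        k, p, seed=int(rng.integers(2**31)), orthogonal=config.orthogonal_subtypes
    )
    slopes_z = config.age_slope_scale * rng.normal(-1.0, 0.5, size=p)
    baseline = rng.normal(0.0, 1.0, size=p)
    scale = np.exp(rng.normal(0.0, 0.3, size=p))

    sex_eff, edu_eff = config.covariate_effects
    z = (
        np.outer(age - mid_age, slopes_z)
        + sex_eff * (sex - 0.5)[:, None]
        + edu_eff * (edu - edu.mean())[:, None]
    )
    # subtype offsets
    if n_aba:
        z[aba_flag] += config.subtype_effect_size * directions[labels[aba_flag] - 1]
    # block-correlated noise
    rho = config.block_noise_corr
    eps = rng.normal(size=(n, p))
    col = 0
    for modality, cols in schema.modality_blocks.items():
        b = len(cols)
        shared = rng.normal(size=n)
        eps[:, col : col + b] = (
            np.sqrt(1.0 - rho) * eps[:, col : col + b]
            + np.sqrt(rho) * shared[:, None]
        )
        col += b
    z += config.noise_sd * eps

    idps = baseline + scale * z

    # cognitive battery: scores decline with subtype severity; duration-valued
    # tests (reaction time, trail making) are generated on a positive scale.
    cog = {}
    cog_base = {
        "pairs_matching": 3.6,
        "numeric_memory": 6.8,
        "fluid_intelligence": 6.8,
        "paired_associate_learning": 7.2,
        "matrix_pattern_completion": 8.2,
        "symbol_digit_substitution": 19.6,
        "tower_rearranging": 10.0,
    }
    slope = config.cognitive_severity_slope
    for name in schema.cognitive_columns:
        if name in schema.log_transform_columns:
            # log-scale mean rises with severity (slower = worse)
            base = 6.3 if name == "reaction_time" else 5.5
            cog[name] = np.exp(
                base + 0.04 * slope * severity + 0.08 * rng.normal(size=n)
            )
        else:
            base = cog_base.get(name, 10.0)
            cog[name] = base - slope * severity + rng.normal(size=n)

    life = {
        "systolic_bp": rng.normal(135.0, 15.0, size=n) + 2.0 * severity,
        "driving_time": np.clip(rng.normal(60.0, 20.0, size=n), 0, None),
        "grip_strength_left": rng.normal(30.0, 8.0, size=n) - severity,
        "grip_strength_right": rng.normal(31.0, 8.0, size=n) - severity,
        "walking_pace": rng.integers(0, 3, size=n),
        "diabetes": (rng.random(n) < 0.05 + 0.02 * severity).astype(int),
    }

    table = {
        schema.id_column: ids,
        schema.age_column: age,
        schema.sex_column: sex,
        schema.education_column: edu.astype(int),
    }
    for j, c in enumerate(idp_cols):
        table[c] = idps[:, j]
    for name in schema.cognitive_columns:
        table[name] = cog[name]
    for name in schema.lifestyle_columns:
        table[name] = life.get(name, rng.normal(size=n))

    truth = GroundTruth(
        subtype_label={ids[i]: int(labels[i]) for i in np.flatnonzero(aba_flag)},
        aba_flag=pd.Series(aba_flag, index=ids),
        offset_directions=directions,
        age_slopes=scale * slopes_z,
        idp_scale=scale,
    )
    cohort = Cohort(schema, pd.DataFrame(table), dict(truth.subtype_label))
    return cohort, truth


def null_cohort(
    config: GeneratorConfig, schema: CohortSchema | None = None
) -> tuple[Cohort, GroundTruth]:
    """Same generative process with the subtype effect forced to zero.

    Labels are still drawn and emitted (they are uninformative), so null
    cohorts exercise the identical code path and randomness stream.
    """
    return generate_cohort(replace(config, subtype_effect_size=0.0), schema)
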