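"""Cohort tables: schema, validation, and delimited-text I/O.

A *cohort* is one row per subject: identifier, chronological age, sex,
years of education, imaging-derived phenotypes (IDPs) grouped into
modality blocks, a battery of cognitive scores, and lifestyle/health
variables.  The default schema mirrors a multimodal brain-imaging study
design: 207 structural (sMRI) features (139 regional gray-matter volumes
plus 68 cortical thicknesses), 144 diffusion (dMRI) tract means (48 FA,
48 MD, 48 ISOVF) and 210 resting-state (rsfMRI) partial-correlation
edges from 21 networks — 561 IDPs in total — alongside nine cognitive
tests and six lifestyle/physical-health variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "CohortValidationError",
    "CohortParseError",
    "CohortSchema",
    "Cohort",
    "default_schema",
    "read_cohort",
    "write_cohort",
    "filter_complete_cases",
]


class SchemaError(ValueError):
    """A column required by the schema is missing or misdeclared."""


class CohortValidationError(ValueError):
    """Table content violates a cohort invariant (duplicate IDs, bad ages...)."""


class CohortParseError(ValueError):
    """A cell could not be parsed as the type its column requires."""


# Sex is stored as an integer code throughout: 0 = female, 1 = male.
SEX_LEGEND = {0: "female", 1: "male"}

# Categorical lifestyle variables carry integer codes; legends documented here
# and serialized with the schema so output tables remain self-describing.
DEFAULT_CATEGORICAL_LEGEND: dict[str, dict[int, str]] = {
    "walking_pace": {0: "slow", 1: "steady", 2: "brisk"},
    "diabetes": {0: "no", 1: "yes"},
}


@dataclass(frozen=True)
class CohortSchema:
    """Declares every column of a cohort table and its role.

    ``modality_blocks`` maps modality name to the ordered list of IDP
    column names in that block.  ``log_transform_columns`` names the
    cognitive scores measured as durations, which downstream statistics
    log-transform before comparison.
    """

    id_column: str = "subject_id"
    age_column: str = "age"
    sex_column: str = "sex"
    education_column: str = "education_years"
    modality_blocks: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    cognitive_columns: tuple[str, ...] = ()
    lifestyle_columns: tuple[str, ...] = ()
    log_transform_columns: tuple[str, ...] = ()
    categorical_legend: Mapping[str, Mapping[int, str]] = field(default_factory=dict)
    age_range: tuple[float, float] = (45.0, 83.0)

    def __post_init__(self) -> None:
        roles: list[str] = [
            self.id_column,
            self.age_column,
            self.sex_column,
            self.education_column,
        ]
        for cols in self.modality_blocks.values():
            roles.extend(cols)
        roles.extend(self.cognitive_columns)
        roles.extend(self.lifestyle_columns)
        seen: set[str] = set()
        for name in roles:
            if name in seen:
                raise SchemaError(f"column {name!r} appears in two schema roles")
            seen.add(name)
        extra = set(self.log_transform_columns) - set(self.cognitive_columns)
        if extra:
            raise SchemaError(
                f"log_transform_columns not among cognitive columns: {sorted(extra)}"
            )

    @property
    def idp_columns(self) -> tuple[str, ...]:
        return tuple(
            itertools.chain.from_iterable(self.modality_blocks.values())
        )

    @property
    def covariate_columns(self) -> tuple[str, str, str]:
        return (self.age_column, self.sex_column, self.education_column)

    @property
    def all_columns(self) -> tuple[str, ...]:
        """Canonical column order used for every file this package writes."""
        return (
            self.id_column,
            self.age_column,
            self.sex_column,
            self.education_column,
            *self.idp_columns,
            *self.cognitive_columns,
            *self.lifestyle_columns,
        )

    def block_of(self, column: str) -> str:
        for modality, cols in self.modality_blocks.items():
            if column in cols:
                return modality
        raise SchemaError(f"{column!r} is not an IDP column")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id_column": self.id_column,
            "age_column": self.age_column,
            "sex_column": self.sex_column,
            "education_column": self.education_column,
            "modality_blocks": {k: list(v) for k, v in self.modality_blocks.items()},
            "cognitive_columns": list(self.cognitive_columns),
            "lifestyle_columns": list(self.lifestyle_columns),
            "log_transform_columns": list(self.log_transform_columns),
            "categorical_legend": {
                k: {int(c): lab for c, lab in v.items()}
                for k, v in self.categorical_legend.items()
            },
            "age_range": list(self.age_range),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSchema":
        return cls(
            id_column=d["id_column"],
            age_column=d["age_column"],
            sex_column=d["sex_column"],
            education_column=d["education_column"],
            modality_blocks={k: tuple(v) for k, v in d["modality_blocks"].items()},
            cognitive_columns=tuple(d["cognitive_columns"]),
            lifestyle_columns=tuple(d["lifestyle_columns"]),
            log_transform_columns=tuple(d["log_transform_columns"]),
            categorical_legend={
                k: {int(c): lab for c, lab in v.items()}
                for k, v in d.get("categorical_legend", {}).items()
            },
            age_range=tuple(d.get("age_range", (45.0, 83.0))),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_schema(n_networks: int = 21) -> CohortSchema:
    """The default multimodal schema: 207 sMRI + 144 dMRI + 210 rsfMRI IDPs.

    rsfMRI edges are the upper triangle of an ``n_networks`` × ``n_networks``
    partial-correlation matrix, n(n-1)/2 columns.
    """
    smri = tuple(f"smri_gmv_{i:03d}" for i in range(1, 140)) + tuple(
        f"smri_ct_{i:03d}" for i in range(1, 69)
    )
    dmri = (
        tuple(f"dmri_fa_{i:02d}" for i in range(1, 49))
        + tuple(f"dmri_md_{i:02d}" for i in range(1, 49))
        + tuple(f"dmri_isovf_{i:02d}" for i in range(1, 49))
    )
    rsfmri = tuple(
        f"rsfmri_edge_{a:02d}_{b:02d}"
        for a in range(1, n_networks + 1)
        for b in range(a + 1, n_networks + 1)
    )
    cognitive = (
        "pairs_matching",
        "numeric_memory",
        "fluid_intelligence",
        "paired_associate_learning",
        "matrix_pattern_completion",
        "reaction_time",
        "symbol_digit_substitution",
        "tower_rearranging",
        "trail_making",
    )
    lifestyle = (
        "systolic_bp",
        "driving_time",
        "grip_strength_left",
        "grip_strength_right",
        "walking_pace",
        "diabetes",
    )
    return CohortSchema(
        modality_blocks={"sMRI": smri, "dMRI": dmri, "rsfMRI": rsfmri},
        cognitive_columns=cognitive,
        lifestyle_columns=lifestyle,
        log_transform_columns=("reaction_time", "trail_making"),
        categorical_legend=DEFAULT_CATEGORICAL_LEGEND,
    )


@dataclass
class Cohort:
    """A validated subject table plus, for synthetic cohorts, planted truth.

    ``truth_labels`` maps subject ID -> planted subtype index (1-based)
    for subjects carrying a planted accelerated-aging offset.
    """

    schema: CohortSchema
    data: pd.DataFrame
    truth_labels: dict | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        s = self.schema
        missing = [c for c in s.all_columns if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table lacks schema column(s): {missing}")
        ids = self.data[s.id_column]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise CohortValidationError(f"duplicate subject IDs: {dupes[:5]}")
        ages = self.data[s.age_column].to_numpy(dtype=float)
        lo, hi = s.age_range
        if len(ages) and (np.nanmin(ages) < lo or np.nanmax(ages) > hi):
            raise CohortValidationError(
                f"ages outside declared range [{lo}, {hi}]"
            )
        # canonical column order
        self.data = self.data.loc[:, list(s.all_columns)].reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> pd.Series:
        return self.data[self.schema.id_column]

    def idp_matrix(self, modality: str | None = None) -> np.ndarray:
        cols = (
            self.schema.idp_columns
            if modality is None
            else self.schema.modality_blocks[modality]
        )
        return self.data.loc[:, list(cols)].to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        """Columns: age, sex, education (the nuisance covariates)."""
        return self.data.loc[:, list(self.schema.covariate_columns)].to_numpy(
            dtype=float
        )

    def subset(self, mask_or_index) -> "Cohort":
        sub = self.data.loc[mask_or_index]
        labels = None
        if self.truth_labels is not None:
            kept = set(sub[self.schema.id_column])
            labels = {k: v for k, v in self.truth_labels.items() if k in kept}
        return Cohort(self.schema, sub.copy(), labels)


_DELIMITERS = {".csv": ",", ".tsv": "\t"}


def _sep_for(path: Path) -> str:
    try:
        return _DELIMITERS[path.suffix.lower()]
    except KeyError:
        raise ValueError(
            f"unsupported extension {path.suffix!r}: use .csv or .tsv"
        ) from None


def read_cohort(
    path: str | Path, schema: CohortSchema, truth_labels: dict | None = None
) -> Cohort:
    """Read and validate a delimited cohort table.

    Empty cells and the literal ``NA`` are read as missing.  IDP,
    cognitive and covariate columns must parse as numbers; the first
    offending cell is reported with its row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        na_values=["NA"],
        keep_default_na=True,
        dtype={schema.id_column: str},
    )
    missing = [c for c in schema.all_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name} lacks schema column(s): {missing}")
    numeric_cols = (
        (schema.age_column, schema.sex_column, schema.education_column)
        + schema.idp_columns
        + schema.cognitive_columns
        + schema.lifestyle_columns
    )
    for col in numeric_cols:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortParseError(
                    f"non-numeric value {df[col].iloc[row]!r} in column "
                    f"{col!r}, row {row}"
                )
            df[col] = coerced
    return Cohort(schema, df, truth_labels)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write the cohort as delimited text; floats keep full (round-trip) precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = cohort.data.loc[:, list(cohort.schema.all_columns)]
    # pandas serializes floats with repr round-trip precision by default
    df.to_csv(path, sep=_sep_for(path), index=False, na_rep="")
    return path


def filter_complete_cases(cohort: Cohort, required: Sequence[str]) -> Cohort:
    """Keep only rows with no missing value in any ``required`` column."""
    known = set(cohort.data.columns)
    unknown = [c for c in required if c not in known]
    if unknown:
        raise SchemaError(f"unknown column(s) in completeness filter: {unknown}")
    mask = cohort.data.loc[:, list(required)].notna().all(axis=1)
    return cohort.subset(mask)
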