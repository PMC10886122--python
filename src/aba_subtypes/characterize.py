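"""Subtype characterization statistics.

Every IDP is expressed as a Z-score against the resilient (RBA)
reference group — whose Z is 0 by construction — and compared across
groups with a one-way ANOVA on covariate-adjusted values, Bonferroni-
controlled across all IDPs at a family threshold q (default 0.01).
Cognitive scores (duration-valued tests log-transformed first) are
compared by ANOVA plus Dunnett many-to-one tests against a reference
group, and categorical lifestyle variables by chi-square tests on
group-by-category contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CharacterizeError",
    "SubtypeReport",
    "zscore_vs_reference",
    "adjust_covariates_glm",
    "anova_idps",
    "compare_cognitive",
    "compare_qualitative",
    "characterize_subtypes",
]


class CharacterizeError(ValueError):
    pass


def zscore_vs_reference(values: np.ndarray, reference_values: np.ndarray) -> np.ndarray:
    """(value - reference mean) / reference SD."""
    values = np.asarray(values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if ref.size < 2:
        raise CharacterizeError("reference group needs at least 2 values")
    sd = ref.std(ddof=0)
    if sd <= 0:
        raise CharacterizeError("reference group is constant (SD = 0)")
    return (values - ref.mean()) / sd


def adjust_covariates_glm(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of an all-groups-pooled least-squares fit on the covariates.

    ``values`` may be a vector or an (n, p) matrix; the design always
    includes an intercept, so residual means are 0.
    """
    v = np.asarray(values, dtype=float)
    Z = np.asarray(covariates, dtype=float)
    if np.isnan(v).any() or np.isnan(Z).any():
        raise CharacterizeError("missing values not allowed")
    design = np.column_stack([np.ones(len(Z)), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CharacterizeError("covariate design is rank deficient")
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def _group_arrays(values: np.ndarray, groups: np.ndarray, order: list) -> list[np.ndarray]:
    return [np.asarray(values)[groups == g] for g in order]


def anova_idps(
    frame: pd.DataFrame,
    group_labels: pd.Series | np.ndarray,
    idp_columns: Sequence[str],
    covariates: np.ndarray | None = None,
    reference: str = "RBA",
    q_threshold: float = 0.01,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-IDP group comparison: Z vs reference, ANOVA, Bonferroni flags.

    Returns one row per IDP with, per group, the mean Z against the
    reference (computed on covariate-adjusted values when ``adjust``)
    and its 95% CI half-width, plus the ANOVA p-value and a flag set
    when p < q_threshold / m with m = number of IDPs tested.
    """
    groups = np.asarray(group_labels)
    order = [reference] + sorted(set(groups) - {reference})
    for g in order:
        if np.sum(groups == g) < 2:
            raise CharacterizeError(f"group {g!r} has fewer than 2 subjects")
    X = frame.loc[:, list(idp_columns)].to_numpy(dtype=float)
    if adjust:
        if covariates is None:
            raise CharacterizeError("covariates required when adjust=True")
        X = adjust_covariates_glm(X, covariates)

    m = len(idp_columns)
    cutoff = q_threshold / m
    ref_mask = groups == reference
    ref_mean = X[ref_mask].mean(axis=0)
    ref_sd = X[ref_mask].std(axis=0, ddof=0)
    if np.any(ref_sd <= 0):
        raise CharacterizeError("constant reference IDP encountered")
    Z = (X - ref_mean) / ref_sd

    # vectorized one-way ANOVA across all IDPs at once
    f_stat, p_val = stats.f_oneway(*_group_arrays(X, groups, order), axis=0)

    out: dict[str, np.ndarray] = {"idp": np.asarray(list(idp_columns))}
    for g in order:
        zg = Z[groups == g]
        out[f"mean_z_{g}"] = zg.mean(axis=0)
        out[f"ci95_halfwidth_{g}"] = 1.96 * zg.std(axis=0, ddof=1) / np.sqrt(len(zg))
    out["anova_F"] = f_stat
    out["anova_p"] = p_val
    out["significant"] = p_val < cutoff
    table = pd.DataFrame(out)
    table.attrs["bonferroni_cutoff"] = cutoff
    table.attrs["n_tests"] = m
    return table


def compare_cognitive(
    frame: pd.DataFrame,
    group_labels: pd.Series | np.ndarray,
    cognitive_columns: Sequence[str],
    log_columns: Sequence[str] = (),
    alpha: float = 0.05,
    reference: str = "RBA",
    random_state: int = 0,
) -> pd.DataFrame:
    """ANOVA plus Dunnett contrasts for the cognitive battery.

    Duration-valued scores in ``log_columns`` are natural-log
    transformed first (values must be strictly positive).  Dunnett
    many-to-one p-values are reported for each non-reference group
    against ``reference``, and additionally for every pair of
    non-reference groups (the lower-sorted group acting as the control
    in its own Dunnett family).
    """
    groups = np.asarray(group_labels)
    names = sorted(set(groups))
    if reference not in names:
        raise CharacterizeError(f"reference group {reference!r} absent")
    others = [g for g in names if g != reference]
    rows = []
    for col in cognitive_columns:
        v = frame[col].to_numpy(dtype=float)
        if col in log_columns:
            bad = np.flatnonzero(v <= 0)
            if len(bad):
                raise CharacterizeError(
                    f"non-positive value in log column {col!r} at row {bad[0]}"
                )
            v = np.log(v)
        samples = {g: v[groups == g] for g in names}
        f_stat, p_val = stats.f_oneway(*[samples[g] for g in names])
        row: dict = {"test": col, "anova_F": f_stat, "anova_p": p_val}
        for g in names:
            row[f"mean_{g}"] = samples[g].mean()
        # many-to-one against the declared reference
        res = stats.dunnett(
            *[samples[g] for g in others],
            control=samples[reference],
            random_state=random_state,
        )
        for g, p in zip(others, res.pvalue):
            row[f"dunnett_p_{g}_vs_{reference}"] = float(p)
            row[f"flag_{g}_vs_{reference}"] = bool(p < alpha)
        # pairwise contrasts among the non-reference groups
        for i, gi in enumerate(others):
            rest = others[i + 1 :]
            if not rest:
                continue
            res2 = stats.dunnett(
                *[samples[g] for g in rest],
                control=samples[gi],
                random_state=random_state,
            )
            for g, p in zip(rest, res2.pvalue):
                row[f"dunnett_p_{g}_vs_{gi}"] = float(p)
                row[f"flag_{g}_vs_{gi}"] = bool(p < alpha)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_qualitative(
    frame: pd.DataFrame,
    group_labels: pd.Series | np.ndarray,
    qualitative_columns: Sequence[str],
) -> pd.DataFrame:
    """Chi-square homogeneity test per categorical variable."""
    groups = np.asarray(group_labels)
    names = sorted(set(groups))
    rows = []
    for col in qualitative_columns:
        v = frame[col]
        cats = sorted(v.dropna().unique())
        if len(cats) < 2:
            raise CharacterizeError(f"variable {col!r} has a single category")
        table = np.array(
            [[int(np.sum((groups == g) & (v == c))) for c in cats] for g in names]
        )
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        row = {"variable": col, "chi2": float(chi2), "p": float(p), "dof": int(dof)}
        for g, counts in zip(names, table):
            row[f"counts_{g}"] = "|".join(str(c) for c in counts)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SubtypeReport:
    """The three characterization tables for one subtyping solution."""

    idp_table: pd.DataFrame
    cognitive_table: pd.DataFrame
    qualitative_table: pd.DataFrame

    def summary(self) -> dict:
        return {
            "n_idps_tested": int(self.idp_table.attrs.get("n_tests", len(self.idp_table))),
            "bonferroni_cutoff": float(self.idp_table.attrs.get("bonferroni_cutoff", np.nan)),
            "n_significant_idps": int(self.idp_table["significant"].sum()),
            "n_cognitive_tests": int(len(self.cognitive_table)),
            "n_qualitative_variables": int(len(self.qualitative_table)),
        }


def characterize_subtypes(
    cohort,
    group_labels: pd.Series,
    q_threshold: float = 0.01,
    alpha: float = 0.05,
    reference: str = "RBA",
    adjust: bool = True,
    random_state: int = 0,
) -> SubtypeReport:
    """Full characterization of an RBA + subtypes labeling of a cohort.

    ``group_labels`` is indexed by subject ID and covers the subjects to
    compare (the reference group plus each subtype).
    """
    schema = cohort.schema
    sub = cohort.data.set_index(schema.id_column).loc[group_labels.index]
    groups = group_labels.to_numpy()
    covs = sub.loc[:, list(schema.covariate_columns)].to_numpy(dtype=float)
    idp_table = anova_idps(
        sub,
        groups,
        schema.idp_columns,
        covariates=covs,
        reference=reference,
        q_threshold=q_threshold,
        adjust=adjust,
    )
    cognitive = compare_cognitive(
        sub,
        groups,
        schema.cognitive_columns,
        log_columns=schema.log_transform_columns,
        alpha=alpha,
        reference=reference,
        random_state=random_state,
    )
    qual_cols = [c for c in schema.lifestyle_columns if c in schema.categorical_legend]
    quant_cols = [c for c in schema.lifestyle_columns if c not in schema.categorical_legend]
    qualitative = compare_qualitative(sub, groups, qual_cols)
    if quant_cols:
        extra = compare_cognitive(
            sub, groups, quant_cols, alpha=alpha, reference=reference,
            random_state=random_state,
        )
        cognitive = pd.concat([cognitive, extra], ignore_index=True)
    return SubtypeReport(idp_table, cognitive, qualitative)
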