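"""Variable filtering, scaling and missing-value imputation.

Imputation follows a two-tier rule: a (variable, stratum) pair with exactly
one missing cell gets the stratum mean; anything with more missing cells
goes through bootstrapped regression predictive mean matching (PMM), where
each missing case receives the observed value of one of its K
nearest-prediction donors, drawn at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phenodisc._random import substream
from phenodisc.errors import (
    DegenerateDependentError,
    EmptyStratumError,
    ImputationError,
    ZeroVarianceError,
)
from phenodisc.tabular_io import PhenoTable, TYPE_QUAL, TYPE_QUANT

SMALL_STRATUM = 10


@dataclass
class ImputationSpec:
    """Settings for predictive-mean-matching imputation."""

    method: str = "pmm"
    k_donors: int = 5
    n_bootstrap: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("group_mean", "pmm"):
            raise ImputationError(f"unknown imputation method {self.method!r}")
        if self.k_donors < 1 or self.n_bootstrap < 1:
            raise ImputationError("k_donors and n_bootstrap must be >= 1")


def drop_low_information(table: PhenoTable) -> tuple[PhenoTable, list[str]]:
    """Remove variables that cannot inform any analysis.

    Quantitative variables need at least 3 unique non-missing values;
    qualitative variables need at least 2 observed levels.  The dependent
    variable is never removed — if it fails the rule that is an error.
    """
    dep = table.dependent
    if table.values[dep].dropna().nunique() < 2:
        raise DegenerateDependentError(f"dependent variable {dep!r} has fewer than two levels")
    removed: list[str] = []
    for col in table.values.columns:
        if col == dep:
            continue
        observed = table.values[col].dropna()
        if table.var_types[col] == TYPE_QUANT and observed.nunique() < 3:
            removed.append(col)
        elif table.var_types[col] == TYPE_QUAL and observed.nunique() < 2:
            removed.append(col)
    return (table.drop_variables(removed) if removed else table.copy()), removed


def scale_features(table: PhenoTable) -> PhenoTable:
    """Standardize every quantitative column to mean 0, unit sample SD.

    Qualitative columns are untouched.  The centering/scaling constants are
    kept on the returned table (``.scaling``) so that group summaries can be
    reported on the original scale.  Must run after imputation.
    """
    out = table.copy()
    quant = out.variables_of_type(TYPE_QUANT)
    if quant and out.values[quant].isna().any().any():
        bad = [c for c in quant if out.values[c].isna().any()]
        raise ImputationError(f"missing values remain at scaling stage in: {bad}")
    constants = {}
    for col in quant:
        x = out.values[col].astype(float)
        mean, sd = float(x.mean()), float(x.std(ddof=1))
        if sd <= 0 or not np.isfinite(sd):
            raise ZeroVarianceError(f"column {col!r} has zero variance")
        out.values[col] = (x - mean) / sd
        constants[col] = (mean, sd)
    out.scaling = pd.DataFrame(constants, index=["mean", "sd"]).T  # type: ignore[attr-defined]
    return out


def _strata(table: PhenoTable, conditioning: list[str]) -> pd.Series:
    if not conditioning:
        return pd.Series("all", index=table.values.index)
    return table.values[conditioning].astype(str).agg("|".join, axis=1)


def impute_group_mean(
    table: PhenoTable, conditioning: list[str] | None = None
) -> PhenoTable:
    """Fill single missing cells with their conditioning-stratum mean.

    Applies only to (quantitative variable, stratum) pairs with exactly one
    missing cell; pairs with more are left for PMM.  A stratum whose values
    are all missing for some variable is an error.  Strata smaller than 10
    individuals trigger a warning, not an error.
    """
    out = table.copy()
    conditioning = conditioning if conditioning is not None else table.conditioning
    strata = _strata(out, conditioning)
    counts = strata.value_counts()
    small = counts[counts < SMALL_STRATUM]
    if len(small):
        warnings.warn(
            f"conditioning strata with <{SMALL_STRATUM} individuals: "
            f"{dict(small)} — imputation is unreliable at this size",
            stacklevel=2,
        )
    for col in out.variables_of_type(TYPE_QUANT):
        series = out.values[col]
        for stratum, idx in series.groupby(strata).groups.items():
            chunk = series.loc[idx]
            n_missing = int(chunk.isna().sum())
            if n_missing == len(chunk) and len(chunk):
                raise EmptyStratumError(
                    f"stratum {stratum!r} has no observed values for {col!r}"
                )
            if n_missing != 1:
                continue
            target = chunk.index[chunk.isna()][0]
            out.values.loc[target, col] = chunk.mean()
            out.imputed_mask.loc[target, col] = True
    return out


def impute_pmm(table: PhenoTable, spec: ImputationSpec) -> PhenoTable:
    """Bootstrapped regression predictive-mean-matching imputation.

    For each missing cell, per bootstrap round: resample the complete cases,
    fit a linear additive regression of the target on every other variable
    (qualitative ones one-hot encoded), find the K complete cases whose
    predictions are closest to the missing case's prediction, and draw one
    donor's observed value at random.  Rounds are averaged for quantitative
    targets; qualitative targets take the modal donor category.  Variables
    are processed in increasing order of missingness so earlier completions
    feed later fits.  A donor log is attached as ``.imputation_log``.
    """
    out = table.copy()
    log_rows: list[dict] = []
    missing_counts = out.values.isna().sum()
    targets = [c for c in out.values.columns if missing_counts[c] > 0]
    targets.sort(key=lambda c: (missing_counts[c], list(out.values.columns).index(c)))

    for col in targets:
        series = out.values[col]
        obs_idx = series.index[series.notna()]
        mis_idx = series.index[series.isna()]
        if len(obs_idx) < spec.k_donors:
            raise ImputationError(
                f"{col!r}: {len(obs_idx)} complete cases < K={spec.k_donors}"
            )
        design = _design_matrix(out, exclude=col)
        if design.shape[1] == 0:
            raise ImputationError(f"no complete predictor columns available for {col!r}")
        rng = substream(spec.seed, f"pmm/{col}")
        is_quant = out.var_types[col] == TYPE_QUANT

        X_obs = design.loc[obs_idx].to_numpy(dtype=float)
        X_mis = design.loc[mis_idx].to_numpy(dtype=float)
        y_obs_raw = series.loc[obs_idx]
        # qualitative targets are regressed through integer level codes;
        # only the donor MATCHING uses predictions, the imputed value is
        # always a donor's observed category/value
        y_obs = (
            y_obs_raw.to_numpy(dtype=float)
            if is_quant
            else pd.Categorical(y_obs_raw).codes.astype(float)
        )

        draws: dict[object, list] = {i: [] for i in mis_idx}
        donor_sets: dict[object, list] = {i: [] for i in mis_idx}
        for b in range(spec.n_bootstrap):
            boot = rng.integers(0, len(obs_idx), size=len(obs_idx))
            beta = _fit_linear(X_obs[boot], y_obs[boot])
            pred_obs = _predict(X_obs, beta)
            pred_mis = _predict(X_mis, beta)
            for row_pos, row_id in enumerate(mis_idx):
                dist = np.abs(pred_obs - pred_mis[row_pos])
                donor_pos = np.argsort(dist, kind="stable")[: spec.k_donors]
                pick = donor_pos[rng.integers(0, len(donor_pos))]
                donor_id = obs_idx[pick]
                draws[row_id].append(y_obs_raw.loc[donor_id])
                donor_sets[row_id].append(donor_id)

        for row_id in mis_idx:
            vals = draws[row_id]
            if is_quant:
                final = float(np.mean([float(v) for v in vals]))
            else:
                final = pd.Series(vals).mode().iloc[0]
            out.values.loc[row_id, col] = final
            out.imputed_mask.loc[row_id, col] = True
            log_rows.append(
                {
                    "row_id": row_id,
                    "variable": col,
                    "method": "pmm",
                    "n_rounds": spec.n_bootstrap,
                    "donor_ids": ";".join(str(d) for d in donor_sets[row_id]),
                    "round_values": ";".join(str(v) for v in vals),
                    "final_value": final,
                }
            )

    out.imputation_log = pd.DataFrame(  # type: ignore[attr-defined]
        log_rows,
        columns=[
            "row_id", "variable", "method", "n_rounds",
            "donor_ids", "round_values", "final_value",
        ],
    )
    return out


def _design_matrix(table: PhenoTable, exclude: str) -> pd.DataFrame:
    """One-hot design from every fully observed column except ``exclude``."""
    parts = []
    for col in table.values.columns:
        if col == exclude or table.values[col].isna().any():
            continue
        if table.var_types[col] == TYPE_QUANT:
            parts.append(table.values[[col]].astype(float))
        else:
            parts.append(
                pd.get_dummies(table.values[col].astype(str), prefix=col, prefix_sep="=")
                .astype(float)
                .iloc[:, 1:]  # drop one level to avoid exact collinearity
            )
    if not parts:
        return pd.DataFrame(index=table.values.index)
    return pd.concat(parts, axis=1)


def _fit_linear(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    X1 = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    return beta


def _predict(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X]) @ beta
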