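"""Feature pre-selection: high-correlation removal and the 30%-contribution rule.

Three predictor sets ("models") flow out of this module: *full* (everything
that survived low-information filtering), *decorrelated* (no pair with
|r| above the analyst threshold, default 0.75), and *sel30* (variables whose
association with the first three factor dimensions reaches the contribution
threshold, default 0.30).  The sets nest: sel30 is a subset of decorrelated,
which is a subset of full.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from phenodisc.errors import ConfigError
from phenodisc.factor_core import FactorResult
from phenodisc.tabular_io import PhenoTable, TYPE_QUAL, TYPE_QUANT


@dataclass
class SelectionReport:
    correlation: pd.DataFrame  # r values (quant-quant, quant-binary)
    pvalues: pd.DataFrame  # two-sided p per r
    cramers_v: pd.DataFrame  # qualitative-qualitative association (informative)
    flagged_pairs: pd.DataFrame = None  # type: ignore[assignment]
    removed: dict[str, str] = field(default_factory=dict)
    kept: list[str] = field(default_factory=list)
    contributions: pd.DataFrame = None  # type: ignore[assignment]
    model_sets: dict[str, list[str]] = field(default_factory=dict)

    def to_selection_frame(self) -> pd.DataFrame:
        """One row per variable with model-membership flags."""
        variables = sorted(
            set(self.model_sets.get("full", []))
            | set(self.correlation.index.tolist())
        )
        rows = []
        for v in variables:
            rows.append(
                {
                    "variable": v,
                    "in_full": v in self.model_sets.get("full", []),
                    "in_decorrelated": v in self.model_sets.get("decorrelated", []),
                    "in_sel30": v in self.model_sets.get("sel30", []),
                    "removal_reason": self.removed.get(v, ""),
                }
            )
        return pd.DataFrame(rows)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        return np.nan, np.nan
    if np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x[mask], y[mask])
    return float(r), float(p)


def _cramers_v(a: pd.Series, b: pd.Series) -> float:
    tab = pd.crosstab(a, b)
    if tab.size == 0 or min(tab.shape) < 2:
        return np.nan
    chi2 = stats.chi2_contingency(tab, correction=False)[0]
    n = tab.to_numpy().sum()
    k = min(tab.shape) - 1
    return float(np.sqrt(chi2 / (n * k))) if n * k > 0 else np.nan


def correlation_matrix(table: PhenoTable) -> SelectionReport:
    """Pairwise association among predictor variables.

    Pearson r for quantitative pairs, point-biserial r (Pearson on a 0/1
    coding) for quantitative vs binary qualitative, each with its two-sided
    p-value.  Qualitative-qualitative pairs get Cramér's V, reported for
    information only and never used for removal decisions.
    """
    predictors = table.predictors
    numericized: dict[str, np.ndarray] = {}
    for col in predictors:
        if table.var_types[col] == TYPE_QUANT:
            numericized[col] = table.values[col].astype(float).to_numpy()
        else:
            levels = table.values[col].dropna().unique()
            if len(levels) == 2:  # binary qualitative -> 0/1 coding
                coding = {levels[0]: 0.0, levels[1]: 1.0}
                numericized[col] = table.values[col].map(coding).astype(float).to_numpy()

    corr = pd.DataFrame(np.nan, index=predictors, columns=predictors)
    pvals = pd.DataFrame(np.nan, index=predictors, columns=predictors)
    quals = [c for c in predictors if table.var_types[c] == TYPE_QUAL]
    cramers = pd.DataFrame(np.nan, index=quals, columns=quals)

    for i, a in enumerate(predictors):
        corr.loc[a, a] = 1.0
        pvals.loc[a, a] = 0.0
        for b in predictors[i + 1 :]:
            # r only when at least one member is quantitative; qualitative
            # pairs are assessed by Cramér's V and never drive removal
            both_qual = a in quals and b in quals
            if a in numericized and b in numericized and not both_qual:
                r, p = _pearson(numericized[a], numericized[b])
                corr.loc[a, b] = corr.loc[b, a] = r
                pvals.loc[a, b] = pvals.loc[b, a] = p
    for i, a in enumerate(quals):
        cramers.loc[a, a] = 1.0
        for b in quals[i + 1 :]:
            v = _cramers_v(table.values[a], table.values[b])
            cramers.loc[a, b] = cramers.loc[b, a] = v

    return SelectionReport(correlation=corr, pvalues=pvals, cramers_v=cramers)


def flag_pairs(report: SelectionReport, threshold: float) -> pd.DataFrame:
    """All pairs with |r| > threshold, symmetric-deduplicated, sorted by |r|."""
    rows = []
    cols = list(report.correlation.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = report.correlation.loc[a, b]
            if pd.notna(r) and abs(r) > threshold:
                rows.append({"var1": a, "var2": b, "r": float(r),
                             "p": float(report.pvalues.loc[a, b])})
    flagged = pd.DataFrame(rows, columns=["var1", "var2", "r", "p"])
    return flagged.sort_values("r", key=np.abs, ascending=False, kind="stable").reset_index(drop=True)


def remove_correlated(
    report: SelectionReport,
    threshold: float,
    protected: tuple[str, ...] = (),
) -> list[str]:
    """Greedy removal of highly correlated variables; returns the kept set.

    While any pair exceeds the threshold, take the worst pair and drop the
    member with the larger mean absolute correlation to all remaining
    variables (ties broken by column order: the later column goes).
    Conditioning variables listed in ``protected`` are never auto-removed;
    if both members of a flagged pair are protected the pair is logged and
    left alone.
    """
    corr = report.correlation.abs()
    order = {v: i for i, v in enumerate(corr.columns)}
    alive = list(corr.columns)
    ignored_pairs: set[frozenset] = set()
    removed: dict[str, str] = {}

    while True:
        sub = corr.loc[alive, alive].copy()
        np.fill_diagonal(sub.values, np.nan)
        best_r, best_pair = -np.inf, None
        for i, a in enumerate(alive):
            for b in alive[i + 1 :]:
                r = sub.loc[a, b]
                if pd.isna(r) or frozenset((a, b)) in ignored_pairs:
                    continue
                if r > threshold and r > best_r:
                    best_r, best_pair = r, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        if a in protected and b in protected:
            ignored_pairs.add(frozenset((a, b)))
            continue
        if a in protected:
            victim = b
        elif b in protected:
            victim = a
        else:
            mean_a = sub.loc[a].mean(skipna=True)
            mean_b = sub.loc[b].mean(skipna=True)
            if np.isclose(mean_a, mean_b):
                victim = a if order[a] > order[b] else b
            else:
                victim = a if mean_a > mean_b else b
        alive.remove(victim)
        removed[victim] = f"|r|={best_r:.3f} with {a if victim == b else b}"

    report.flagged_pairs = flag_pairs(report, threshold)
    report.removed.update(removed)
    report.kept = alive
    return alive


def select_contributing(
    mfa: FactorResult,
    threshold: float,
    n_dims: int,
    exclude: tuple[str, ...] = (),
) -> list[str]:
    """Variables associated with the leading dimensions above the threshold.

    A quantitative variable is selected iff its maximum |correlation| with
    dimensions 1..n_dims reaches the threshold; a qualitative variable iff
    its maximum squared loading (the correlation ratio eta^2) reaches the
    squared threshold.  Names in ``exclude`` (the dependent variable) are
    evaluated for reporting but never returned.
    """
    if not (0.0 < threshold < 1.0):
        raise ConfigError("contribution threshold must be in (0, 1)")
    k = min(n_dims, mfa.rank)
    dim_cols = list(mfa.squared_loadings.columns[:k])

    selected = []
    for var in mfa.squared_loadings.index:
        if var in mfa.quant_correlations.index:
            score = mfa.quant_correlations.loc[var, dim_cols].abs().max()
            hit = score >= threshold
        else:
            score = mfa.squared_loadings.loc[var, dim_cols].max()
            hit = score >= threshold**2
        if hit and var not in exclude:
            selected.append(var)
    return selected


def contribution_table(mfa: FactorResult, n_dims: int) -> pd.DataFrame:
    """Per-variable max |correlation| / max squared loading on dims 1..n_dims."""
    k = min(n_dims, mfa.rank)
    dim_cols = list(mfa.squared_loadings.columns[:k])
    rows = []
    for var in mfa.squared_loadings.index:
        if var in mfa.quant_correlations.index:
            rows.append(
                {"variable": var, "kind": TYPE_QUANT,
                 "max_abs_correlation": float(mfa.quant_correlations.loc[var, dim_cols].abs().max()),
                 "max_squared_loading": float(mfa.squared_loadings.loc[var, dim_cols].max())}
            )
        else:
            sq = float(mfa.squared_loadings.loc[var, dim_cols].max())
            rows.append(
                {"variable": var, "kind": TYPE_QUAL,
                 "max_abs_correlation": float(np.sqrt(sq)),
                 "max_squared_loading": sq}
            )
    return pd.DataFrame(rows)
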