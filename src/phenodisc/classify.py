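"""Importance-ranking classifiers and group summaries.

Four classifiers are fit on each model's predictor set: a binary logistic
GLM, a multinomial log-linear model, an elastic net tuned over (alpha,
lambda), and a random forest.  Each yields per-class raw variable
importances rescaled so the most important variable scores exactly 100.
The importance definitions (the source tooling never states them) are:
|z| of the coefficient for the GLM, per-class |standardized coefficient|
for the multinomial and elastic-net models, and mean decrease in impurity
for the forest; qualitative predictors take the maximum over their dummy
columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from phenodisc._random import substream, substream_seed
from phenodisc.errors import ConfigError, ConvergenceError
from phenodisc.tabular_io import PhenoTable, TYPE_QUAL, TYPE_QUANT


@dataclass
class ImportanceTable:
    """Long-format importances: one row per (class, variable)."""

    classifier: str
    frame: pd.DataFrame  # columns: class, variable, raw, scaled
    accuracy: float = np.nan
    accuracy_sd: float = np.nan
    tuning: dict = field(default_factory=dict)

    def scaled_matrix(self) -> pd.DataFrame:
        return self.frame.pivot(index="variable", columns="class", values="scaled")


@dataclass
class GroupSummary:
    frame: pd.DataFrame  # columns: stratum, variable, n, mean, sd, se, ci_low, ci_high


# ---------------------------------------------------------------------------
# encoding and scaling helpers


def _var_kinds(X: pd.DataFrame) -> dict[str, str]:
    return {
        c: TYPE_QUANT if pd.api.types.is_numeric_dtype(X[c]) else TYPE_QUAL
        for c in X.columns
    }


def encode_predictors(X: pd.DataFrame, drop_first: bool = True) -> tuple[pd.DataFrame, dict[str, str]]:
    """One-hot encode qualitative columns; returns (matrix, column -> variable)."""
    kinds = _var_kinds(X)
    parts, owner = [], {}
    for col in X.columns:
        if kinds[col] == TYPE_QUANT:
            parts.append(X[[col]].astype(float))
            owner[col] = col
        else:
            dummies = pd.get_dummies(X[col].astype(str), prefix=col, prefix_sep="=").astype(float)
            if drop_first and dummies.shape[1] > 1:
                dummies = dummies.iloc[:, 1:]
            for d in dummies.columns:
                owner[d] = col
            parts.append(dummies)
    mat = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=X.index)
    return mat, owner


def scale_to_100(raw: pd.Series) -> pd.Series:
    """Rescale so the maximum is exactly 100; an all-zero vector stays zero."""
    top = raw.abs().max()
    if not np.isfinite(top) or top == 0:
        return raw * 0.0
    return 100.0 * raw.abs() / top


def _collapse(
    raw_cols: pd.Series,
    owner: dict[str, str],
    variables: list[str],
    mat: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-variable importance = max over the variable's encoded columns.

    Columns with zero variance carry no signal and are forced to 0 (their
    fitted coefficient is an artifact of collinearity with the intercept).
    """
    raw_cols = raw_cols.copy()
    if mat is not None:
        constant = mat.std(ddof=0) == 0
        raw_cols[constant[constant].index] = 0.0
    by_var = {v: 0.0 for v in variables}
    for col, val in raw_cols.items():
        var = owner[col]
        by_var[var] = max(by_var[var], abs(float(val)))
    return pd.Series(by_var)


def _assemble(classifier: str, per_class_raw: dict[str, pd.Series], **kw) -> ImportanceTable:
    rows = []
    for cls, raw in per_class_raw.items():
        scaled = scale_to_100(raw)
        for var in raw.index:
            rows.append({"class": cls, "variable": var,
                         "raw": float(raw[var]), "scaled": float(scaled[var])})
    return ImportanceTable(classifier=classifier, frame=pd.DataFrame(rows), **kw)


# ---------------------------------------------------------------------------
# classifiers


def fit_glm_importance(X: pd.DataFrame, y: pd.Series, max_iter: int = 1000) -> ImportanceTable:
    """Binary logistic regression; importance = |z| of each coefficient.

    With more than two outcome levels the call is routed to the multinomial
    model.  Perfect separation (infinite/unstable z) falls back to a weakly
    L2-regularized refit whose |coefficient| stands in for |z| (flagged in
    ``tuning``).
    """
    y = pd.Series(y).astype(str)
    levels = sorted(y.unique())
    if len(levels) > 2:
        out = fit_multiglm_importance(X, y, max_iter=max_iter)
        out.tuning["routed_from"] = "glm"
        return out
    if len(levels) < 2:
        raise ConfigError("dependent variable needs at least 2 levels")

    mat, owner = encode_predictors(X)
    variables = list(X.columns)
    y01 = (y == levels[1]).astype(float).to_numpy()

    import statsmodels.api as sm

    z = None
    flagged = False
    design = sm.add_constant(mat.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y01, design).fit(disp=0, maxiter=max_iter)
            z = pd.Series(np.abs(fit.tvalues[1:]), index=mat.columns)
            if not np.all(np.isfinite(z)) or np.abs(fit.params).max() > 50:
                z = None
        except Exception:  # separation / singular hessian
            z = None
    if z is None:
        flagged = True
        clf = LogisticRegression(C=1.0, max_iter=max_iter)
        clf.fit(mat.to_numpy(dtype=float), y01)
        z = pd.Series(np.abs(clf.coef_[0]), index=mat.columns)

    raw = _collapse(z, owner, variables, mat)
    per_class = {lvl: raw for lvl in levels}
    return _assemble("glm", per_class, tuning={"regularized_fallback": flagged})


def fit_multiglm_importance(
    X: pd.DataFrame, y: pd.Series, weight_decay: float = 1e-4, max_iter: int = 1000
) -> ImportanceTable:
    """Multinomial log-linear model; per-class importance = |coefficient|.

    Predictors are expected standardized, so coefficient magnitudes are
    comparable; a small L2 weight decay stabilizes separation, mirroring the
    neural-network-based multinomial fitters.
    """
    y = pd.Series(y).astype(str)
    mat, owner = encode_predictors(X)
    variables = list(X.columns)
    C = 1.0 / max(weight_decay * len(y), 1e-12)
    clf = LogisticRegression(C=C, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(mat.to_numpy(dtype=float), y)
    if clf.n_iter_.max() >= max_iter:
        raise ConvergenceError(
            f"multinomial model did not converge in {max_iter} iterations"
        )
    coef = clf.coef_
    classes = list(clf.classes_)
    if coef.shape[0] == 1:  # binary: same magnitude for both classes
        coef = np.vstack([-coef[0], coef[0]])
    per_class = {
        cls: _collapse(pd.Series(np.abs(coef[i]), index=mat.columns), owner, variables, mat)
        for i, cls in enumerate(classes)
    }
    return _assemble("multiglm", per_class, tuning={"weight_decay": weight_decay})


def default_lambda_grid(n_lambda: int = 50) -> tuple[float, ...]:
    """Log-spaced penalty strengths spanning near-null to near-saturated fits."""
    return tuple(np.logspace(-4, 1, n_lambda))


def fit_glmnet_importance(
    X: pd.DataFrame,
    y: pd.Series,
    alphas: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    lambdas: tuple[float, ...] | None = None,
    cv: int = 3,
    seed: int = 0,
    max_iter: int = 2000,
) -> ImportanceTable:
    """Elastic-net multinomial model tuned over (alpha, lambda) by CV accuracy.

    alpha is the lasso/ridge mixing parameter, lambda the penalty strength in
    the glmnet parameterization (objective mean-loss + lambda * penalty);
    importance is the per-class |coefficient| at the selected penalty, with
    zeroed-out variables scoring 0.
    """
    if not alphas or (lambdas is not None and not len(lambdas)):
        raise ConfigError("alpha and lambda grids must be non-empty")
    if lambdas is None:
        lambdas = default_lambda_grid()
    y = pd.Series(y).astype(str)
    mat, owner = encode_predictors(X)
    variables = list(X.columns)
    Xa = mat.to_numpy(dtype=float)
    n = len(y)

    from sklearn.model_selection import StratifiedKFold, cross_val_score

    best = (-np.inf, None, None)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=substream_seed(seed, "glmnet/cv"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for alpha in alphas:
            for lam in lambdas:
                clf = LogisticRegression(
                    penalty="elasticnet", solver="saga", l1_ratio=float(alpha),
                    C=1.0 / (n * float(lam)), max_iter=max_iter, tol=1e-3,
                    random_state=substream_seed(seed, "glmnet/fit"),
                )
                acc = cross_val_score(clf, Xa, y, cv=skf, scoring="accuracy").mean()
                if acc > best[0]:
                    best = (acc, float(alpha), float(lam))
        _, alpha, lam = best
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=alpha,
            C=1.0 / (n * lam), max_iter=max_iter, tol=1e-4,
            random_state=substream_seed(seed, "glmnet/fit"),
        )
        clf.fit(Xa, y)
    coef = clf.coef_
    classes = list(clf.classes_)
    if coef.shape[0] == 1:
        coef = np.vstack([-coef[0], coef[0]])
    per_class = {
        cls: _collapse(pd.Series(np.abs(coef[i]), index=mat.columns), owner, variables, mat)
        for i, cls in enumerate(classes)
    }
    return _assemble(
        "glmnet", per_class,
        accuracy=float(best[0]),
        tuning={"alpha": alpha, "lambda": lam},
    )


def fit_rf_importance(
    X: pd.DataFrame,
    y: pd.Series,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
    permutation: bool = False,
) -> ImportanceTable:
    """Random forest; importance = mean decrease in impurity (or permutation).

    The forest importance is not class-specific, so every class row carries
    the same raw values.  Out-of-bag accuracy is reported when the forest is
    large enough to have OOB coverage.
    """
    if n_trees < 1:
        raise ConfigError("n_trees must be >= 1")
    y = pd.Series(y).astype(str)
    mat, owner = encode_predictors(X, drop_first=False)
    variables = list(X.columns)
    mtry = mtry or max(1, int(np.sqrt(mat.shape[1])))
    use_oob = n_trees >= 10
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry,
        oob_score=use_oob, random_state=substream_seed(seed, "rf"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(mat.to_numpy(dtype=float), y)
    if permutation:
        from sklearn.inspection import permutation_importance

        perm = permutation_importance(
            clf, mat.to_numpy(dtype=float), y, n_repeats=10,
            random_state=substream_seed(seed, "rf/perm"),
        )
        cols = pd.Series(perm.importances_mean, index=mat.columns)
    else:
        cols = pd.Series(clf.feature_importances_, index=mat.columns)
    raw = _collapse(cols, owner, variables)
    per_class = {cls: raw for cls in clf.classes_}
    return _assemble(
        "rf", per_class,
        accuracy=float(clf.oob_score_) if use_oob else np.nan,
        tuning={"n_trees": n_trees, "mtry": mtry,
                "importance": "permutation" if permutation else "impurity"},
    )


# ---------------------------------------------------------------------------
# accuracy estimation


def assess_accuracy(
    make_classifier,
    X: pd.DataFrame,
    y: pd.Series,
    resampling: tuple = ("bootstrap", 25),
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of held-out accuracy over resamples.

    ``resampling`` is ``("bootstrap", n)`` — train on a with-replacement
    resample, test out-of-bag — or ``("kfold", k)`` for stratified k-fold.
    A resample that misses a class is redrawn (at most 10 retries each).
    Fully deterministic under a fixed seed.
    """
    y = pd.Series(y).astype(str).reset_index(drop=True)
    mat, _ = encode_predictors(X)
    Xa = mat.to_numpy(dtype=float)
    rng = substream(seed, "accuracy")
    n = len(y)
    classes = set(y.unique())
    accs: list[float] = []

    if resampling[0] == "bootstrap":
        for _ in range(int(resampling[1])):
            for _retry in range(10):
                train = rng.integers(0, n, size=n)
                oob = np.setdiff1d(np.arange(n), np.unique(train))
                if len(oob) and set(y.iloc[train].unique()) == classes:
                    break
            clf = make_classifier()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xa[train], y.iloc[train])
            accs.append(float(np.mean(clf.predict(Xa[oob]) == y.iloc[oob].to_numpy())))
    elif resampling[0] == "kfold":
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(
            n_splits=int(resampling[1]), shuffle=True,
            random_state=substream_seed(seed, "accuracy/kfold"),
        )
        for train, test in skf.split(Xa, y):
            clf = make_classifier()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xa[train], y.iloc[train])
            accs.append(float(np.mean(clf.predict(Xa[test]) == y.iloc[test].to_numpy())))
    else:
        raise ConfigError(f"unknown resampling scheme {resampling[0]!r}")
    return float(np.mean(accs)), float(np.std(accs, ddof=1))


# ---------------------------------------------------------------------------
# descriptive summaries


def group_summaries(
    table: PhenoTable, strata_vars: list[str] | None = None, confidence: float = 0.95
) -> GroupSummary:
    """Mean, SD, SE and t-based confidence limits per stratum and variable.

    Strata default to dependent level x conditioning values.  Strata of size
    one report missing SD/CI.
    """
    if strata_vars is None:
        strata_vars = [table.dependent] + [
            c for c in table.conditioning if table.var_types[c] == TYPE_QUAL
        ]
    strata = table.values[strata_vars].astype(str).agg("|".join, axis=1)
    rows = []
    for col in table.variables_of_type(TYPE_QUANT):
        for stratum, idx in table.values[col].groupby(strata).groups.items():
            vals = table.values.loc[idx, col].dropna().astype(float)
            n = len(vals)
            if n == 0:
                continue
            mean = float(vals.mean())
            if n == 1:
                sd = se = lo = hi = np.nan
            else:
                sd = float(vals.std(ddof=1))
                se = sd / np.sqrt(n)
                tcrit = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
                lo, hi = mean - tcrit * se, mean + tcrit * se
            rows.append({"stratum": stratum, "variable": col, "n": n, "mean": mean,
                         "sd": sd, "se": se, "ci_low": lo, "ci_high": hi})
    return GroupSummary(frame=pd.DataFrame(rows))
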