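"""Mixed-data principal component analysis and multiple factor analysis.

``pcamix`` runs a generalized SVD on the concatenation of the standardized
quantitative block and the centered indicator matrix of the qualitative
block, with each level column carrying the correspondence-analysis metric
``n / n_level``.  With no qualitative variables this reduces to ordinary
correlation-matrix PCA; with no quantitative variables it reduces to
multiple correspondence analysis.  Total inertia is ``p1 + (m - q)`` where
``p1`` counts quantitative variables, ``m`` total observed levels and ``q``
qualitative variables.

``mfamix`` additionally organizes variables in groups and gives every
variable of group ``g`` the metric weight ``1 / lambda1(g)`` — the inverse
of the first eigenvalue of the group analyzed alone — so that no group
dominates the global axes (its first within-group eigenvalue becomes 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phenodisc.errors import FactorError

EIG_TOL = 1e-10


@dataclass
class FactorInput:
    """Input block for the factor analysis.

    ``quantitative``: n x p1 numeric frame (any location/scale — columns are
    re-standardized internally with the population SD).
    ``qualitative``: n x q frame of category labels.
    ``groups``: variable -> group name; ungrouped variables become singleton
    groups named after themselves.
    """

    quantitative: pd.DataFrame
    qualitative: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.quantitative) != len(self.qualitative):
            if len(self.quantitative) and len(self.qualitative):
                raise FactorError("quantitative and qualitative blocks disagree on n")
        for frame in (self.quantitative, self.qualitative):
            if frame.isna().any().any():
                raise FactorError("factor analysis input must have no missing cells")
        for var in self.variables:
            self.groups.setdefault(var, var)

    @property
    def n(self) -> int:
        return len(self.quantitative) if len(self.quantitative.columns) else len(self.qualitative)

    @property
    def variables(self) -> list[str]:
        return list(self.quantitative.columns) + list(self.qualitative.columns)

    def subset(self, variables: Sequence[str]) -> "FactorInput":
        qn = [v for v in variables if v in self.quantitative.columns]
        ql = [v for v in variables if v in self.qualitative.columns]
        return FactorInput(
            quantitative=self.quantitative[qn],
            qualitative=self.qualitative[ql],
            groups={v: self.groups[v] for v in variables},
        )


@dataclass
class FactorResult:
    eigenvalues: np.ndarray
    scores: pd.DataFrame  # n x r individual coordinates
    quant_correlations: pd.DataFrame  # p1 x r Pearson correlations
    level_coordinates: pd.DataFrame  # m x r barycentric level coordinates
    squared_loadings: pd.DataFrame  # (p1+q) x r, corr^2 or eta^2
    column_contributions: pd.DataFrame  # expanded-column x r, sums to lambda_d
    loadings: pd.DataFrame  # expanded-column x r signed right singular vectors
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    total_inertia: float

    @property
    def rank(self) -> int:
        return len(self.eigenvalues)


@dataclass
class MFAResult(FactorResult):
    group_weights: dict[str, float] = field(default_factory=dict)
    group_contributions: pd.DataFrame = None  # type: ignore[assignment]
    partial_axes: pd.DataFrame = None  # type: ignore[assignment]
    partial_coordinates: dict[str, pd.DataFrame] = field(default_factory=dict)


def _indicator(qualitative: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-hot expansion with ``var=level`` column names, observed levels only."""
    blocks, levels = [], {}
    for var in qualitative.columns:
        series = qualitative[var].astype(str)
        dummies = pd.get_dummies(series, prefix=var, prefix_sep="=").astype(float)
        observed = [c for c in dummies.columns if dummies[c].sum() > 0]
        if not observed:
            raise FactorError(f"qualitative variable {var!r} has no observed levels")
        blocks.append(dummies[observed])
        levels[var] = observed
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=qualitative.index), levels


def pcamix(
    data: FactorInput,
    variable_weights: Mapping[str, float] | None = None,
) -> FactorResult:
    """Generalized-SVD factor analysis of a mixed quantitative/qualitative block.

    ``variable_weights`` multiplies the metric of every expanded column of a
    variable (used by :func:`mfamix` for group weighting); default 1.
    """
    n = data.n
    if n < 3:
        raise FactorError("need at least 3 individuals")
    p1 = data.quantitative.shape[1]
    q = data.qualitative.shape[1]
    if p1 + q == 0:
        raise FactorError("no variables")
    weights = dict(variable_weights or {})

    col_names: list[str] = []
    col_var: list[str] = []  # owning variable per expanded column
    z_cols: list[np.ndarray] = []
    metric: list[float] = []

    X = data.quantitative.to_numpy(dtype=float) if p1 else np.empty((n, 0))
    for j, var in enumerate(data.quantitative.columns):
        col = X[:, j]
        sd = col.std(ddof=0)
        if sd <= 0:
            raise FactorError(f"quantitative variable {var!r} has zero variance")
        z_cols.append((col - col.mean()) / sd)
        metric.append(weights.get(var, 1.0))
        col_names.append(var)
        col_var.append(var)

    level_counts: dict[str, float] = {}
    if q:
        indicator, level_map = _indicator(data.qualitative)
        G = indicator.to_numpy(dtype=float)
        freqs = G.mean(axis=0)
        Gc = G - freqs
        for k, level_col in enumerate(indicator.columns):
            var = level_col.split("=", 1)[0]
            z_cols.append(Gc[:, k])
            metric.append((1.0 / freqs[k]) * weights.get(var, 1.0))
            col_names.append(level_col)
            col_var.append(var)
            level_counts[level_col] = freqs[k] * n
    else:
        level_map = {}

    Z = np.column_stack(z_cols)
    A = Z * np.sqrt(np.asarray(metric)) / np.sqrt(n)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    lam = s**2
    keep = lam > EIG_TOL
    U, s, V, lam = U[:, keep], s[keep], Vt[keep].T, lam[keep]
    r = len(lam)
    if r == 0:
        raise FactorError("rank-0 input")

    # sign convention: largest-|loading| entry positive on each dimension
    for d in range(r):
        pivot = np.argmax(np.abs(V[:, d]))
        if V[pivot, d] < 0:
            V[:, d] *= -1
            U[:, d] *= -1

    dims = [f"Dim{d + 1}" for d in range(r)]
    F = np.sqrt(n) * U * s  # individual coordinates
    scores = pd.DataFrame(F, index=data.quantitative.index if p1 else data.qualitative.index,
                          columns=dims)

    contrib = pd.DataFrame((s * V) ** 2, index=col_names, columns=dims)

    # squared loadings: per-variable sums of column contributions
    sqload = contrib.groupby(pd.Index(col_var, name="variable"), sort=False).sum()
    sqload = sqload.loc[[v for v in data.variables if v in sqload.index]]

    quant_corr = pd.DataFrame(index=list(data.quantitative.columns), columns=dims, dtype=float)
    Fsd = F.std(axis=0, ddof=0)
    for j, var in enumerate(data.quantitative.columns):
        zj = z_cols[j]
        quant_corr.loc[var] = (zj @ F) / (n * Fsd)  # z_j already unit variance

    level_rows = []
    for var, levels in level_map.items():
        for level_col in levels:
            mask = data.qualitative[var].astype(str) == level_col.split("=", 1)[1]
            level_rows.append(pd.Series(F[mask.to_numpy()].mean(axis=0), index=dims, name=level_col))
    level_coords = (
        pd.DataFrame(level_rows) if level_rows else pd.DataFrame(columns=dims, dtype=float)
    )

    total_inertia = float(sum(
        weights.get(v, 1.0) for v in data.quantitative.columns
    )) + float(sum(
        weights.get(var, 1.0) * (len(levels) - 1) for var, levels in level_map.items()
    ))
    pct = 100.0 * lam / lam.sum()
    return FactorResult(
        eigenvalues=lam,
        scores=scores,
        quant_correlations=quant_corr,
        level_coordinates=level_coords,
        squared_loadings=sqload,
        column_contributions=contrib,
        loadings=pd.DataFrame(V, index=col_names, columns=dims),
        variance_pct=pct,
        cumulative_pct=np.cumsum(pct),
        total_inertia=total_inertia,
    )


def mfamix(data: FactorInput) -> MFAResult:
    """Multiple factor analysis: group-weighted :func:`pcamix`.

    Every variable of group ``g`` is assigned metric weight ``1/lambda1(g)``,
    then a single global ``pcamix`` is run on the weighted ensemble.  Group
    contributions per dimension sum to the dimension's eigenvalue; partial
    axes are correlations of each group's own dimensions with the global
    ones; partial individual coordinates average to the global coordinates.
    """
    group_names = list(dict.fromkeys(data.groups[v] for v in data.variables))
    if not group_names:
        raise FactorError("no groups")
    members = {g: [v for v in data.variables if data.groups[v] == g] for g in group_names}

    group_results: dict[str, FactorResult] = {}
    weights: dict[str, float] = {}
    for g, vars_g in members.items():
        try:
            res_g = pcamix(data.subset(vars_g))
        except FactorError as exc:
            raise FactorError(f"group {g!r} failed its own analysis: {exc}") from exc
        group_results[g] = res_g
        weights[g] = 1.0 / res_g.eigenvalues[0]

    var_weights = {v: weights[data.groups[v]] for v in data.variables}
    global_res = pcamix(data, variable_weights=var_weights)
    dims = list(global_res.scores.columns)

    group_contrib = pd.DataFrame(
        [global_res.squared_loadings.loc[members[g]].sum(axis=0) for g in group_names],
        index=pd.Index(group_names, name="group"),
    )

    # partial axes: corr(group's own dimension scores, global dimension scores)
    rows = []
    for g in group_names:
        own = group_results[g].scores
        for own_dim in own.columns:
            corr = [
                float(np.corrcoef(own[own_dim], global_res.scores[d])[0, 1]) for d in dims
            ]
            rows.append(pd.Series(corr, index=dims, name=f"{g}.{own_dim}"))
    partial_axes = pd.DataFrame(rows)

    # partial individual coordinates: per-group reconstruction, averaging to global
    n_groups = len(group_names)
    partial = {
        g: _partial_scores(data, members[g], var_weights, global_res, n_groups)
        for g in group_names
    }

    return MFAResult(
        eigenvalues=global_res.eigenvalues,
        scores=global_res.scores,
        quant_correlations=global_res.quant_correlations,
        level_coordinates=global_res.level_coordinates,
        squared_loadings=global_res.squared_loadings,
        column_contributions=global_res.column_contributions,
        loadings=global_res.loadings,
        variance_pct=global_res.variance_pct,
        cumulative_pct=global_res.cumulative_pct,
        total_inertia=global_res.total_inertia,
        group_weights=weights,
        group_contributions=group_contrib,
        partial_axes=partial_axes,
        partial_coordinates=partial,
    )


def _partial_scores(
    data: FactorInput,
    group_vars: list[str],
    var_weights: Mapping[str, float],
    global_res: FactorResult,
    n_groups: int,
) -> pd.DataFrame:
    """Project the global axes using only one group's columns (times n_groups)."""
    n = data.n
    dims = list(global_res.scores.columns)

    # rebuild the weighted standardized columns for this group's variables
    cols = {}
    for var in group_vars:
        w = np.sqrt(var_weights.get(var, 1.0))
        if var in data.quantitative.columns:
            col = data.quantitative[var].to_numpy(dtype=float)
            cols[var] = w * (col - col.mean()) / col.std(ddof=0)
        else:
            series = data.qualitative[var].astype(str)
            dummies = pd.get_dummies(series, prefix=var, prefix_sep="=").astype(float)
            for level_col in dummies.columns:
                freq = dummies[level_col].mean()
                cols[level_col] = w * (dummies[level_col] - freq).to_numpy() / np.sqrt(freq)
    block_cols = [c for c in global_res.loadings.index if c in cols]
    A_block = np.column_stack([cols[c] for c in block_cols]) / np.sqrt(n)
    V_block = global_res.loadings.loc[block_cols].to_numpy(dtype=float)
    F_partial = n_groups * np.sqrt(n) * (A_block @ V_block)
    return pd.DataFrame(F_partial, index=global_res.scores.index, columns=dims)


def cumulative_variance(result: FactorResult, n_dims: int) -> pd.DataFrame:
    """Per-dimension variance % and running cumulative %, capped at rank."""
    if n_dims < 1:
        raise FactorError("n_dims must be >= 1")
    k = min(n_dims, result.rank)
    return pd.DataFrame(
        {
            "dimension": np.arange(1, k + 1),
            "eigenvalue": result.eigenvalues[:k],
            "variance_pct": result.variance_pct[:k],
            "cumulative_pct": result.cumulative_pct[:k],
        }
    )


def cosine_similarity(
    result: FactorResult, dims: int, variables: Sequence[str]
) -> pd.DataFrame:
    """Pairwise cosine similarity of variable trajectories in component space.

    Each name is looked up among quantitative-variable correlation vectors
    first, then among qualitative level coordinates; vectors are restricted
    to the first ``dims`` dimensions.  Zero-norm vectors give missing cells.
    """
    if dims > result.rank:
        raise FactorError(f"dims={dims} exceeds rank {result.rank}")
    dim_cols = list(result.scores.columns[:dims])
    vecs = {}
    for name in variables:
        if name in result.quant_correlations.index:
            vecs[name] = result.quant_correlations.loc[name, dim_cols].to_numpy(dtype=float)
        elif name in result.level_coordinates.index:
            vecs[name] = result.level_coordinates.loc[name, dim_cols].to_numpy(dtype=float)
        else:
            raise FactorError(f"unknown variable or level {name!r}")
    out = pd.DataFrame(index=list(variables), columns=list(variables), dtype=float)
    for a in variables:
        for b in variables:
            u, v = vecs[a], vecs[b]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            out.loc[a, b] = np.nan if nu == 0 or nv == 0 else float(u @ v / (nu * nv))
    return out
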