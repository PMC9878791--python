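"""Reading, writing and normalizing phenotyping tables.

A table holds individuals in rows and recorded variables in columns, mixing
quantitative and qualitative values.  Columns may carry a group label in the
header with a ``::`` separator (``"HotPlate50::Latency"``), marking variables
recorded in the same test; ungrouped variables are treated downstream as
singleton groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from phenodisc.errors import (
    ConfigError,
    DegenerateDependentError,
    DuplicateColumnError,
    GroupLabelError,
    MissingDependentError,
    UnreadableFileError,
)

GROUP_SEPARATOR = "::"

ROLE_ID = "id"
ROLE_DEPENDENT = "dependent"
ROLE_CONDITIONING = "conditioning"
ROLE_PREDICTOR = "predictor"

TYPE_QUANT = "quantitative"
TYPE_QUAL = "qualitative"

DEFAULT_MISSING = ("", "NA", "NaN", "na")


@dataclass
class RunConfig:
    """Run-wide configuration.

    ``dependent`` and ``conditioning`` are declared explicitly; the input
    format does not mark them.  Thresholds live here so that the correlation
    filter (default ``|r| > 0.75``) and the component-contribution selection
    (default 30% on the first three dimensions) are analyst-controlled.
    """

    dependent: str | None = None
    conditioning: tuple[str, ...] = ()
    id_column: str | None = None
    correlation_threshold: float = 0.75
    contribution_threshold: float = 0.30
    n_dims_selection: int = 3
    n_dims_variance: int = 10
    seed: int = 0
    missing_values: tuple[str, ...] = DEFAULT_MISSING
    numeric_fraction: float = 0.90
    type_overrides: Mapping[str, str] = field(default_factory=dict)
    sheet_name: str | int = 0
    anonymize: bool = True
    # imputation
    pmm_k_donors: int = 5
    pmm_n_bootstrap: int = 10
    # classifiers
    n_resamples: int = 25
    n_trees: int = 500
    rf_mtry: int | None = None
    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
    n_lambda: int = 50
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.correlation_threshold <= 1.0):
            raise ConfigError("correlation_threshold must be in (0, 1]")
        if not (0.0 < self.contribution_threshold <= 1.0):
            raise ConfigError("contribution_threshold must be in (0, 1]")
        if self.n_dims_selection < 1 or self.n_dims_variance < 1:
            raise ConfigError("n_dims settings must be >= 1")

    def to_json(self) -> str:
        payload = {
            k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
            for k, v in self.__dict__.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        payload = json.loads(text)
        for key in ("conditioning", "missing_values", "alpha_grid"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class PhenoTable:
    """Individuals x variables with declared roles, types and group labels.

    ``values`` is indexed by the individual identifiers; ``imputed_mask``
    shares its shape and is True exactly where a cell value was imputed.
    """

    values: pd.DataFrame
    var_roles: dict[str, str]
    var_types: dict[str, str]
    var_groups: dict[str, str | None]
    imputed_mask: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.imputed_mask is None:
            self.imputed_mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        # duplicate ids are tolerated on load; anonymize_ids re-keys them
        cols = list(self.values.columns)
        for registry, what in (
            (self.var_roles, "role"),
            (self.var_types, "type"),
            (self.var_groups, "group"),
        ):
            missing = [c for c in cols if c not in registry]
            if missing:
                raise ConfigError(f"variables missing a {what}: {missing}")
        dependents = [c for c in cols if self.var_roles[c] == ROLE_DEPENDENT]
        if len(dependents) != 1:
            raise MissingDependentError(
                f"exactly one dependent variable required, found {dependents}"
            )
        dep = dependents[0]
        if self.var_types[dep] != TYPE_QUAL:
            raise ConfigError(f"dependent variable {dep!r} must be qualitative")
        if self.values[dep].dropna().nunique() < 2:
            raise DegenerateDependentError(
                f"dependent variable {dep!r} has fewer than two observed levels"
            )
        if self.imputed_mask.shape != self.values.shape:
            raise ConfigError("imputed_mask shape mismatch")

    # -- accessors ----------------------------------------------------------
    @property
    def ids(self) -> list:
        return list(self.values.index)

    @property
    def n_individuals(self) -> int:
        return len(self.values)

    @property
    def dependent(self) -> str:
        return next(c for c in self.values.columns if self.var_roles[c] == ROLE_DEPENDENT)

    @property
    def conditioning(self) -> list[str]:
        return [c for c in self.values.columns if self.var_roles[c] == ROLE_CONDITIONING]

    @property
    def predictors(self) -> list[str]:
        return [
            c
            for c in self.values.columns
            if self.var_roles[c] in (ROLE_PREDICTOR, ROLE_CONDITIONING)
        ]

    def variables_of_type(self, var_type: str, among: Iterable[str] | None = None) -> list[str]:
        pool = list(among) if among is not None else list(self.values.columns)
        return [c for c in pool if self.var_types[c] == var_type]

    def copy(self) -> "PhenoTable":
        return PhenoTable(
            values=self.values.copy(),
            var_roles=dict(self.var_roles),
            var_types=dict(self.var_types),
            var_groups=dict(self.var_groups),
            imputed_mask=self.imputed_mask.copy(),
        )

    def drop_variables(self, names: Iterable[str]) -> "PhenoTable":
        names = list(names)
        return PhenoTable(
            values=self.values.drop(columns=names),
            var_roles={k: v for k, v in self.var_roles.items() if k not in names},
            var_types={k: v for k, v in self.var_types.items() if k not in names},
            var_groups={k: v for k, v in self.var_groups.items() if k not in names},
            imputed_mask=self.imputed_mask.drop(columns=names),
        )


def parse_group_label(header: str) -> tuple[str | None, str]:
    """Split ``"Group::Variable"`` into its parts.

    Headers without the separator denote ungrouped variables and return
    ``(None, header)``.  More than one separator is ambiguous and an error,
    as are empty group or variable parts.
    """
    if not header:
        raise GroupLabelError("empty column header")
    parts = header.split(GROUP_SEPARATOR)
    if len(parts) == 1:
        return None, header
    if len(parts) > 2:
        raise GroupLabelError(f"ambiguous header {header!r}: more than one {GROUP_SEPARATOR!r}")
    group, name = parts
    if not group or not name:
        raise GroupLabelError(f"header {header!r} has an empty group or variable part")
    return group, name


def _infer_type(raw: pd.Series, missing: tuple[str, ...], numeric_fraction: float) -> str:
    observed = raw[~raw.astype(str).str.strip().isin(missing) & raw.notna()]
    if observed.empty:
        return TYPE_QUAL
    parsed = pd.to_numeric(observed.astype(str).str.strip(), errors="coerce")
    return TYPE_QUANT if parsed.notna().mean() >= numeric_fraction else TYPE_QUAL


def _read_raw(path: Path, config: RunConfig) -> pd.DataFrame:
    suffix = path.suffix.lower()
    try:
        if suffix in (".xlsx", ".xls"):
            raw = pd.read_excel(path, sheet_name=config.sheet_name, dtype=object)
        elif suffix == ".tsv":
            raw = pd.read_csv(path, sep="\t", dtype=object, keep_default_na=False)
        else:
            raw = pd.read_csv(path, dtype=object, keep_default_na=False)
    except FileNotFoundError:
        raise UnreadableFileError(f"input file not found: {path}") from None
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise UnreadableFileError(f"cannot parse {path}: {exc}") from exc
    if raw.empty or raw.shape[1] == 0:
        raise UnreadableFileError(f"{path} contains no data")
    return raw


def read_pheno_table(path: str | Path, config: RunConfig) -> PhenoTable:
    """Load a CSV/TSV/XLSX phenotyping table into a :class:`PhenoTable`.

    Column types are inferred (a column is quantitative iff at least
    ``config.numeric_fraction`` of its non-missing cells parse as numbers,
    overridable per column), group labels are parsed from headers, and
    missing cells are recorded as absent.  A ``<path>.meta.json`` sidecar
    written by :func:`write_pheno_table` takes precedence over inference.
    """
    path = Path(path)
    raw = _read_raw(path, config)

    sidecar = path.with_name(path.name + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None

    headers = [str(c) for c in raw.columns]
    groups: dict[str, str | None] = {}
    names: list[str] = []
    for header in headers:
        group, name = parse_group_label(header)
        names.append(name)
        groups[name] = group
    dupes = [n for n in names if names.count(n) > 1]
    if dupes:
        raise DuplicateColumnError(f"duplicate column names after group stripping: {sorted(set(dupes))}")
    raw.columns = names

    id_col = config.id_column or (meta or {}).get("id_column") or names[0]
    if id_col not in names:
        raise ConfigError(f"id column {id_col!r} not in table")
    dependent = config.dependent or (meta or {}).get("dependent")
    if dependent is None or dependent not in names:
        raise MissingDependentError(
            f"dependent column {dependent!r} not found among {names}"
        )
    conditioning = tuple(config.conditioning) or tuple((meta or {}).get("conditioning", ()))
    absent = [c for c in conditioning if c not in names]
    if absent:
        raise ConfigError(f"conditioning columns not in table: {absent}")

    missing = tuple(config.missing_values)
    ids = raw[id_col].astype(str).str.strip()
    body = raw.drop(columns=[id_col])

    var_types: dict[str, str] = {}
    data: dict[str, pd.Series] = {}
    meta_types = (meta or {}).get("var_types", {})
    for col in body.columns:
        cells = body[col].astype(str).str.strip()
        is_missing = cells.isin(missing) | body[col].isna()
        if col in config.type_overrides:
            vtype = config.type_overrides[col]
        elif col in meta_types:
            vtype = meta_types[col]
        elif col == dependent:
            vtype = TYPE_QUAL
        else:
            vtype = _infer_type(body[col], missing, config.numeric_fraction)
        if vtype not in (TYPE_QUANT, TYPE_QUAL):
            raise ConfigError(f"unknown type {vtype!r} for column {col!r}")
        if vtype == TYPE_QUANT:
            series = pd.to_numeric(cells.where(~is_missing), errors="coerce")
        else:
            series = cells.where(~is_missing)
        var_types[col] = vtype
        data[col] = series

    values = pd.DataFrame(data, columns=list(body.columns))
    values.index = pd.Index(ids, name=id_col)

    var_roles = {}
    for col in values.columns:
        if col == dependent:
            var_roles[col] = ROLE_DEPENDENT
        elif col in conditioning:
            var_roles[col] = ROLE_CONDITIONING
        else:
            var_roles[col] = ROLE_PREDICTOR
    var_groups = {c: groups.get(c) for c in values.columns}
    return PhenoTable(values=values, var_roles=var_roles, var_types=var_types, var_groups=var_groups)


def write_pheno_table(table: PhenoTable, path: str | Path) -> Path:
    """Write a normalized TSV plus a ``.meta.json`` sidecar (roles/types/groups).

    Group labels are reassembled into the headers with ``::`` so that
    :func:`read_pheno_table` round-trips the table cell-for-cell.
    """
    path = Path(path)
    out = table.values.copy()
    headers = []
    for col in out.columns:
        group = table.var_groups.get(col)
        headers.append(f"{group}{GROUP_SEPARATOR}{col}" if group else col)
    out.columns = headers
    out.index.name = table.values.index.name or "Ind"
    out.to_csv(path, sep="\t", na_rep="NA")
    sidecar = path.with_name(path.name + ".meta.json")
    dep = table.dependent
    sidecar.write_text(
        json.dumps(
            {
                "id_column": out.index.name,
                "dependent": dep,
                "conditioning": table.conditioning,
                "var_types": table.var_types,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return path


def anonymize_ids(
    table: PhenoTable, conditioning: Iterable[str] | None = None
) -> tuple[PhenoTable, pd.DataFrame]:
    """Re-key individuals to unique identifiers ``Ind_001..Ind_n``.

    Two rows count as duplicated observations only when the original id AND
    all conditioning values coincide; such rows are flagged in the returned
    mapping but still kept under distinct new ids.  The mapping (one row per
    individual, old id vs new id) is the only place original ids survive.
    Deterministic in row order, hence idempotent.
    """
    conditioning = list(conditioning) if conditioning is not None else table.conditioning
    absent = [c for c in conditioning if c not in table.values.columns]
    if absent:
        raise ConfigError(f"conditioning variables not in table: {absent}")

    old_ids = [str(i) for i in table.values.index]
    width = max(3, len(str(len(old_ids))))
    new_ids = [f"Ind_{i + 1:0{width}d}" for i in range(len(old_ids))]

    strata = (
        table.values[conditioning].astype(str).agg("|".join, axis=1)
        if conditioning
        else pd.Series("", index=table.values.index)
    )
    key = pd.Series(old_ids, index=table.values.index) + "@" + strata.values
    dup_flags = key.duplicated(keep=False).to_numpy()

    mapping = pd.DataFrame(
        {"old_id": old_ids, "new_id": new_ids, "duplicate_observation": dup_flags}
    )
    new_table = table.copy()
    new_table.values.index = pd.Index(new_ids, name=table.values.index.name or "Ind")
    new_table.imputed_mask.index = new_table.values.index
    return new_table, mapping


def make_config(**overrides) -> RunConfig:
    """Convenience constructor used by the CLI (kwargs mirror RunConfig)."""
    return replace(RunConfig(), **overrides)
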