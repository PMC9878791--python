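"""Seeded synthetic phenotyping cohorts with planted, recoverable structure.

Cohorts mimic mouse phenotyping campaigns: 2-4 genotype classes crossed with
two sexes (unbalanced sizes allowed), quantitative test readouts organized
in ``::``-labelled groups, three kinds of traits (linear gene-dosage signal,
a non-monotone/dispersed non-linear signal, pure noise), and
missing-at-random cells.  The returned ground-truth record states exactly
which variables carry signal so recovery tests need no bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from phenodisc._random import substream
from phenodisc.errors import ConfigError
from phenodisc.tabular_io import (
    PhenoTable,
    ROLE_CONDITIONING,
    ROLE_DEPENDENT,
    ROLE_PREDICTOR,
    TYPE_QUAL,
    TYPE_QUANT,
)


@dataclass
class SyntheticSpec:
    """Blueprint of a synthetic cohort.

    ``group_sizes`` maps genotype -> {sex -> n}; genotype order defines the
    dose (0, 1, 2, ...).  Linear traits shift by ``linear_delta * dose``;
    the non-linear trait shifts and over-disperses the middle-dose class
    only, so its class means are non-monotone while its linear projection on
    the dosage axis is weak.
    """

    group_sizes: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "WT": {"F": 18, "M": 18},
            "Het": {"F": 17, "M": 18},
            "Homo": {"F": 18, "M": 17},
        }
    )
    n_signal_linear: int = 3
    n_signal_nonlinear: int = 1
    n_noise: int = 8
    traits_per_group: int = 2
    linear_delta: float = 0.9
    nonlinear_shift: float = 2.8
    nonlinear_scale: float = 5.0
    sex_effect: float = 0.6
    sex_effect_mode: str = "random"  # random | all | none
    noise_within_group_corr: float = 0.0
    noise_sd: float = 1.0
    heavy_tailed_noise: bool = False
    missing_rate: float = 0.0
    mar_by_sex: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(n for sexes in self.group_sizes.values() for n in sexes.values())
        if total <= 0:
            raise ConfigError("cohort must contain at least one individual")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_signal_linear + self.n_signal_nonlinear + self.n_noise < 1:
            raise ConfigError("at least one trait required")

    @property
    def n_individuals(self) -> int:
        return sum(n for sexes in self.group_sizes.values() for n in sexes.values())

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        return cls(**json.loads(text))


def _trait_names(spec: SyntheticSpec) -> tuple[list[str], dict[str, str | None]]:
    """Name traits and assign them to ``::`` test groups round-robin."""
    names = (
        [f"LinTrait{i + 1}" for i in range(spec.n_signal_linear)]
        + [f"NonLinTrait{i + 1}" for i in range(spec.n_signal_nonlinear)]
        + [f"Noise{i + 1}" for i in range(spec.n_noise)]
    )
    groups: dict[str, str | None] = {}
    per = max(1, spec.traits_per_group)
    for i, name in enumerate(names):
        groups[name] = f"Test{i // per + 1}" if per > 1 else None
    return names, groups


def generate_cohort(spec: SyntheticSpec) -> tuple[PhenoTable, dict]:
    """Draw one cohort; returns the table and its ground-truth record."""
    rng = substream(spec.seed, "synthetic/cohort")
    genotypes = list(spec.group_sizes)
    doses = {g: float(i) for i, g in enumerate(genotypes)}
    mid = genotypes[len(genotypes) // 2] if len(genotypes) >= 3 else genotypes[-1]

    rows_geno, rows_sex = [], []
    for g, sexes in spec.group_sizes.items():
        for sex, n in sexes.items():
            rows_geno += [g] * n
            rows_sex += [sex] * n
    n = len(rows_geno)
    geno = np.array(rows_geno)
    sex = np.array(rows_sex)
    dose = np.array([doses[g] for g in geno])
    is_mid = (geno == mid).astype(float)
    sex01 = (sex == sex[0]).astype(float)

    names, groups = _trait_names(spec)
    truth: dict = {
        "genotypes": genotypes,
        "doses": doses,
        "signal_linear": [], "signal_nonlinear": [], "noise": [],
        "effects": {},
    }
    data: dict[str, np.ndarray] = {}
    group_factor: dict[str, np.ndarray] = {}  # shared factor for correlated noise
    for name in names:
        eps = (
            rng.lognormal(0.0, 0.6, size=n) - np.exp(0.18)
            if spec.heavy_tailed_noise and name.startswith("Noise1")
            else rng.normal(0.0, spec.noise_sd, size=n)
        )
        if name.startswith("LinTrait"):
            trait_no = int(name.removeprefix("LinTrait"))
            if spec.sex_effect_mode == "orthogonal":
                # alternating dosage signs + uniform sex shift give separate
                # dosage and sex axes instead of one merged axis
                sign = 1.0 if trait_no % 2 else -1.0
                sexfx = spec.sex_effect
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                if spec.sex_effect_mode == "all":
                    sexfx = spec.sex_effect
                elif spec.sex_effect_mode == "none":
                    sexfx = 0.0
                else:
                    sexfx = spec.sex_effect if rng.random() < 0.5 else 0.0
            x = sign * spec.linear_delta * dose + sexfx * sex01 + eps
            truth["signal_linear"].append(name)
            truth["effects"][name] = {
                "kind": "linear_dosage", "delta": sign * spec.linear_delta,
                "sex_effect": sexfx,
            }
        elif name.startswith("NonLinTrait"):
            x = spec.nonlinear_shift * is_mid + (1.0 + (spec.nonlinear_scale - 1.0) * is_mid) * eps
            truth["signal_nonlinear"].append(name)
            truth["effects"][name] = {
                "kind": "nonlinear", "mid_class": mid,
                "shift": spec.nonlinear_shift, "scale": spec.nonlinear_scale,
            }
        else:
            rho = spec.noise_within_group_corr
            if rho > 0 and groups[name] is not None:
                shared = group_factor.setdefault(groups[name], rng.normal(0.0, 1.0, size=n))
                x = np.sqrt(rho) * shared * spec.noise_sd + np.sqrt(1 - rho) * eps
            else:
                x = eps
            truth["noise"].append(name)
            truth["effects"][name] = {"kind": "noise"}
        data[name] = x

    values = pd.DataFrame({"Genotype": geno, "Sex": sex, **data})
    values.index = pd.Index([f"Ind_{i + 1:03d}" for i in range(n)], name="Ind")

    if spec.missing_rate > 0:
        miss_rng = substream(spec.seed, "synthetic/missing")
        for name in names:
            prob = np.full(n, spec.missing_rate)
            if spec.mar_by_sex:
                prob = np.where(sex01 > 0, spec.missing_rate * 1.8, spec.missing_rate * 0.2)
            mask = miss_rng.random(n) < prob
            values.loc[mask, name] = np.nan

    var_roles = {"Genotype": ROLE_DEPENDENT, "Sex": ROLE_CONDITIONING}
    var_types = {"Genotype": TYPE_QUAL, "Sex": TYPE_QUAL}
    var_groups: dict[str, str | None] = {"Genotype": None, "Sex": None}
    for name in names:
        var_roles[name] = ROLE_PREDICTOR
        var_types[name] = TYPE_QUANT
        var_groups[name] = groups[name]

    table = PhenoTable(
        values=values, var_roles=var_roles, var_types=var_types, var_groups=var_groups
    )
    return table, truth
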