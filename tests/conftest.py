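import numpy as np
import pandas as pd
import pytest

from phenodisc.tabular_io import (
    PhenoTable,
    ROLE_CONDITIONING,
    ROLE_DEPENDENT,
    ROLE_PREDICTOR,
    TYPE_QUAL,
    TYPE_QUANT,
)


def make_table(values: pd.DataFrame, dependent: str, conditioning=(), groups=None,
               types=None) -> PhenoTable:
    """Build a PhenoTable from a plain frame with sensible defaults."""
    var_roles, var_types, var_groups = {}, {}, {}
    for col in values.columns:
        if col == dependent:
            var_roles[col] = ROLE_DEPENDENT
        elif col in conditioning:
            var_roles[col] = ROLE_CONDITIONING
        else:
            var_roles[col] = ROLE_PREDICTOR
        if types and col in types:
            var_types[col] = types[col]
        else:
            var_types[col] = (
                TYPE_QUANT if pd.api.types.is_numeric_dtype(values[col]) else TYPE_QUAL
            )
        var_groups[col] = (groups or {}).get(col)
    return PhenoTable(values=values, var_roles=var_roles, var_types=var_types,
                      var_groups=var_groups)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cohort(rng):
    """30 individuals, 2 genotypes x 2 sexes, 3 quantitative traits."""
    n = 30
    geno = np.repeat(["WT", "Mut"], n // 2)
    sex = np.tile(["F", "M"], n // 2)
    values = pd.DataFrame(
        {
            "Genotype": geno,
            "Sex": sex,
            "TraitA": rng.normal(size=n) + (geno == "Mut") * 1.5,
            "TraitB": rng.normal(size=n),
            "TraitC": rng.normal(size=n) + (sex == "F") * 0.8,
        },
        index=pd.Index([f"Ind_{i:03d}" for i in range(n)], name="Ind"),
    )
    return make_table(values, dependent="Genotype", conditioning=("Sex",))
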