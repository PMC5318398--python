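import numpy as np
import pandas as pd
import pytest

import epiqts as e
from epiqts.design import Term


def make_qts_table(effects: dict, env_means=None, trait="T1") -> e.QTSTable:
    """Build a QTSTable from {(cls, loci_tuple[, env]): effect}."""
    rows = []
    for key, val in effects.items():
        cls, loci = key[0], tuple(key[1])
        env = key[2] if len(key) > 2 else None
        term = Term(cls, loci, env)
        rows.append({"term": term.label(), "class": cls,
                     "loci": "|".join(loci), "environment": env,
                     "effect": float(val), "se": 0.1, "neglog_pew": 3.0,
                     "p_floor": False})
    entries = pd.DataFrame(rows, columns=list(e.QTSTable.COLUMNS))
    return e.QTSTable(trait=trait, entries=entries,
                      env_means=env_means or {"E1": 0.0, "E2": 0.0})


def oracle_value(combination: dict, env: str, q: e.QTSTable) -> float:
    """Independent genotypic-value oracle: naive per-term evaluation."""
    A = {2: 1.0, 1: 0.0, 0: -1.0}
    D = {2: 0.0, 1: 1.0, 0: 0.0}
    fac = {"a": A, "d": D}
    pair_factors = {"aa": ("a", "a"), "ad": ("a", "d"), "da": ("d", "a"),
                    "dd": ("d", "d")}
    base_of = {"ae": "a", "de": "d", "aae": "aa", "ade": "ad", "dae": "da",
               "dde": "dd"}
    total = 0.0
    for _, row in q.entries.iterrows():
        term_env = row["environment"]
        if term_env is not None and not (isinstance(term_env, float)
                                         and np.isnan(term_env)):
            if term_env != env:
                continue
        cls = base_of.get(row["class"], row["class"])
        loci = row["loci"].split("|")
        if cls in ("a", "d"):
            coeff = fac[cls][combination[loci[0]]]
        else:
            fi, fj = pair_factors[cls]
            coeff = fac[fi][combination[loci[0]]] * fac[fj][combination[loci[1]]]
        total += coeff * row["effect"]
    return total


@pytest.fixture(scope="session")
def small_population():
    """A reduced line/hybrid population: 2 females x 20 males, 26 hybrids."""
    spec = e.DesignSpec(n_females=2, n_males=20, crosses_per_female=(12, 14),
                        n_snps=30, n_replicates=2, seed=11)
    g, plan = e.simulate_population(spec)
    return spec, g, plan


@pytest.fixture(scope="session")
def study_population():
    """A population at the study's full design scale."""
    spec = e.DesignSpec(n_snps=60, seed=5)
    g, plan = e.simulate_population(spec)
    return spec, g, plan
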