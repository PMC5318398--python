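"""Prediction of genotypic values and superior line/hybrid combinations.

Given the experiment-wise significant terms of a trait (a ``QTSTable``), the
total genotypic value of any multi-locus genotype combination in an
environment is the sum of coefficient x effect over the retained terms
(environment-specific terms contribute only in their environment).  Values
are deviations from the per-environment population mean, which the table
carries separately.

The superior line (homozygous combinations only) and superior hybrid (any
genotype) are exact optima found by exhaustive enumeration for up to 15 loci;
beyond that a branch-and-bound search with an admissible bound provides the
same optimum with a certificate.  The best line/hybrid is the realized
subject of the mapping population with the optimal predicted value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design as dz
from .datamodel import (MISSING, QH, QQ, CrossPlan, GenotypeMatrix,
                        derive_f1_genotypes, qq)
from .mapping import QTSTable

#: genotype states in tie-break order (QQ < Qq < qq)
STATE_ORDER = (QQ, QH, qq)
STATE_NAME = {QQ: "QQ", QH: "Qq", qq: "qq"}

_A = {QQ: 1.0, QH: 0.0, qq: -1.0}
_D = {QQ: 0.0, QH: 1.0, qq: 0.0}
_FACTOR = {"a": _A, "d": _D}

MAX_EXHAUSTIVE_LOCI = 15


def _term_tuples(q: QTSTable, env: str) -> list:
    """Active (factor_i, locus_i, factor_j or None, locus_j or None, effect)
    tuples of the table in one environment."""
    out = []
    for term, effect in q.term_effects().items():
        if term.env is not None and term.env != env:
            continue
        base = dz.BASE_OF_ENV.get(term.cls, term.cls)
        if len(term.loci) == 1:
            out.append((base[0], term.loci[0], None, None, effect))
        else:
            fi, fj = dz._FACTORS[base]
            out.append((fi, term.loci[0], fj, term.loci[1], effect))
    return out


def genotypic_value(combination: dict, env: str, q: QTSTable) -> float:
    """Total genotypic value (deviation from the environment mean) of a
    genotype combination; ``combination`` maps locus id -> call code."""
    for l in q.loci():
        if l not in combination:
            raise KeyError(f"combination lacks QTS locus {l!r}")
    total = 0.0
    for fi, li, fj, lj, effect in _term_tuples(q, env):
        coeff = _FACTOR[fi][combination[li]]
        if fj is not None:
            coeff *= _FACTOR[fj][combination[lj]]
        total += coeff * effect
    return total


def uniform_genotype_values(q: QTSTable, env: str) -> tuple:
    """Genotypic values of the all-QQ, all-qq and all-Qq combinations."""
    loci = q.loci()
    vals = []
    for state in (QQ, qq, QH):
        vals.append(genotypic_value({l: state for l in loci}, env, q))
    return tuple(vals)


def _value_grid(q: QTSTable, env: str, loci: list, states: tuple) -> np.ndarray:
    """Genotypic value over the full combination grid, one axis per locus."""
    L = len(loci)
    axis = {l: k for k, l in enumerate(loci)}
    grid = np.zeros((len(states),) * L)
    state_arr = {f: np.array([_FACTOR[f][s] for s in states])
                 for f in ("a", "d")}
    for fi, li, fj, lj, effect in _term_tuples(q, env):
        if fj is None:
            shape = [1] * L
            shape[axis[li]] = len(states)
            grid += effect * state_arr[fi].reshape(shape)
        else:
            shape = [1] * L
            shape[axis[li]] = len(states)
            ci = state_arr[fi].reshape(shape)
            shape = [1] * L
            shape[axis[lj]] = len(states)
            cj = state_arr[fj].reshape(shape)
            grid += effect * ci * cj
    return grid


def superior_combination(q: QTSTable, env: str, space: str = "hybrids",
                         direction: str = "maximize",
                         method: str = "exhaustive") -> tuple[dict, float]:
    """Optimal genotype combination over the table's loci in one environment.

    ``space="lines"`` restricts every locus to the homozygotes {QQ, qq};
    ``space="hybrids"`` allows all three genotypes.  Exhaustive enumeration is
    exact and the default up to 15 loci; ties break to the lexicographically
    smallest combination under QQ < Qq < qq.  For larger tables pass
    ``method="branch_and_bound"``.
    """
    if space not in ("lines", "hybrids"):
        raise ValueError(f"unknown space {space!r}")
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"unknown direction {direction!r}")
    loci = q.loci()
    states = (QQ, qq) if space == "lines" else STATE_ORDER
    if not loci:
        return {}, 0.0
    if method == "exhaustive":
        if len(loci) > MAX_EXHAUSTIVE_LOCI:
            raise ValueError(
                f"{len(loci)} loci exceed the exhaustive-enumeration limit "
                f"({MAX_EXHAUSTIVE_LOCI}); use method='branch_and_bound'")
        grid = _value_grid(q, env, loci, states)
        flat = np.argmax(grid) if direction == "maximize" else np.argmin(grid)
        idx = np.unravel_index(flat, grid.shape)
        combo = {l: states[i] for l, i in zip(loci, idx)}
        return combo, float(grid[idx])
    if method == "branch_and_bound":
        return _branch_and_bound(q, env, loci, states, direction)
    raise ValueError(f"unknown method {method!r}")


def _branch_and_bound(q: QTSTable, env: str, loci: list, states: tuple,
                      direction: str) -> tuple[dict, float]:
    """Depth-first search with an admissible bound: the value of decided
    terms plus, for every term touching an undecided locus, its best
    achievable contribution.  Returns the certified optimum."""
    sign = 1.0 if direction == "maximize" else -1.0
    terms = _term_tuples(q, env)

    def term_best(t, assigned):
        fi, li, fj, lj, effect = t
        ci = [_FACTOR[fi][assigned[li]]] if li in assigned else \
            [_FACTOR[fi][s] for s in states]
        if fj is None:
            return max(sign * c * effect for c in ci)
        cj = [_FACTOR[fj][assigned[lj]]] if lj in assigned else \
            [_FACTOR[fj][s] for s in states]
        return max(sign * a * b * effect for a in ci for b in cj)

    best_val = -np.inf
    best_combo = None

    def value_of(assigned):
        total = 0.0
        for fi, li, fj, lj, effect in terms:
            c = _FACTOR[fi][assigned[li]]
            if fj is not None:
                c *= _FACTOR[fj][assigned[lj]]
            total += c * effect
        return sign * total

    def recurse(k, assigned):
        nonlocal best_val, best_combo
        bound = sum(term_best(t, assigned) for t in terms)
        if bound <= best_val:
            return
        if k == len(loci):
            v = value_of(assigned)
            if v > best_val:
                best_val = v
                best_combo = dict(assigned)
            return
        for s in states:
            assigned[loci[k]] = s
            recurse(k + 1, assigned)
            del assigned[loci[k]]

    recurse(0, {})
    return best_combo, float(sign * best_val)


def population_values(g: GenotypeMatrix, q: QTSTable, env: str) -> pd.Series:
    """Predicted genotypic value of every subject carrying calls at all QTS
    loci (subjects with a missing call at any QTS locus are excluded)."""
    loci = q.loci()
    calls = g.calls[loci] if loci else g.calls.iloc[:, :0]
    complete = ~(calls.to_numpy() == MISSING).any(axis=1) if loci else \
        np.ones(len(g.calls), dtype=bool)
    values = {}
    for sid in g.calls.index[complete]:
        combo = {l: int(calls.at[sid, l]) for l in loci}
        values[sid] = genotypic_value(combo, env, q)
    return pd.Series(values, dtype=float)


def best_in_population(g: GenotypeMatrix, q: QTSTable, env: str,
                       subset: str = "lines", direction: str = "maximize"
                       ) -> tuple[str, float]:
    """The realized subject with the optimal predicted genotypic value.

    ``subset`` picks inbred lines or F1 hybrids; ties break to the smallest
    subject id.
    """
    cls = {"lines": "inbred_line", "hybrids": "f1_hybrid"}[subset]
    members = g.subject_class[g.subject_class == cls].index
    if len(members) == 0:
        raise ValueError(f"population contains no {subset}")
    vals = population_values(g.subset_subjects(members), q, env)
    if vals.empty:
        raise ValueError(f"no {subset} carries complete calls at the QTS loci")
    opt = vals.max() if direction == "maximize" else vals.min()
    winners = sorted(vals.index[vals == opt])
    return winners[0], float(opt)


@dataclass
class PredictionReport:
    """Per-trait, per-environment prediction summary (Table-3 shape)."""

    rows: pd.DataFrame

    COLUMNS = ("trait", "environment", "mean", "QQ", "qq", "Qq",
               "best_line", "best_line_value", "superior_line_value",
               "best_hybrid", "best_hybrid_value", "superior_hybrid_value",
               "direction")

    def write(self, path, sep: str = "\t") -> None:
        self.rows.to_csv(path, sep=sep, index=False)


def build_prediction_report(g: GenotypeMatrix, q: QTSTable,
                            direction: str = "maximize") -> PredictionReport:
    """Assemble the prediction summary over all environments of a QTS table."""
    rows = []
    for env in sorted(q.env_means):
        v_qq, v_qq_minor, v_het = uniform_genotype_values(q, env)
        bl, blv = best_in_population(g, q, env, "lines", direction)
        bh, bhv = best_in_population(g, q, env, "hybrids", direction)
        _, slv = superior_combination(q, env, "lines", direction)
        _, shv = superior_combination(q, env, "hybrids", direction)
        rows.append({
            "trait": q.trait, "environment": env,
            "mean": q.env_means[env], "QQ": v_qq, "qq": v_qq_minor,
            "Qq": v_het, "best_line": bl, "best_line_value": blv,
            "superior_line_value": slv, "best_hybrid": bh,
            "best_hybrid_value": bhv, "superior_hybrid_value": shv,
            "direction": direction,
        })
    return PredictionReport(rows=pd.DataFrame(rows,
                                              columns=PredictionReport.COLUMNS))


@dataclass
class DonorReport:
    """Donor lines whose F1 with an acceptor attains the superior-hybrid
    value, with the loci where each donor supplies the needed allele."""

    trait: str
    environment: str
    acceptors: list
    donors: pd.DataFrame  # acceptor, donor, value, contributed_loci

    @property
    def n_donors(self) -> int:
        return self.donors["donor"].nunique() if len(self.donors) else 0

    def write(self, path, sep: str = "\t") -> None:
        self.donors.to_csv(path, sep=sep, index=False)


def donor_recommendation(g: GenotypeMatrix, acceptors: list, q: QTSTable,
                         env: str, direction: str = "maximize") -> DonorReport:
    """Which inbred donors, crossed to an acceptor, give an F1 that attains
    the superior-hybrid genotypic value.

    Every candidate donor x acceptor F1 is derived at the QTS loci and its
    value compared with the superior-hybrid optimum (ties in value count as
    attainment).  Contributed loci are those where the donor's allele differs
    from the acceptor's.
    """
    loci = q.loci()
    inbreds = list(g.subject_class[g.subject_class == "inbred_line"].index)
    for a in acceptors:
        if a not in inbreds:
            raise ValueError(f"acceptor {a!r} is not an inbred line")
    _, target = superior_combination(q, env, "hybrids", direction)
    parents = g.subset_subjects(inbreds).subset_loci(loci) if loci else \
        g.subset_subjects(inbreds)
    rows = []
    for acceptor in acceptors:
        donors = [d for d in inbreds if d != acceptor]
        plan = CrossPlan(crosses=[(acceptor, d, f"{acceptor}x{d}")
                                  for d in donors])
        f1 = derive_f1_genotypes(parents, plan)
        vals = population_values(f1, q, env)
        for d in donors:
            hid = f"{acceptor}x{d}"
            if hid not in vals.index:
                continue  # missing call at a QTS locus
            if not np.isclose(vals[hid], target, rtol=0, atol=1e-9):
                continue
            contributed = [l for l in loci
                           if parents.calls.at[d, l] != parents.calls.at[acceptor, l]]
            rows.append({"acceptor": acceptor, "donor": d,
                         "value": float(vals[hid]),
                         "contributed_loci": "|".join(contributed)})
    donors = pd.DataFrame(rows, columns=["acceptor", "donor", "value",
                                         "contributed_loci"])
    return DonorReport(trait=q.trait, environment=env,
                       acceptors=list(acceptors), donors=donors)


def gp_map(q: QTSTable, pair: tuple, env: str) -> pd.DataFrame:
    """3x3 genotype-phenotype map of a locus pair.

    Cell (g_i, g_j) is the genotypic value of the combination with the pair
    set accordingly and every other locus at the QQ reference.  A pair with no
    epistatic entry in the table is still computable (main effects only).
    """
    li, lj = pair
    loci = q.loci()
    for l in (li, lj):
        if l not in loci:
            raise KeyError(f"locus {l!r} not in QTS table")
    base = {l: QQ for l in loci}
    grid = pd.DataFrame(0.0,
                        index=[STATE_NAME[s] for s in STATE_ORDER],
                        columns=[STATE_NAME[s] for s in STATE_ORDER])
    for si in STATE_ORDER:
        for sj in STATE_ORDER:
            combo = dict(base)
            combo[li], combo[lj] = si, sj
            grid.loc[STATE_NAME[si], STATE_NAME[sj]] = \
                genotypic_value(combo, env, q)
    grid.index.name = li
    grid.columns.name = lj
    return grid
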