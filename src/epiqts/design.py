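"""Coefficient codings and design-matrix assembly for the full genetic model.

The phenotype of line or hybrid *k* in environment *h* is modelled as

    y_hk = mu + sum_i a_i u_A + sum_i d_i u_D
         + sum_{i<j} (aa_ij u_AA + ad_ij u_AD + da_ij u_DA + dd_ij u_DD)
         + e_h + environment-specific counterparts (ae, de, aae, ade, dae, dde)
         + eps_hk

with coefficient codings u_A in {+1 (QQ), 0 (Qq), -1 (qq)} and
u_D in {1 (Qq), 0 (QQ, qq)}.  Every digenic coefficient is the product of its
single-locus factors (AA = A_i * A_j, AD = A_i * D_j, DA = D_i * A_j,
DD = D_i * D_j); the enumerated cases of the model reduce to this product
rule, which also fixes the cells the enumeration leaves out (all zero).
For a stored pair (i, j) with i < j, AD means additive at locus i times
dominance at locus j and DA the reverse.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, QH, QQ, GenotypeMatrix, PhenotypeTable, qq

#: model term classes in canonical order
TERM_CLASSES = ("a", "d", "aa", "ad", "da", "dd",
                "ae", "de", "aae", "ade", "dae", "dde")

#: which single-locus factor each class applies at (locus_i, locus_j)
_FACTORS = {"aa": ("a", "a"), "ad": ("a", "d"), "da": ("d", "a"),
            "dd": ("d", "d"), "aae": ("a", "a"), "ade": ("a", "d"),
            "dae": ("d", "a"), "dde": ("d", "d")}

MAIN_CLASSES = ("a", "d")
PAIR_CLASSES = ("aa", "ad", "da", "dd")
ENV_MAIN_CLASSES = ("ae", "de")
ENV_PAIR_CLASSES = ("aae", "ade", "dae", "dde")
ENV_CLASSES = ENV_MAIN_CLASSES + ENV_PAIR_CLASSES

#: environment-specific class -> its general (cross-environment) base class
BASE_OF_ENV = {"ae": "a", "de": "d", "aae": "aa", "ade": "ad",
               "dae": "da", "dde": "dd"}


def additive_coefficient(call: int) -> int:
    """+1 for the major homozygote QQ, -1 for qq, 0 for Qq (and missing)."""
    if call == QQ:
        return 1
    if call == qq:
        return -1
    return 0


def dominance_coefficient(call: int) -> int:
    """1 for the heterozygote Qq, 0 otherwise."""
    return 1 if call == QH else 0


_SINGLE = {"a": additive_coefficient, "d": dominance_coefficient}


def epistasis_coefficient(kind: str, call_i: int, call_j: int) -> int:
    """Digenic coefficient: the product of the single-locus factor codings."""
    fi, fj = _FACTORS[kind.lower()]
    return _SINGLE[fi](call_i) * _SINGLE[fj](call_j)


def environment_coefficient(base: int, subject_env: str, term_env: str) -> int:
    """Environment-specific terms carry their base coefficient only in their
    own environment."""
    return base if subject_env == term_env else 0


@dataclass(frozen=True, order=True)
class Term:
    """One model column: a term class, its locus or locus pair, and (for
    environment-specific classes) the environment it is active in."""

    cls: str
    loci: tuple  # (locus_id,) or (locus_i, locus_j) with i < j by panel order
    env: str = None

    def __post_init__(self):
        if self.cls not in TERM_CLASSES:
            raise ValueError(f"unknown term class {self.cls!r}")
        if (self.cls in ENV_CLASSES) != (self.env is not None):
            raise ValueError(f"term {self.cls} environment mismatch")

    def label(self) -> str:
        s = f"{self.cls}:" + ":".join(self.loci)
        if self.env is not None:
            s += f":{self.env}"
        return s

    @classmethod
    def from_label(cls, label: str) -> "Term":
        parts = label.split(":")
        kind = parts[0]
        if kind in ENV_CLASSES:
            return cls(kind, tuple(parts[1:-1]), parts[-1])
        return cls(kind, tuple(parts[1:]))


#: class of the mirrored pair term when (i, j) is written as (j, i)
_SWAPPED_CLASS = {"aa": "aa", "ad": "da", "da": "ad", "dd": "dd",
                  "aae": "aae", "ade": "dae", "dae": "ade", "dde": "dde"}


def orient_term(term: "Term", panel_order: list) -> "Term":
    """Express a term with its pair loci in panel order.

    A dominance x additive term on (i, j) is the additive x dominance term on
    (j, i); single-locus terms pass through unchanged.
    """
    if len(term.loci) != 2:
        return term
    pos = {l: k for k, l in enumerate(panel_order)}
    i, j = term.loci
    if pos[i] <= pos[j]:
        return term
    return Term(_SWAPPED_CLASS[term.cls], (j, i), term.env)


@dataclass
class ModelSpec:
    """Which loci, term classes and environments enter the design."""

    candidate_loci: list
    classes: tuple = TERM_CLASSES
    environments: list = field(default_factory=list)

    def __post_init__(self):
        bad = set(self.classes) - set(TERM_CLASSES)
        if bad:
            raise ValueError(f"unknown term classes {sorted(bad)}")
        if len(set(self.candidate_loci)) != len(self.candidate_loci):
            raise ValueError("candidate loci must be distinct")

    def terms(self) -> list:
        """Canonical column order: class order as in the model, then locus
        index, then pair lexicographic by panel order, then environment."""
        loci = list(self.candidate_loci)
        pairs = list(itertools.combinations(loci, 2))
        out = []
        for cls in TERM_CLASSES:
            if cls not in self.classes:
                continue
            if cls in MAIN_CLASSES:
                out.extend(Term(cls, (l,)) for l in loci)
            elif cls in PAIR_CLASSES:
                out.extend(Term(cls, p) for p in pairs)
            elif cls in ENV_MAIN_CLASSES:
                out.extend(Term(cls, (l,), env)
                           for l in loci for env in self.environments)
            else:
                out.extend(Term(cls, p, env)
                           for p in pairs for env in self.environments)
        return out

    def normalize_pair(self, i: str, j: str) -> tuple:
        """Order a pair by panel order; swapping flips AD <-> DA downstream."""
        order = {l: k for k, l in enumerate(self.candidate_loci)}
        return (i, j) if order[i] < order[j] else (j, i)


@dataclass
class DesignMatrix:
    """Observations = (subject, environment) rows with replicate-mean response."""

    subjects: np.ndarray  # object, len n
    environments: np.ndarray  # object, len n
    y: np.ndarray  # float, len n
    X: np.ndarray  # n x p, coefficients in {-1, 0, +1}
    terms: list  # list[Term], len p
    trait: str = ""
    env_levels: list = field(default_factory=list)

    def __post_init__(self):
        if not self.env_levels:
            self.env_levels = sorted(set(self.environments))

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def term_labels(self) -> list:
        return [t.label() for t in self.terms]

    def class_index(self) -> np.ndarray:
        """Per-column index into the canonical class list (variance grouping)."""
        lut = {c: k for k, c in enumerate(TERM_CLASSES)}
        return np.array([lut[t.cls] for t in self.terms], dtype=np.int64)

    def env_index(self) -> np.ndarray:
        lut = {e: k for k, e in enumerate(self.env_levels)}
        return np.array([lut[e] for e in self.environments], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.term_labels())
        df.insert(0, "subject", self.subjects)
        df.insert(1, "environment", self.environments)
        df.insert(2, "y", self.y)
        return df

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def coefficient_columns(g: GenotypeMatrix, loci) -> tuple[np.ndarray, np.ndarray]:
    """Additive and dominance codings (subjects x loci) for the given loci.

    Missing calls code to 0 in both (subjects lacking a call carry no
    information for that locus's terms).
    """
    c = g.calls[list(loci)].to_numpy()
    A = np.where(c == QQ, 1, np.where(c == qq, -1, 0)).astype(np.int8)
    D = (c == QH).astype(np.int8)
    A[c == MISSING] = 0
    D[c == MISSING] = 0
    return A, D


def build_design_matrix(g: GenotypeMatrix, p: PhenotypeTable, spec: ModelSpec,
                        trait: str) -> DesignMatrix:
    """Assemble the model design for one trait.

    One row per (subject, environment) with the replicate-mean response; one
    column per enabled term, ordered canonically.  Subjects with phenotype but
    no genotype row are excluded.
    """
    missing_loci = [l for l in spec.candidate_loci if l not in g.calls.columns]
    if missing_loci:
        raise KeyError(f"candidate loci absent from genotypes: {missing_loci}")
    cells = p.cell_means(trait)
    if cells.empty:
        raise KeyError(f"trait {trait!r} has no phenotype records")
    known = set(g.calls.index)
    genotyped = cells["subject"].isin(known)
    cells = cells[genotyped].reset_index(drop=True)
    if not spec.environments:
        spec = ModelSpec(spec.candidate_loci, spec.classes,
                         sorted(cells["environment"].unique()))

    subs = cells["subject"].to_numpy()
    envs = cells["environment"].to_numpy()
    y = cells["value"].to_numpy(dtype=float)

    A, D = coefficient_columns(g, spec.candidate_loci)
    row_of = {s: i for i, s in enumerate(g.calls.index)}
    ridx = np.array([row_of[s] for s in subs])
    A, D = A[ridx].astype(np.float64), D[ridx].astype(np.float64)
    col_of = {l: j for j, l in enumerate(spec.candidate_loci)}

    terms = spec.terms()
    X = np.zeros((len(y), len(terms)))
    env_mask = {e: (envs == e).astype(np.float64) for e in spec.environments}
    factor = {"a": A, "d": D}
    for k, t in enumerate(terms):
        base_cls = BASE_OF_ENV.get(t.cls, t.cls)
        if len(t.loci) == 1:
            col = factor[base_cls[0]][:, col_of[t.loci[0]]]
        else:
            fi, fj = _FACTORS[base_cls]
            col = (factor[fi][:, col_of[t.loci[0]]]
                   * factor[fj][:, col_of[t.loci[1]]])
        if t.env is not None:
            col = col * env_mask[t.env]
        X[:, k] = col
    return DesignMatrix(subjects=subs, environments=envs, y=y, X=X,
                        terms=terms, trait=trait,
                        env_levels=list(spec.environments))
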