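"""Heritability partitioning of fitted variance components.

Per-effect heritability is h_g^2 = alpha * sigma_g^2 / V_P with the class
constants alpha = 2 (additive), 1 (dominance), 4 (additive x additive),
2 (additive x dominance or dominance x additive) and 1 (dominance x
dominance); environment-interaction classes inherit the alpha of their
genetic part.  Phenotypic variance is the model-based sum
V_P = V_G + V_GE + V_eps, so the per-effect percentages, the six category
sums (A, D, I, AE, DE, IE) and the total are additive by construction.

Two conventions are offered for the per-effect variance sigma_g^2.  The
default ``empirical`` mode takes the realized phenotypic-variance
contribution, posterior mean^2 times the variance of the effect's design
column; the realized column variance already embodies the segregation ratios
the alpha constants idealize, so no alpha is applied there.  The
``posterior`` mode follows the variance-component convention: sigma_g^2 is
the posterior mean of the squared effect (mean^2 + posterior variance) and
the alpha constant of the class scales it.  In both modes the phenotypic
variance is the model-based sum V_P = V_G + V_GE + V_eps, so percentages and
their category/total sums are additive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .design import BASE_OF_ENV, ENV_CLASSES, TERM_CLASSES
from .mapping import MappingResult

#: alpha constants by genetic part
ALPHA = {"a": 2.0, "d": 1.0, "aa": 4.0, "ad": 2.0, "da": 2.0, "dd": 1.0}

#: the six heritability categories and their member term classes
CATEGORIES = {
    "A": ("a",), "D": ("d",), "I": ("aa", "ad", "da", "dd"),
    "AE": ("ae",), "DE": ("de",), "IE": ("aae", "ade", "dae", "dde"),
}

_CLASS_TO_CATEGORY = {cls: cat for cat, members in CATEGORIES.items()
                      for cls in members}


def alpha_for(term_class: str) -> float:
    """Alpha constant for a term class; environment classes inherit the
    alpha of their genetic part."""
    cls = term_class.lower()
    base = BASE_OF_ENV.get(cls, cls)
    try:
        return ALPHA[base]
    except KeyError:
        raise KeyError(f"unknown term class {term_class!r}") from None


def component_heritability(sigma2_g: float, term_class: str,
                           v_p: float) -> float:
    """Percent of phenotypic variance attributable to one effect:
    100 * alpha * sigma_g^2 / V_P."""
    if v_p <= 0:
        raise ValueError("V_P must be positive")
    return 100.0 * alpha_for(term_class) * sigma2_g / v_p


@dataclass
class VarianceDecomposition:
    """Phenotypic-variance contributions by term class (trait units^2),
    on the scale of the decomposition mode that produced them."""

    by_class: dict  # term class -> variance contribution (mode convention)
    v_eps: float

    @property
    def v_g(self) -> float:
        return sum(v for c, v in self.by_class.items() if c not in ENV_CLASSES)

    @property
    def v_ge(self) -> float:
        return sum(v for c, v in self.by_class.items() if c in ENV_CLASSES)

    @property
    def v_p(self) -> float:
        return self.v_g + self.v_ge + self.v_eps


@dataclass
class HeritabilityTable:
    """Per-effect and per-category heritability percentages (Table-1 shape)."""

    categories: dict  # "A","D","I","AE","DE","IE" -> percent
    per_effect: dict = field(default_factory=dict)  # term label -> percent
    alphas: dict = field(default_factory=lambda: dict(ALPHA))
    trait: str = ""

    CATEGORY_ORDER = ("A", "D", "I", "AE", "DE", "IE")

    def __post_init__(self):
        for cat in self.CATEGORY_ORDER:
            self.categories.setdefault(cat, 0.0)

    @property
    def total(self) -> float:
        return total_heritability(self)

    def to_frame(self) -> pd.DataFrame:
        row = {"trait": self.trait}
        row.update({f"h2_{c}": self.categories[c] for c in self.CATEGORY_ORDER})
        row["h2_T"] = self.total
        return pd.DataFrame([row])


def total_heritability(h: HeritabilityTable) -> float:
    """Total heritability: the exact sum of the six category percentages."""
    return float(sum(h.categories[c] for c in h.CATEGORY_ORDER))


def decompose(m: MappingResult, mode: str = "empirical"
              ) -> tuple[VarianceDecomposition, HeritabilityTable]:
    """Partition a mapping result into variance components and heritability.

    ``mode="empirical"`` (default) takes each effect's contribution as
    posterior mean^2 times its design-column variance (realized convention,
    no alpha); ``mode="posterior"`` uses the variance-component convention
    alpha * (posterior mean^2 + posterior variance).
    """
    if mode not in ("posterior", "empirical"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "empirical":
        if m.col_var is None:
            raise ValueError("empirical mode needs design column variances")
        contrib = m.post_mean ** 2 * m.col_var
        scale = {c: 1.0 for c in TERM_CLASSES}
    else:
        contrib = m.post_mean ** 2 + m.post_se ** 2
        scale = {c: alpha_for(c) for c in TERM_CLASSES}

    by_class = {c: 0.0 for c in TERM_CLASSES}
    per_term = {}
    for j, t in enumerate(m.terms):
        v = scale[t.cls] * float(contrib[j])
        by_class[t.cls] += v
        per_term[t.label()] = v
    decomp = VarianceDecomposition(by_class=by_class, v_eps=float(m.sigma2_resid))
    if decomp.v_p <= 0:
        raise ValueError("phenotypic variance is not positive")

    per_effect = {lbl: 100.0 * v / decomp.v_p for lbl, v in per_term.items()}
    categories = {cat: 0.0 for cat in HeritabilityTable.CATEGORY_ORDER}
    for j, t in enumerate(m.terms):
        categories[_CLASS_TO_CATEGORY[t.cls]] += per_effect[t.label()]
    table = HeritabilityTable(categories=categories, per_effect=per_effect,
                              trait=m.trait)
    return decomp, table
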