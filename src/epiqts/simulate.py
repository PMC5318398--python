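"""Synthetic line/hybrid populations with known genetic architecture.

The generator emulates an NCII-like mating design: a few female tester lines
crossed to many male inbred lines, the F1 hybrids evaluated alongside all
parents in several environments with replication.  Defaults mirror a design of
2 females x 149 males producing 216 hybrids (97 + 119), i.e. 367 subjects,
two environments, and SNPs with minor-allele frequencies in 0.05-0.17.

Inbred genotypes are drawn per locus i.i.d. with the minor-homozygote state at
probability MAF (no linkage disequilibrium); hybrids follow by Mendelian F1
derivation from the homozygous parents.  Phenotypes follow the full genetic
model (additive, dominance, digenic epistasis, environment interactions) with
Gaussian residual noise; replicates share genotype and differ only by noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import design as dz
from .datamodel import (CrossPlan, GenotypeMatrix, PhenotypeTable, SNPLocus,
                        concat_genotypes, derive_f1_genotypes, QH, QQ, qq)


@dataclass
class DesignSpec:
    """Mating design and measurement layout of a simulated study."""

    n_females: int = 2
    n_males: int = 149
    crosses_per_female: tuple = (97, 119)
    n_snps: int = 100
    maf_range: tuple = (0.05, 0.17)
    n_environments: int = 2
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.crosses_per_female) != self.n_females:
            raise ValueError("crosses_per_female must have one entry per female")
        if any(c > self.n_males for c in self.crosses_per_female):
            raise ValueError("cannot cross a female to more males than exist")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @property
    def n_hybrids(self) -> int:
        return int(sum(self.crosses_per_female))

    @property
    def n_subjects(self) -> int:
        return self.n_females + self.n_males + self.n_hybrids

    @property
    def environments(self) -> list:
        return [f"E{i + 1}" for i in range(self.n_environments)]


@dataclass
class EffectSet:
    """All effect terms of the full genetic model, keyed by locus / pair / env.

    Pair keys are stored with the first locus first in panel order; for a pair
    (i, j), ``ad`` means additive at i times dominance at j and ``da`` the
    reverse.  Absent keys are zero effects.
    """

    mu: float = 0.0
    env_effects: dict = field(default_factory=dict)  # env -> e_h
    additive: dict = field(default_factory=dict)  # locus -> a
    dominance: dict = field(default_factory=dict)  # locus -> d
    epistasis: dict = field(default_factory=dict)  # (cls, i, j) -> effect
    env_main: dict = field(default_factory=dict)  # (cls, locus, env) -> effect
    env_epistasis: dict = field(default_factory=dict)  # (cls, i, j, env) -> effect
    residual_sd: float = 1.0

    def set_effect(self, cls: str, loci: tuple, value: float,
                   env: str = None) -> None:
        cls = cls.lower()
        if cls == "a":
            self.additive[loci[0]] = value
        elif cls == "d":
            self.dominance[loci[0]] = value
        elif cls in dz.PAIR_CLASSES:
            self.epistasis[(cls, loci[0], loci[1])] = value
        elif cls in dz.ENV_MAIN_CLASSES:
            self.env_main[(cls, loci[0], env)] = value
        elif cls in dz.ENV_PAIR_CLASSES:
            self.env_epistasis[(cls, loci[0], loci[1], env)] = value
        else:
            raise KeyError(f"unknown effect class {cls!r}")

    def term_map(self) -> dict:
        """Every nonzero effect as a ``design.Term`` -> value mapping."""
        out = {}
        for l, v in self.additive.items():
            out[dz.Term("a", (l,))] = v
        for l, v in self.dominance.items():
            out[dz.Term("d", (l,))] = v
        for (cls, i, j), v in self.epistasis.items():
            out[dz.Term(cls, (i, j))] = v
        for (cls, l, env), v in self.env_main.items():
            out[dz.Term(cls, (l,), env)] = v
        for (cls, i, j, env), v in self.env_epistasis.items():
            out[dz.Term(cls, (i, j), env)] = v
        return out

    def loci(self) -> list:
        """Loci carrying any nonzero effect, in first-appearance order."""
        seen = []
        for t in self.term_map():
            for l in t.loci:
                if l not in seen:
                    seen.append(l)
        return seen


@dataclass
class SimulationTruth:
    """Ground truth of a simulated trait: the generating effects and the
    variance decomposition they imply in the emitted population."""

    effect_set: EffectSet
    qts_loci: list
    variance_components: dict  # term class -> empirical variance of contribution
    v_genetic: float  # within-environment variance of total genotypic value
    v_residual_cell: float  # residual variance at replicate-mean level
    h2_total: float


def simulate_population(spec: DesignSpec) -> tuple[GenotypeMatrix, CrossPlan]:
    """Simulate inbred parents plus F1 hybrids under the mating design.

    Returns a single genotype matrix holding the inbreds followed by the
    hybrids (subject_class distinguishes them) and the realized cross plan.
    Males are sampled without replacement per female.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [f"A{i:02d}" for i in range(1, 11)] + [f"C{i:02d}" for i in range(1, 10)]
    letters = np.array(list("ACGT"))
    loci = []
    for j in range(spec.n_snps):
        a1, a2 = rng.choice(4, size=2, replace=False)
        loci.append(SNPLocus(id=f"{chroms[j % len(chroms)]}_M{j + 1}",
                             chromosome=chroms[j % len(chroms)],
                             major_allele=str(letters[a1]),
                             minor_allele=str(letters[a2])))

    females = [f"F{i + 1}" for i in range(spec.n_females)]
    males = [f"L{i + 1:03d}" for i in range(spec.n_males)]
    inbred_ids = females + males
    maf = rng.uniform(*spec.maf_range, size=spec.n_snps)
    minor = rng.random((len(inbred_ids), spec.n_snps)) < maf
    calls = np.where(minor, qq, QQ).astype(np.int8)
    parents = GenotypeMatrix(
        calls=pd.DataFrame(calls, index=inbred_ids,
                           columns=[l.id for l in loci], dtype=np.int8),
        loci=loci,
        subject_class=pd.Series("inbred_line", index=inbred_ids, dtype=object))

    crosses = []
    for f, n_cross in zip(females, spec.crosses_per_female):
        chosen = rng.choice(spec.n_males, size=n_cross, replace=False)
        for m in sorted(chosen):
            crosses.append((f, males[m], f"{f}x{males[m]}"))
    plan = CrossPlan(crosses=crosses)
    hybrids = derive_f1_genotypes(parents, plan)
    return concat_genotypes(parents, hybrids), plan


def assign_true_effects(loci: list, architecture: dict, seed: int = 0) -> EffectSet:
    """Build an EffectSet from an architecture description.

    ``architecture`` keys (all optional):

    - ``mu``: population mean (trait units).
    - ``env_effects``: sequence of e_h values, one per environment.
    - ``fixed``: mapping ``(cls, loci_tuple)`` or ``(cls, loci_tuple, env)``
      -> exact effect value.
    - ``classes``: mapping term class -> ``{"n": count, "range": (lo, hi)}``;
      ``n`` effects of that class are placed on seeded draws of loci (pairs for
      digenic classes, (locus, env) for environment classes) with values drawn
      uniformly from ``range``.
    - ``n_qts``: size of the locus pool the sampled classes draw from
      (default 2, taken as a seeded subset of ``loci``).
    - ``environments``: environment ids for sampled environment classes.
    - ``residual_sd``: residual standard deviation (default 1.0).

    Inactive classes are exactly zero.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    arch = dict(architecture)
    envs = list(arch.get("environments", ["E1", "E2"]))
    eff = EffectSet(mu=float(arch.get("mu", 0.0)),
                    env_effects={e: float(v) for e, v in
                                 zip(envs, arch.get("env_effects", []))},
                    residual_sd=float(arch.get("residual_sd", 1.0)))

    for key, value in arch.get("fixed", {}).items():
        cls, term_loci = key[0], tuple(key[1])
        env = key[2] if len(key) > 2 else None
        for l in term_loci:
            if l not in loci:
                raise KeyError(f"effect locus {l!r} not in locus panel")
        eff.set_effect(cls, term_loci, float(value), env)

    sampled = arch.get("classes", {})
    if sampled:
        n_qts = int(arch.get("n_qts", 2))
        pool = [loci[i] for i in rng.choice(len(loci), size=min(n_qts, len(loci)),
                                            replace=False)]
        pairs = list(itertools.combinations(pool, 2))
        for cls, desc in sampled.items():
            cls = cls.lower()
            n = int(desc.get("n", 1))
            lo, hi = desc["range"]
            for _ in range(n):
                value = float(rng.uniform(lo, hi))
                env = envs[rng.integers(len(envs))] if cls in dz.ENV_CLASSES else None
                if cls in ("a", "d") or cls in dz.ENV_MAIN_CLASSES:
                    target = (pool[rng.integers(len(pool))],)
                else:
                    if not pairs:
                        raise ValueError("digenic class needs >= 2 QTS loci")
                    target = pairs[rng.integers(len(pairs))]
                eff.set_effect(cls, target, value, env)
    return eff


def genotypic_values(g: GenotypeMatrix, eff: EffectSet,
                     environments: list) -> pd.DataFrame:
    """Total genotypic deviation (no mu, e_h, or noise) per subject x environment."""
    terms = eff.term_map()
    qts = eff.loci()
    for l in qts:
        if l not in g.calls.columns:
            raise KeyError(f"QTS locus {l!r} absent from genotype matrix")
    out = pd.DataFrame(0.0, index=g.calls.index, columns=environments)
    if not qts:
        return out
    A, D = dz.coefficient_columns(g, qts)
    A = A.astype(float)
    D = D.astype(float)
    col = {l: k for k, l in enumerate(qts)}
    factor = {"a": A, "d": D}
    for term, value in terms.items():
        base = dz.BASE_OF_ENV.get(term.cls, term.cls)
        if len(term.loci) == 1:
            contrib = factor[base[0]][:, col[term.loci[0]]] * value
        else:
            fi, fj = dz._FACTORS[base]
            contrib = (factor[fi][:, col[term.loci[0]]]
                       * factor[fj][:, col[term.loci[1]]]) * value
        if term.env is None:
            for e in environments:
                out[e] += contrib
        else:
            out[term.env] += contrib
    return out


def simulate_phenotypes(g: GenotypeMatrix, eff: EffectSet,
                        spec: DesignSpec, trait: str = "T1") -> PhenotypeTable:
    """Forward-simulate phenotype records from the full genetic model.

    value(subject, env, rep) = mu + e_h + total genotypic deviation +
    N(0, residual_sd); deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    envs = spec.environments
    gv = genotypic_values(g, eff, envs)
    n_s, n_e, n_r = gv.shape[0], len(envs), spec.n_replicates
    noise = rng.normal(0.0, eff.residual_sd, size=(n_s, n_e, n_r)) \
        if eff.residual_sd > 0 else np.zeros((n_s, n_e, n_r))
    e_h = np.array([eff.env_effects.get(e, 0.0) for e in envs])
    values = eff.mu + e_h[None, :, None] + gv.to_numpy()[:, :, None] + noise
    subj = np.repeat(gv.index.to_numpy(), n_e * n_r)
    env = np.tile(np.repeat(envs, n_r), n_s)
    rep = np.tile(np.arange(1, n_r + 1), n_s * n_e)
    return PhenotypeTable(records=pd.DataFrame({
        "subject": subj, "environment": env, "replicate": rep,
        "trait": trait, "value": values.ravel()}))


def make_truth(g: GenotypeMatrix, eff: EffectSet, spec: DesignSpec
               ) -> SimulationTruth:
    """Empirical variance decomposition of the generating model in ``g``.

    Per-class variances are variances of that class's summed contribution over
    (subject, environment) cells after removing per-environment means; classes
    are not orthogonal in a finite population, so they need not sum to the
    total.  ``h2_total`` is the heritability at the replicate-mean analysis
    level: V_(G+GE) / (V_(G+GE) + residual_sd^2 / n_replicates).
    """
    envs = spec.environments
    per_class = {}
    for cls in dz.TERM_CLASSES:
        sub = EffectSet(mu=0.0)
        for term, v in eff.term_map().items():
            if term.cls == cls:
                sub.set_effect(term.cls, term.loci, v, term.env)
        if not sub.term_map():
            per_class[cls] = 0.0
            continue
        gv = genotypic_values(g, sub, envs).to_numpy()
        gv = gv - gv.mean(axis=0, keepdims=True)
        per_class[cls] = float(gv.var())
    total = genotypic_values(g, eff, envs).to_numpy()
    total = total - total.mean(axis=0, keepdims=True)
    v_gen = float(total.var())
    v_res = eff.residual_sd ** 2 / spec.n_replicates
    h2 = v_gen / (v_gen + v_res) if (v_gen + v_res) > 0 else 0.0
    return SimulationTruth(effect_set=eff, qts_loci=eff.loci(),
                           variance_components=per_class, v_genetic=v_gen,
                           v_residual_cell=v_res, h2_total=h2)


def tune_residual_to_heritability(g: GenotypeMatrix, eff: EffectSet,
                                  spec: DesignSpec, h2_target: float
                                  ) -> EffectSet:
    """Set residual_sd so total heritability at the replicate-mean level is
    ``h2_target`` in this population."""
    if not 0 < h2_target < 1:
        raise ValueError("h2_target must be in (0, 1)")
    truth = make_truth(g, replace(eff, residual_sd=0.0), spec)
    v_gen = truth.v_genetic
    sd = float(np.sqrt(spec.n_replicates * v_gen * (1 - h2_target) / h2_target))
    return replace(eff, residual_sd=sd)


def select_qts_pair(g: GenotypeMatrix, females: list) -> tuple:
    """Pick a pair of effect loci whose digenic effects are identifiable in
    this population.

    With few female testers a dominance contrast at a locus is carried almost
    entirely by the hybrids of the female that holds the minor allele there,
    so a dominance effect and a dominance x additive product are separated
    only by hybrids in the (heterozygote, minor-homozygote) cells.  This
    helper restricts candidates to loci whose minor allele is carried by
    exactly one female (a distinct female per locus) and returns the pair
    maximizing the scarcer of the two separating cell counts — a study-design
    condition fixed before any phenotype exists.
    """
    calls = g.calls
    hyb = g.subject_class[g.subject_class == "f1_hybrid"].index
    by_female = {}
    for l in calls.columns:
        carriers = tuple(f for f in females if calls.at[f, l] == qq)
        if len(carriers) == 1:
            by_female.setdefault(carriers[0], []).append(l)
    groups = [by_female[f] for f in females if f in by_female]
    if len(groups) < 2:
        raise ValueError(
            "panel lacks loci segregating in two distinct female testers")
    hcalls = calls.loc[hyb]
    best, best_score = None, -1
    for l1 in groups[0]:
        h1 = hcalls[l1].to_numpy()
        for l2 in groups[1]:
            h2 = hcalls[l2].to_numpy()
            n12 = int(((h1 == QH) & (h2 == qq)).sum())
            n21 = int(((h1 == qq) & (h2 == QH)).sum())
            score = min(n12, n21)
            if score > best_score:
                best, best_score = (l1, l2), score
    return best


def ph_like_architecture(locus_1: str, locus_2: str) -> dict:
    """A plant-height-like two-locus architecture: one locus with a = 4.59 and
    d = 13.09, one with a = -7.11 and d = -3.57, and a dominance x additive
    epistasis of -11.00 between them."""
    return {
        "mu": 134.0,
        "env_effects": [0.0, 1.0],
        "fixed": {
            ("a", (locus_1,)): 4.59,
            ("d", (locus_1,)): 13.09,
            ("a", (locus_2,)): -7.11,
            ("d", (locus_2,)): -3.57,
            ("da", (locus_1, locus_2)): -11.00,
        },
    }
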