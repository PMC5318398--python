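"""Simulation studies validating the estimation pipeline end to end.

Each study regenerates its data from the synthetic-population module at the
study's mating-design scale (367 subjects: 151 inbreds + 216 hybrids, two
environments) and runs the same code paths a real analysis would.  They back
the reproducibility script and the analysis drivers.

Problem sizes are chosen for a single-CPU desk run: 20 replicate fits of a
5,000-iteration chain for parameter recovery, and 200 null datasets with 200
permutations each for the family-wise error-rate study (a scaled-down version
of the 2,000-permutation production setting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import simulate as sim
from .design import ModelSpec, build_design_matrix, orient_term
from .mapping import (McmcSpec, fit_gibbs, permutation_threshold,
                      prediction_correlation, term_statistics)
from .heritability import decompose


def study_design_spec(n_snps: int = 200, seed: int = 0,
                      **kwargs) -> sim.DesignSpec:
    """The study's mating design: 2 female testers x 149 males, 216 hybrids."""
    return sim.DesignSpec(n_females=2, n_males=149,
                          crosses_per_female=(97, 119), n_snps=n_snps,
                          seed=seed, **kwargs)


def _ph_like_fit(seed: int, n_iterations: int, h2_target: float = 0.85,
                 residual_sd: float = None):
    """Simulate one PH-like population and fit the full two-locus model."""
    spec = study_design_spec(seed=seed)
    g, _ = sim.simulate_population(spec)
    l1, l2 = sim.select_qts_pair(g, ["F1", "F2"])
    eff = sim.assign_true_effects(g.locus_ids,
                                  sim.ph_like_architecture(l1, l2), seed=seed)
    if residual_sd is None:
        eff = sim.tune_residual_to_heritability(g, eff, spec, h2_target)
    else:
        from dataclasses import replace
        eff = replace(eff, residual_sd=residual_sd)
    p = sim.simulate_phenotypes(g, eff, spec)
    cands = sorted([l1, l2], key=g.locus_ids.index)
    ms = ModelSpec(candidate_loci=cands, environments=spec.environments)
    x = build_design_matrix(g, p, ms, "T1")
    result = fit_gibbs(x, McmcSpec(n_iterations=n_iterations,
                                   burn_in=max(n_iterations // 5, 200),
                                   seed=seed + 10_000))
    return x, result, eff, cands


@dataclass
class RecoveryStudy:
    per_seed: list  # one bool per replicate: every true effect within 2 SE
    details: list  # (seed, term label, truth, posterior mean, posterior se)

    @property
    def fraction_recovered(self) -> float:
        return float(np.mean(self.per_seed))


def parameter_recovery_study(n_seeds: int = 20, n_iterations: int = 5000,
                             seed: int = 0) -> RecoveryStudy:
    """Parameter recovery of a plant-height-like architecture.

    Two QTS loci (a = 4.59 / d = 13.09 and a = -7.11 / d = -3.57) with a
    dominance x additive interaction of -11.00, residual noise tuned so total
    heritability is 0.85.  A replicate counts as recovered when every true
    effect lies within two posterior standard errors of its posterior mean.
    """
    per_seed, details = [], []
    for k in range(n_seeds):
        rep_seed = (seed + k * 1009) % (2 ** 31)
        x, result, eff, cands = _ph_like_fit(rep_seed, n_iterations)
        ok = True
        for term, truth in eff.term_map().items():
            term = orient_term(term, cands)
            j = x.terms.index(term)
            m, s = result.post_mean[j], result.post_se[j]
            details.append((rep_seed, term.label(), truth, float(m), float(s)))
            if abs(m - truth) > 2 * s:
                ok = False
        per_seed.append(ok)
    return RecoveryStudy(per_seed=per_seed, details=details)


def familywise_error_study(n_sims: int = 200, n_perm: int = 200,
                           alpha: float = 0.05, seed: int = 0) -> dict:
    """Empirical experiment-wise type-I error of the permutation threshold.

    Null populations (environment offsets plus residual noise, no genetic
    effects) are simulated at the study scale; a simulation counts as a
    family-wise error when any term of the full two-locus model exceeds the
    permutation critical value at the given alpha.
    """
    hits = 0
    for k in range(n_sims):
        rep_seed = (seed + k * 613) % (2 ** 31)
        spec = study_design_spec(n_snps=4, seed=rep_seed)
        g, _ = sim.simulate_population(spec)
        eff = sim.EffectSet(mu=0.0, env_effects={"E1": 0.0, "E2": 1.0},
                            residual_sd=1.0)
        p = sim.simulate_phenotypes(g, eff, spec)
        ms = ModelSpec(candidate_loci=g.locus_ids[:2],
                       environments=spec.environments)
        x = build_design_matrix(g, p, ms, "T1")
        null = permutation_threshold(x, n_perm=n_perm, alpha=alpha,
                                     spec=McmcSpec(seed=rep_seed + 1))
        if term_statistics(x).max() > null.critical:
            hits += 1
    return {"fwer": hits / n_sims, "n_sims": n_sims, "n_perm": n_perm,
            "alpha": alpha}


def noiseless_limit_study(seed: int = 0, n_iterations: int = 3000) -> dict:
    """With zero residual noise the fitted genotypic values must reproduce
    the phenotypes (R_Yhat = 1) and the heritability partition must absorb
    all phenotypic variance."""
    x, result, eff, _ = _ph_like_fit(seed, n_iterations, residual_sd=0.0)
    corr = prediction_correlation(result, x)
    _, table = decompose(result)
    return {"r_yhat": corr["pooled"], "h2_total": table.total}
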