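import numpy as np
import pytest

import epiqts as e
from epiqts.design import Term


def single_locus_design(effect=1.0, noise=0.0, seed=0, n_males=60,
                        classes=("a",)):
    spec = e.DesignSpec(n_females=2, n_males=n_males,
                        crosses_per_female=(n_males // 2, n_males // 2),
                        n_snps=10, n_replicates=2, seed=seed)
    g, _ = e.simulate_population(spec)
    locus = g.locus_ids[0]
    eff = e.EffectSet(mu=10.0, additive={locus: effect}, residual_sd=noise)
    p = e.simulate_phenotypes(g, eff, spec)
    ms = e.ModelSpec(candidate_loci=[locus], classes=classes,
                     environments=["E1", "E2"])
    return e.build_design_matrix(g, p, ms, "T1"), locus, g, p


class TestFitGibbs:
    def test_noiseless_additive_effect_recovered_exactly(self):
        x, locus, _, _ = single_locus_design(effect=1.0, noise=0.0)
        r = e.fit_gibbs(x, e.McmcSpec(n_iterations=4000, burn_in=1000, seed=1))
        j = x.terms.index(Term("a", (locus,)))
        assert r.post_mean[j] == pytest.approx(1.0, abs=0.02)

    def test_all_zero_column_stays_at_prior(self):
        # a monomorphic locus yields an all-zero dominance column
        x, locus, g, p = single_locus_design(effect=1.0, noise=0.1,
                                             classes=("a", "d"))
        jd = x.terms.index(Term("d", (locus,)))
        if x.X[:, jd].any():  # make the column zero explicitly
            x.X[:, jd] = 0.0
        r = e.fit_gibbs(x, e.McmcSpec(n_iterations=4000, burn_in=1000, seed=2))
        assert abs(r.post_mean[jd]) < 3 * r.post_se[jd]
        assert r.post_se[jd] > 0

    def test_seed_pairs_agree_within_mc_error(self):
        x, locus, _, _ = single_locus_design(effect=2.0, noise=0.5)
        spec1 = e.McmcSpec(n_iterations=6000, burn_in=2000, seed=3)
        spec2 = e.McmcSpec(n_iterations=6000, burn_in=2000, seed=99)
        r1, r2 = e.fit_gibbs(x, spec1), e.fit_gibbs(x, spec2)
        tol = 3 * np.sqrt(r1.mc_se ** 2 + r2.mc_se ** 2)
        assert np.all(np.abs(r1.post_mean - r2.post_mean) <= tol + 1e-9)

    def test_posterior_means_unbiased_over_replicates(self):
        """Average bias of a and d estimates over 50 simulated replicates is
        below a tenth of the effect size."""
        errs_a, errs_d = [], []
        for seed in range(50):
            spec = e.DesignSpec(n_females=2, n_males=40,
                                crosses_per_female=(20, 20), n_snps=20,
                                n_replicates=2, seed=seed)
            g, _ = e.simulate_population(spec)
            try:
                l1, l2 = e.simulate.select_qts_pair(g, ["F1", "F2"])
            except ValueError:
                continue
            eff = e.EffectSet(mu=10.0, additive={l1: 2.0},
                              dominance={l1: 4.0}, residual_sd=1.0)
            p = e.simulate_phenotypes(g, eff, spec)
            ms = e.ModelSpec(candidate_loci=[l1], classes=("a", "d"),
                             environments=["E1", "E2"])
            x = e.build_design_matrix(g, p, ms, "T1")
            r = e.fit_gibbs(x, e.McmcSpec(n_iterations=2000, burn_in=500,
                                          seed=seed))
            errs_a.append(r.post_mean[x.terms.index(Term("a", (l1,)))] - 2.0)
            errs_d.append(r.post_mean[x.terms.index(Term("d", (l1,)))] - 4.0)
        assert abs(np.mean(errs_a)) < 0.2  # 0.1 x effect size 2
        assert abs(np.mean(errs_d)) < 0.4  # 0.1 x effect size 4

    def test_nonfinite_response_rejected(self):
        x, _, _, _ = single_locus_design()
        x.y[0] = np.nan
        with pytest.raises(ValueError):
            e.fit_gibbs(x, e.McmcSpec(n_iterations=100, burn_in=10))


class TestPermutationThreshold:
    def test_quantile_edge_at_20_permutations(self):
        x, _, _, _ = single_locus_design(effect=0.0, noise=1.0)
        null = e.permutation_threshold(x, n_perm=20, alpha=0.05,
                                       spec=e.McmcSpec(seed=4))
        assert null.critical == pytest.approx(null.maxima.max())

    def test_constant_response_threshold_zero(self):
        x, _, _, _ = single_locus_design(effect=0.0, noise=0.0)
        null = e.permutation_threshold(x, n_perm=30, alpha=0.05,
                                       spec=e.McmcSpec(seed=4))
        assert null.critical == 0.0

    def test_too_few_permutations_rejected(self):
        x, _, _, _ = single_locus_design()
        with pytest.raises(ValueError):
            e.permutation_threshold(x, n_perm=10)

    def test_observed_null_exceedance_near_alpha(self):
        """Family-wise error of the permutation threshold on null data."""
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            spec = e.DesignSpec(n_females=2, n_males=30,
                                crosses_per_female=(15, 15), n_snps=6,
                                n_replicates=2, seed=seed)
            g, _ = e.simulate_population(spec)
            eff = e.EffectSet(mu=0.0, env_effects={"E1": 0, "E2": 1},
                              residual_sd=1.0)
            p = e.simulate_phenotypes(g, eff, spec)
            ms = e.ModelSpec(candidate_loci=g.locus_ids[:2],
                             environments=["E1", "E2"])
            x = e.build_design_matrix(g, p, ms, "T1")
            null = e.permutation_threshold(x, n_perm=100, alpha=0.05,
                                           spec=e.McmcSpec(seed=seed + 1))
            if e.mapping.term_statistics(x).max() > null.critical:
                hits += 1
        assert 0.0 <= hits / n_sim <= 0.12


class TestSignificance:
    def fit_with_planted_dominance(self):
        spec = e.DesignSpec(n_females=2, n_males=60,
                            crosses_per_female=(30, 30), n_snps=10,
                            n_replicates=2, seed=6)
        g, _ = e.simulate_population(spec)
        locus = next(l for l in g.locus_ids if (g.calls[l] == 1).sum() > 10)
        eff = e.EffectSet(mu=10.0, dominance={locus: 5.0}, residual_sd=0.5)
        p = e.simulate_phenotypes(g, eff, spec)
        ms = e.ModelSpec(candidate_loci=[locus], classes=("a", "d"),
                         environments=["E1", "E2"])
        x = e.build_design_matrix(g, p, ms, "T1")
        r = e.fit_gibbs(x, e.McmcSpec(n_iterations=3000, burn_in=1000, seed=7))
        null = e.permutation_threshold(x, n_perm=200, alpha=0.05,
                                       spec=e.McmcSpec(seed=8))
        return r, null, locus

    def test_planted_dominance_retained(self):
        r, null, locus = self.fit_with_planted_dominance()
        table = e.significance(r, null)
        assert f"d:{locus}" in set(table.entries["term"])

    def test_empirical_p_floor_flagged(self):
        r, null, locus = self.fit_with_planted_dominance()
        table = e.significance(r, null)
        row = table.entries[table.entries["term"] == f"d:{locus}"].iloc[0]
        # statistic beats all 200 null maxima -> floor -log10(201)
        assert row["neglog_pew"] == pytest.approx(np.log10(201))
        assert bool(row["p_floor"])

    def test_median_null_statistic_has_p_half(self):
        x, _, _, _ = single_locus_design(effect=0.0, noise=1.0)
        null = e.permutation_threshold(x, n_perm=200, alpha=0.05,
                                       spec=e.McmcSpec(seed=9))
        r = e.fit_gibbs(x, e.McmcSpec(n_iterations=1000, burn_in=200, seed=9))
        r.stats = np.array([np.median(null.maxima)])
        e.significance(r, null)
        assert 10 ** (-r.neglog_pew[0]) == pytest.approx(0.5, abs=0.05)


class TestPredictionCorrelation:
    def test_noiseless_fit_has_unit_correlation(self):
        x, locus, _, _ = single_locus_design(effect=2.0, noise=0.0)
        r = e.fit_gibbs(x, e.McmcSpec(n_iterations=3000, burn_in=1000,
                                      seed=10))
        corr = e.prediction_correlation(r, x)
        assert corr["pooled"] == pytest.approx(1.0, abs=1e-3)

    def test_pure_noise_has_low_correlation(self):
        x, locus, _, _ = single_locus_design(effect=0.0, noise=1.0,
                                             n_males=100)
        r = e.fit_gibbs(x, e.McmcSpec(n_iterations=3000, burn_in=1000,
                                      seed=11))
        corr = e.prediction_correlation(r, x)
        assert abs(corr["pooled"]) < 0.35
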