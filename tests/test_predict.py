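import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epiqts as e
from epiqts.datamodel import QH, QQ, qq
from conftest import make_qts_table, oracle_value

STATES = (QQ, QH, qq)


def random_table(rng, n_loci=None):
    """A random effect table over up to 6 loci and all term classes."""
    n_loci = n_loci or rng.integers(1, 7)
    loci = [f"L{i}" for i in range(n_loci)]
    effects = {}
    for l in loci:
        if rng.random() < 0.7:
            effects[("a", (l,))] = rng.normal(0, 2)
        if rng.random() < 0.7:
            effects[("d", (l,))] = rng.normal(0, 2)
        if rng.random() < 0.3:
            effects[("ae", (l,), "E1")] = rng.normal(0, 1)
    for i, j in itertools.combinations(loci, 2):
        for cls in ("aa", "ad", "da", "dd"):
            if rng.random() < 0.3:
                effects[(cls, (i, j))] = rng.normal(0, 1.5)
        if rng.random() < 0.15:
            effects[("dde", (i, j), "E2")] = rng.normal(0, 1)
    if not effects:
        effects[("a", (loci[0],))] = 1.0
    return make_qts_table(effects), loci


def brute_force_optimum(q, env, space, direction):
    loci = q.loci()
    states = (QQ, qq) if space == "lines" else STATES
    best_combo, best = None, None
    for combo_states in itertools.product(states, repeat=len(loci)):
        combo = dict(zip(loci, combo_states))
        v = oracle_value(combo, env, q)
        better = best is None or (v > best if direction == "maximize"
                                  else v < best)
        if better:
            best, best_combo = v, combo
    return best_combo, best


class TestGenotypicValue:
    def test_additive_only(self):
        q = make_qts_table({("a", ("L1",)): 1.0})
        assert e.genotypic_value({"L1": QQ}, "E1", q) == 1.0
        assert e.genotypic_value({"L1": qq}, "E1", q) == -1.0

    def test_dominance_only(self):
        q = make_qts_table({("d", ("L1",)): 2.0})
        assert e.genotypic_value({"L1": QH}, "E1", q) == 2.0
        assert e.genotypic_value({"L1": QQ}, "E1", q) == 0.0

    def test_dd_epistasis_only(self):
        q = make_qts_table({("dd", ("L1", "L2")): 4.0})
        assert e.genotypic_value({"L1": QH, "L2": QH}, "E1", q) == 4.0
        assert e.genotypic_value({"L1": QQ, "L2": QH}, "E1", q) == 0.0

    def test_environment_specific_term_masked(self):
        q = make_qts_table({("de", ("L1",), "E2"): 3.0})
        assert e.genotypic_value({"L1": QH}, "E1", q) == 0.0
        assert e.genotypic_value({"L1": QH}, "E2", q) == 3.0

    def test_missing_locus_rejected(self):
        q = make_qts_table({("a", ("L1",)): 1.0})
        with pytest.raises(KeyError):
            e.genotypic_value({}, "E1", q)

    def test_agrees_with_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            q, loci = random_table(rng, n_loci=3)
            combo = {l: STATES[rng.integers(3)] for l in loci}
            for env in ("E1", "E2"):
                assert e.genotypic_value(combo, env, q) == pytest.approx(
                    oracle_value(combo, env, q))


class TestUniformGenotypeValues:
    @given(a1=st.floats(-10, 10), a2=st.floats(-10, 10),
           aa=st.floats(-10, 10))
    @settings(deadline=None, max_examples=50)
    def test_uniform_value_identity_holds_for_any_effects(self, a1, a2, aa):
        """value(all-QQ) + value(all-qq) = 2 * sum(aa) for any additive and
        additive-by-additive effects (dominance-free closed form)."""
        q = make_qts_table({("a", ("L1",)): a1, ("a", ("L2",)): a2,
                            ("aa", ("L1", "L2")): aa})
        v_qq, v_minor, v_het = e.uniform_genotype_values(q, "E1")
        assert v_qq + v_minor == pytest.approx(2 * aa, abs=1e-9)
        assert v_het == 0.0

    def test_additive_antisymmetry(self):
        q = make_qts_table({("a", ("L1",)): 2.0, ("a", ("L2",)): -1.0})
        v_qq, v_minor, v_het = e.uniform_genotype_values(q, "E1")
        assert v_qq == -v_minor
        assert v_het == 0.0

    def test_aa_terms_break_antisymmetry_by_twice_their_sum(self):
        q = make_qts_table({("a", ("L1",)): 1.0, ("aa", ("L1", "L2")): 2.0,
                            ("aa", ("L2", "L3")): -0.5})
        v_qq, v_minor, _ = e.uniform_genotype_values(q, "E1")
        assert v_qq + v_minor == pytest.approx(2 * (2.0 - 0.5))

    def test_empty_table(self):
        q = make_qts_table({})
        assert e.uniform_genotype_values(q, "E1") == (0.0, 0.0, 0.0)


class TestSuperiorCombination:
    def test_negative_additive_minimized_at_major_homozygote(self):
        q = make_qts_table({("a", ("L1",)): -3.67})
        combo, value = e.superior_combination(q, "E1", "lines", "minimize")
        assert combo == {"L1": QQ}
        assert value == pytest.approx(-3.67)

    def test_large_dominance_needs_hybrid(self):
        q = make_qts_table({("d", ("L1",)): 13.09})
        _, v_hyb = e.superior_combination(q, "E1", "hybrids", "maximize")
        _, v_line = e.superior_combination(q, "E1", "lines", "maximize")
        assert v_hyb == pytest.approx(13.09)
        assert v_line == 0.0

    @pytest.mark.parametrize("direction", ["maximize", "minimize"])
    def test_matches_brute_force_on_random_tables(self, direction):
        rng = np.random.default_rng(42)
        for _ in range(60):
            q, _ = random_table(rng)
            for space in ("lines", "hybrids"):
                combo, value = e.superior_combination(q, "E1", space,
                                                      direction)
                _, expected = brute_force_optimum(q, "E1", space, direction)
                assert value == pytest.approx(expected)
                assert oracle_value(combo, "E1", q) == pytest.approx(value)

    def test_hybrid_space_dominates_line_space(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            q, _ = random_table(rng, n_loci=int(rng.integers(1, 5)))
            _, v_line = e.superior_combination(q, "E1", "lines", "maximize")
            _, v_hyb = e.superior_combination(q, "E1", "hybrids", "maximize")
            assert v_hyb >= v_line - 1e-12

    def test_branch_and_bound_agrees_with_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            q, _ = random_table(rng, n_loci=4)
            for space, direction in (("hybrids", "maximize"),
                                     ("lines", "minimize")):
                _, v1 = e.superior_combination(q, "E1", space, direction)
                c2, v2 = e.superior_combination(q, "E1", space, direction,
                                                method="branch_and_bound")
                assert v1 == pytest.approx(v2)

    def test_exhaustive_refuses_large_tables(self):
        effects = {("a", (f"L{i}",)): 1.0 for i in range(16)}
        q = make_qts_table(effects)
        with pytest.raises(ValueError, match="branch_and_bound"):
            e.superior_combination(q, "E1", "hybrids", "maximize")

    def test_tie_break_lexicographic(self):
        # no effects at L1: all states tie; QQ must win
        q = make_qts_table({("a", ("L1",)): 0.0})
        combo, _ = e.superior_combination(q, "E1", "hybrids", "maximize")
        assert combo == {"L1": QQ}


class TestBestInPopulation:
    def make_population(self, seed=0):
        spec = e.DesignSpec(n_females=2, n_males=20,
                            crosses_per_female=(10, 10), n_snps=10,
                            maf_range=(0.2, 0.4), seed=seed)
        g, _ = e.simulate_population(spec)
        return g

    def test_attains_superior_when_combination_realized(self):
        g = self.make_population()
        locus = g.locus_ids[0]
        q = make_qts_table({("a", (locus,)): 2.0})
        # some inbred line is QQ at the locus -> attains the line optimum
        _, value = e.best_in_population(g, q, "E1", "lines", "maximize")
        _, sup = e.superior_combination(q, "E1", "lines", "maximize")
        assert value == pytest.approx(sup)

    def test_never_exceeds_superior(self):
        for seed in range(5):
            g = self.make_population(seed)
            rng = np.random.default_rng(seed)
            effects = {("a", (l,)): rng.normal(0, 1)
                       for l in g.locus_ids[:4]}
            effects[("dd", tuple(g.locus_ids[:2]))] = rng.normal(0, 2)
            q = make_qts_table(effects)
            for subset in ("lines", "hybrids"):
                _, best = e.best_in_population(g, q, "E1", subset, "maximize")
                _, sup = e.superior_combination(q, "E1", "hybrids", "maximize")
                assert best <= sup + 1e-9

    def test_tie_smallest_subject_id(self):
        g = self.make_population()
        q = make_qts_table({})  # all subjects tie at value 0
        sid, value = e.best_in_population(g, q, "E1", "lines", "maximize")
        inbreds = sorted(
            g.subject_class[g.subject_class == "inbred_line"].index)
        assert sid == inbreds[0] and value == 0.0

    def test_empty_subset_rejected(self):
        g = self.make_population()
        parents = g.subset_subjects(
            g.subject_class[g.subject_class == "inbred_line"].index)
        q = make_qts_table({("a", (g.locus_ids[0],)): 1.0})
        with pytest.raises(ValueError):
            e.best_in_population(parents, q, "E1", "hybrids", "maximize")


class TestDonorRecommendation:
    def test_donors_are_exactly_minor_homozygote_lines(self):
        g = TestBestInPopulation().make_population()
        locus = g.locus_ids[0]
        q = make_qts_table({("d", (locus,)): 5.0})
        inbreds = g.subject_class[g.subject_class == "inbred_line"].index
        acceptor = next(s for s in inbreds if g.calls.at[s, locus] == QQ)
        report = e.donor_recommendation(g, [acceptor], q, "E1", "maximize")
        expected = {s for s in inbreds
                    if s != acceptor and g.calls.at[s, locus] == qq}
        assert set(report.donors["donor"]) == expected

    def test_planted_donor_recovered(self):
        g = TestBestInPopulation().make_population(seed=3)
        l1, l2 = g.locus_ids[:2]
        q = make_qts_table({("d", (l1,)): 3.0, ("d", (l2,)): 2.0})
        inbreds = list(g.subject_class[g.subject_class == "inbred_line"].index)
        acceptor = next(s for s in inbreds
                        if (g.calls.loc[s, [l1, l2]] == QQ).all())
        donors = [s for s in inbreds if s != acceptor
                  and (g.calls.loc[s, [l1, l2]] == qq).all()]
        report = e.donor_recommendation(g, [acceptor], q, "E1", "maximize")
        assert set(report.donors["donor"]) == set(donors)

    def test_non_inbred_acceptor_rejected(self):
        g = TestBestInPopulation().make_population()
        hybrid = g.subject_class[g.subject_class == "f1_hybrid"].index[0]
        q = make_qts_table({("a", (g.locus_ids[0],)): 1.0})
        with pytest.raises(ValueError):
            e.donor_recommendation(g, [hybrid], q, "E1")


class TestGpMap:
    def test_dd_only_center_cell(self):
        q = make_qts_table({("dd", ("L1", "L2")): 4.0})
        grid = e.gp_map(q, ("L1", "L2"), "E1")
        assert grid.loc["Qq", "Qq"] == 4.0
        assert grid.to_numpy().sum() == 4.0

    def test_additive_rows_columns(self):
        q = make_qts_table({("a", ("L1",)): 1.0, ("a", ("L2",)): 0.0})
        grid = e.gp_map(q, ("L1", "L2"), "E1")
        assert (grid.loc["QQ"] == 1.0).all()
        assert (grid.loc["Qq"] == 0.0).all()
        assert (grid.loc["qq"] == -1.0).all()

    def test_da_contrast_closed_form(self):
        q = make_qts_table({("da", ("L1", "L2")): -11.0,
                            ("a", ("L2",)): 2.0})
        grid = e.gp_map(q, ("L1", "L2"), "E1")
        # row Qq: D(L1)=1, contrast over A(L2) = (QQ) - (qq) = 2*da + 2*a
        assert grid.loc["Qq", "QQ"] - grid.loc["Qq", "qq"] == pytest.approx(
            2 * (-11.0) + 2 * 2.0)

    def test_pair_without_epistasis_still_computable(self):
        q = make_qts_table({("a", ("L1",)): 1.0, ("a", ("L2",)): 2.0})
        grid = e.gp_map(q, ("L1", "L2"), "E1")
        assert grid.loc["QQ", "QQ"] == 3.0


class TestPredictionReport:
    def test_report_is_internally_consistent(self):
        g = TestBestInPopulation().make_population(seed=4)
        q = make_qts_table({("a", (g.locus_ids[0],)): 2.0,
                            ("d", (g.locus_ids[1],)): 3.0},
                           env_means={"E1": 50.0, "E2": 55.0})
        report = e.build_prediction_report(g, q, "maximize")
        assert set(report.rows["environment"]) == {"E1", "E2"}
        for _, row in report.rows.iterrows():
            assert row["superior_hybrid_value"] >= row["superior_line_value"]
            assert row["best_hybrid_value"] <= row["superior_hybrid_value"]
            assert row["best_line_value"] <= row["superior_line_value"]
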