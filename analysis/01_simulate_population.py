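#!/usr/bin/env python
"""Simulate the study population and a plant-height-like trait.

Generates the mating design (2 female testers x 149 male inbreds, 216 F1
hybrids, 367 subjects), a 200-SNP panel with minor-allele frequencies in
0.05-0.17, and one trait with two QTS loci: a = 4.59 / d = 13.09 at the
first, a = -7.11 / d = -3.57 at the second, and a dominance x additive
interaction of -11.00 between them.  Residual noise is tuned so total
heritability at the replicate-mean level is 0.85.  Writes genotypes,
phenotypes, the cross plan and the generating truth under results/sim/.
"""

import pathlib

import yaml

import epiqts as e
import epiqts.studies as st

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 42


def main():
    spec = st.study_design_spec(n_snps=200, seed=SEED, n_replicates=3)
    g, plan = e.simulate_population(spec)
    l1, l2 = e.simulate.select_qts_pair(g, ["F1", "F2"])
    eff = e.assign_true_effects(g.locus_ids,
                                e.ph_like_architecture(l1, l2), seed=SEED)
    eff = e.tune_residual_to_heritability(g, eff, spec, 0.85)
    pheno = e.simulate_phenotypes(g, eff, spec, trait="PH")
    truth = e.make_truth(g, eff, spec)

    OUT.mkdir(parents=True, exist_ok=True)
    e.write_genotype_table(g, OUT / "genotypes.tsv")
    e.write_phenotype_table(pheno, OUT / "phenotypes.tsv")
    e.write_cross_plan(plan, OUT / "crosses.tsv")
    with open(OUT / "truth.yaml", "w") as fh:
        yaml.safe_dump({
            "seed": SEED,
            "qts_loci": truth.qts_loci,
            "effects": {t.label(): float(v) for t, v in eff.term_map().items()},
            "residual_sd": float(eff.residual_sd),
            "h2_total": float(truth.h2_total),
        }, fh)

    n_hyb = int((g.subject_class == "f1_hybrid").sum())
    print(f"population: {g.calls.shape[0]} subjects "
          f"({g.calls.shape[0] - n_hyb} inbreds + {n_hyb} hybrids), "
          f"{g.calls.shape[1]} SNPs")
    print(f"trait PH: QTS at {l1} and {l2}, residual sd "
          f"{eff.residual_sd:.2f}, true h2_T {truth.h2_total:.3f}")
    print(f"wrote {OUT}/genotypes.tsv, phenotypes.tsv, crosses.tsv, truth.yaml")


if __name__ == "__main__":
    main()
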