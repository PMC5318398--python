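#!/usr/bin/env python
"""Predict superior genotype combinations, best realized subjects, donor
lines, and genotype-phenotype maps from the mapped QTS table.

Plant height is bred downward, so the optimization direction is minimize:
the superior line/hybrid is the genotype combination over the significant
loci with the lowest predicted genotypic value, reported as a deviation from
the per-environment population mean.  Writes the Table-3-shaped prediction
report, the donor report for the two female testers, and the 3x3 G-P map of
every epistatic pair under results/prediction/.
"""

import pathlib

import epiqts as e

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    g = e.read_genotype_table(BASE / "qc" / "genotypes.qc.tsv")
    plan = e.read_cross_plan(BASE / "sim" / "crosses.tsv")
    g = e.classify_subjects(g, plan)
    table = e.QTSTable.read(BASE / "mapping" / "qts_ph.tsv")
    direction = "minimize"  # lower plant height is the breeding goal

    out = BASE / "prediction"
    out.mkdir(parents=True, exist_ok=True)

    report = e.build_prediction_report(g, table, direction)
    report.write(out / "prediction_ph.tsv")
    for _, row in report.rows.iterrows():
        print(f"{row['environment']}: mean {row['mean']:.2f} | "
              f"QQ {row['QQ']:+.2f} qq {row['qq']:+.2f} Qq {row['Qq']:+.2f} | "
              f"best line {row['best_line']} ({row['best_line_value']:+.2f}) "
              f"superior line {row['superior_line_value']:+.2f} | "
              f"best hybrid {row['best_hybrid_value']:+.2f} "
              f"superior hybrid {row['superior_hybrid_value']:+.2f}")

    for env in sorted(table.env_means):
        combo, value = e.superior_combination(table, env, "hybrids", direction)
        named = {l: {2: "QQ", 1: "Qq", 0: "qq"}[c] for l, c in combo.items()}
        print(f"superior hybrid genotype in {env}: {named} -> {value:+.2f}")

    donors = e.donor_recommendation(g, ["F1", "F2"], table, "E1", direction)
    donors.write(out / "donors_ph.tsv")
    print(f"donor lines whose F1 with a tester attains the superior hybrid: "
          f"{donors.n_donors}")

    pairs = {t.loci for t in table.term_effects() if len(t.loci) == 2}
    for pair in sorted(pairs):
        for env in sorted(table.env_means):
            grid = e.gp_map(table, pair, env)
            path = out / f"gp_map.{pair[0]}_{pair[1]}.{env}.tsv"
            grid.to_csv(path, sep="\t")
        print(f"G-P map of {pair[0]} x {pair[1]}:")
        print(e.gp_map(table, pair, "E1").round(2).to_string())
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
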