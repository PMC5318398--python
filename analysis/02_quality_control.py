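#!/usr/bin/env python
"""Quality control of the simulated genotype panel and phenotype records.

Applies the study's filters: SNPs are dropped when call frequency < 0.9,
minor-allele frequency < 0.05, or a homozygote class is absent; phenotype
records are dropped for subjects missing > 10% of a trait's records, then
for standardized replicate-cell residuals beyond 3.  Writes the filtered
files and the QC logs under results/qc/.
"""

import pathlib

import epiqts as e

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    g = e.read_genotype_table(BASE / "sim" / "genotypes.tsv")
    p = e.read_phenotype_table(BASE / "sim" / "phenotypes.tsv")

    g2, rep_g = e.qc_filter_snps(g, call_freq_min=0.9, maf_min=0.05,
                                 require_both_homozygotes=True)
    p2, rep_p = e.filter_phenotype_outliers(p, missing_max=0.1, z_max=3.0)

    out = BASE / "qc"
    out.mkdir(parents=True, exist_ok=True)
    e.write_genotype_table(g2, out / "genotypes.qc.tsv")
    e.write_phenotype_table(p2, out / "phenotypes.qc.tsv")
    rep_g.write(out / "qc_snps.log")
    rep_p.write(out / "qc_phenotypes.log")

    print(f"SNPs: kept {g2.calls.shape[1]} of {g.calls.shape[1]} "
          f"({len(rep_g.removed_loci)} removed: "
          f"{dict((r, sum(1 for _, x in rep_g.removed_loci if x == r)) for _, r in rep_g.removed_loci)})")
    print(f"phenotype records: kept {len(p2.records)} of {len(p.records)} "
          f"({len(rep_p.removed_records)} removals)")
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
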