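"""Domain types, delimited-text I/O, quality control, and F1 genotype derivation.

Genotype calls are held as an ``int8`` pandas DataFrame (subjects x loci) with
codes ``2 = QQ`` (major homozygote), ``1 = Qq``, ``0 = qq`` (minor homozygote)
and ``-1 = missing``.  "Major" is always the more frequent allele among the
non-missing calls of the cohort the matrix was built from (ties broken
alphabetically by allele letter), so per-locus minor-allele frequency is in
[0, 0.5] by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

QQ, QH, qq, MISSING = 2, 1, 0, -1

CODE_TO_NAME = {2: "QQ", 1: "Qq", 0: "qq", -1: "missing"}


class ParseError(ValueError):
    """Malformed input file (unknown token, bad header, ...)."""


class IntegrityError(ValueError):
    """Input violates a structural invariant (duplicate ids, unknown parents, ...)."""


class GenotypeError(ValueError):
    """A genotype call violates a biological contract (e.g. heterozygous inbred)."""


@dataclass(frozen=True)
class SNPLocus:
    """A biallelic SNP locus; ``id`` follows the ``<chrom>_M<index>`` convention."""

    id: str
    chromosome: str = ""
    major_allele: str = "Q"
    minor_allele: str = "q"

    def __post_init__(self):
        if self.major_allele == self.minor_allele:
            raise IntegrityError(
                f"locus {self.id}: major and minor allele must differ"
            )


@dataclass(frozen=True)
class GenotypeDialect:
    """Token mapping of a delimited genotype table."""

    tokens: dict = None  # token -> code
    missing: str = "NA"
    sep: str = "\t"

    def __post_init__(self):
        if self.tokens is None:
            object.__setattr__(self, "tokens", {"2": QQ, "1": QH, "0": qq})


NUMERIC_DIALECT = GenotypeDialect()
NAME_DIALECT = GenotypeDialect(tokens={"QQ": QQ, "Qq": QH, "qq": qq}, missing="NA")


@dataclass
class GenotypeMatrix:
    """Subjects x loci genotype calls plus locus metadata and subject class labels.

    ``subject_class`` maps each subject id to ``"inbred_line"`` or ``"f1_hybrid"``.
    """

    calls: pd.DataFrame  # int8, index = subject ids, columns = locus ids
    loci: list = field(default_factory=list)  # list[SNPLocus], aligned to columns
    subject_class: pd.Series = None  # str per subject

    def __post_init__(self):
        if self.subject_class is None:
            self.subject_class = pd.Series(
                "inbred_line", index=self.calls.index, dtype=object
            )
        if not self.loci:
            self.loci = [SNPLocus(id=c) for c in self.calls.columns]
        if len(self.loci) != self.calls.shape[1]:
            raise IntegrityError("loci metadata does not match call columns")
        if self.calls.index.has_duplicates:
            dup = self.calls.index[self.calls.index.duplicated()][0]
            raise IntegrityError(f"duplicate subject id {dup!r}")
        if self.calls.columns.has_duplicates:
            dup = self.calls.columns[self.calls.columns.duplicated()][0]
            raise IntegrityError(f"duplicate locus id {dup!r}")

    @property
    def subjects(self) -> list:
        return list(self.calls.index)

    @property
    def locus_ids(self) -> list:
        return list(self.calls.columns)

    def locus(self, locus_id: str) -> SNPLocus:
        return self.loci[self.calls.columns.get_loc(locus_id)]

    def subset_subjects(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            calls=self.calls.loc[list(ids)].copy(),
            loci=list(self.loci),
            subject_class=self.subject_class.loc[list(ids)].copy(),
        )

    def subset_loci(self, locus_ids) -> "GenotypeMatrix":
        locus_ids = list(locus_ids)
        idx = [self.calls.columns.get_loc(l) for l in locus_ids]
        return GenotypeMatrix(
            calls=self.calls[locus_ids].copy(),
            loci=[self.loci[i] for i in idx],
            subject_class=self.subject_class.copy(),
        )

    def call_frequency(self) -> pd.Series:
        """Fraction of non-missing calls per locus."""
        return (self.calls.to_numpy() != MISSING).mean(axis=0) + pd.Series(
            0.0, index=self.calls.columns
        )

    def minor_allele_frequency(self) -> pd.Series:
        """Minor-allele frequency per locus over non-missing calls (in [0, 0.5])."""
        c = self.calls.to_numpy()
        ok = c != MISSING
        n = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            # allele count of the 'Q' (coded-major) allele
            q_count = np.where(ok, c, 0).sum(axis=0).astype(float)
            freq_q = q_count / (2.0 * n)
        maf = np.minimum(freq_q, 1.0 - freq_q)
        maf[n == 0] = np.nan
        return pd.Series(maf, index=self.calls.columns)

    def validate_inbreds(self) -> None:
        """Inbred lines must carry no heterozygous call."""
        inbred = self.subject_class[self.subject_class == "inbred_line"].index
        sub = self.calls.loc[inbred]
        het = sub.to_numpy() == QH
        if het.any():
            i, j = np.argwhere(het)[0]
            raise GenotypeError(
                f"inbred line {sub.index[i]!r} is heterozygous at locus "
                f"{sub.columns[j]!r}"
            )


@dataclass
class CrossPlan:
    """Female x male crosses producing named F1 hybrids."""

    crosses: list  # list[(female_id, male_id, hybrid_id)]

    def __post_init__(self):
        hybrids = [h for _, _, h in self.crosses]
        if len(set(hybrids)) != len(hybrids):
            raise IntegrityError("hybrid ids in cross plan are not unique")

    def validate_parents(self, g: GenotypeMatrix) -> None:
        inbred = set(g.subject_class[g.subject_class == "inbred_line"].index)
        for female, male, hybrid in self.crosses:
            for parent in (female, male):
                if parent not in inbred:
                    raise IntegrityError(
                        f"cross parent {parent!r} (hybrid {hybrid!r}) is not an "
                        "inbred line in the genotype matrix"
                    )


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: subject, environment, replicate, trait, value."""

    records: pd.DataFrame

    COLUMNS = ("subject", "environment", "replicate", "trait", "value")

    def __post_init__(self):
        missing_cols = set(self.COLUMNS) - set(self.records.columns)
        if missing_cols:
            raise IntegrityError(f"phenotype table lacks columns {sorted(missing_cols)}")
        key = ["subject", "environment", "replicate", "trait"]
        if self.records.duplicated(subset=key).any():
            bad = self.records[self.records.duplicated(subset=key)].iloc[0]
            raise IntegrityError(
                "duplicate phenotype record for "
                f"{tuple(bad[k] for k in key)}"
            )

    @property
    def environments(self) -> list:
        return sorted(self.records["environment"].unique())

    @property
    def traits(self) -> list:
        return sorted(self.records["trait"].unique())

    def trait_records(self, trait: str) -> pd.DataFrame:
        return self.records[self.records["trait"] == trait]

    def cell_means(self, trait: str) -> pd.DataFrame:
        """Replicate means per (subject, environment) for one trait."""
        sub = self.trait_records(trait)
        return (
            sub.groupby(["subject", "environment"], sort=True)["value"]
            .mean()
            .reset_index()
        )


@dataclass
class QCReport:
    """What quality control removed and why; one reason code per removed item."""

    removed_loci: list = field(default_factory=list)  # (locus_id, reason)
    removed_records: list = field(default_factory=list)  # (record_key, reason)
    thresholds: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("locus", str(k), r) for k, r in self.removed_loci]
        rows += [("record", str(k), r) for k, r in self.removed_records]
        return pd.DataFrame(rows, columns=["kind", "key", "reason"])

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in sorted(self.thresholds.items()):
                fh.write(f"# threshold {k}={v}\n")
            for note in self.notes:
                fh.write(f"# note {note}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O


def _parse_locus_header(token: str) -> SNPLocus:
    """Parse a header token like ``C09_M34850`` or ``C09_M34850_G/A``."""
    parts = token.split("_")
    alleles = ("Q", "q")
    lid = token
    if len(parts) >= 2 and "/" in parts[-1]:
        a = parts[-1].split("/")
        if len(a) == 2 and all(len(x) == 1 for x in a):
            alleles = (a[0], a[1])
            lid = "_".join(parts[:-1])
    chrom = lid.split("_")[0] if "_" in lid else ""
    return SNPLocus(id=lid, chromosome=chrom, major_allele=alleles[0],
                    minor_allele=alleles[1])


def read_genotype_table(path, dialect: GenotypeDialect = NUMERIC_DIALECT,
                        subject_class: str = "inbred_line") -> GenotypeMatrix:
    """Read a delimited genotype table (rows = subjects, columns = loci).

    The major allele per locus is recomputed as the more frequent allele among
    non-missing calls (ties broken alphabetically); where the file's coding
    disagrees, calls are flipped (QQ <-> qq) and allele labels swapped so that
    code 2 is always the major homozygote.
    """
    df = pd.read_csv(path, sep=dialect.sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise IntegrityError(f"duplicate subject id {dup!r} in {path}")
    loci = [_parse_locus_header(c) for c in df.columns]
    codes = np.full(df.shape, MISSING, dtype=np.int8)
    values = df.to_numpy()
    token_map = dict(dialect.tokens)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            tok = values[i, j]
            if tok is None or (isinstance(tok, float) and np.isnan(tok)):
                continue
            tok = str(tok).strip()
            if tok == dialect.missing or tok == "":
                continue
            try:
                codes[i, j] = token_map[tok]
            except KeyError:
                raise ParseError(
                    f"unknown genotype token {tok!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                ) from None
    calls = pd.DataFrame(codes, index=df.index.rename(None),
                         columns=[l.id for l in loci], dtype=np.int8)
    g = GenotypeMatrix(calls=calls, loci=loci,
                       subject_class=pd.Series(subject_class, index=df.index,
                                               dtype=object))
    _repolarize_to_major(g)
    return g


def _repolarize_to_major(g: GenotypeMatrix) -> None:
    """Flip codes so code 2 is the cohort-major homozygote at every locus."""
    c = g.calls.to_numpy()
    ok = c != MISSING
    n = ok.sum(axis=0).astype(float)
    q_count = np.where(ok, c, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        freq_q = np.where(n > 0, q_count / (2 * n), 0.5)
    for j, locus in enumerate(g.loci):
        flip = freq_q[j] < 0.5
        if freq_q[j] == 0.5:
            # tie: alphabetically first allele is major
            flip = locus.minor_allele < locus.major_allele
        if flip:
            col = c[:, j]
            swapped = np.where(col == QQ, qq, np.where(col == qq, QQ, col))
            g.calls.iloc[:, j] = swapped.astype(np.int8)
            g.loci[j] = SNPLocus(id=locus.id, chromosome=locus.chromosome,
                                 major_allele=locus.minor_allele,
                                 minor_allele=locus.major_allele)


def write_genotype_table(g: GenotypeMatrix, path,
                         dialect: GenotypeDialect = NUMERIC_DIALECT) -> None:
    inv = {v: k for k, v in dialect.tokens.items()}
    inv[MISSING] = dialect.missing
    out = g.calls.replace(inv)
    out.columns = [
        l.id if (l.major_allele, l.minor_allele) == ("Q", "q")
        else f"{l.id}_{l.major_allele}/{l.minor_allele}"
        for l in g.loci
    ]
    out.to_csv(path, sep=dialect.sep, index_label="subject")


def read_phenotype_table(path, sep: str = "\t") -> PhenotypeTable:
    df = pd.read_csv(path, sep=sep, dtype={"subject": str, "environment": str,
                                           "trait": str})
    return PhenotypeTable(records=df)


def write_phenotype_table(p: PhenotypeTable, path, sep: str = "\t") -> None:
    p.records.to_csv(path, sep=sep, index=False)


def read_cross_plan(path, sep: str = "\t") -> CrossPlan:
    df = pd.read_csv(path, sep=sep, dtype=str)
    need = {"female", "male", "hybrid"}
    if not need <= set(df.columns):
        raise ParseError(f"cross plan lacks columns {sorted(need - set(df.columns))}")
    return CrossPlan(crosses=list(df[["female", "male", "hybrid"]].itertuples(
        index=False, name=None)))


def write_cross_plan(plan: CrossPlan, path, sep: str = "\t") -> None:
    pd.DataFrame(plan.crosses, columns=["female", "male", "hybrid"]).to_csv(
        path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Quality control


def qc_filter_snps(g: GenotypeMatrix, call_freq_min: float = 0.9,
                   maf_min: float = 0.05,
                   require_both_homozygotes: bool = True
                   ) -> tuple[GenotypeMatrix, QCReport]:
    """Drop loci by call frequency, minor-allele frequency and homozygote presence.

    Each removed locus carries the first failing rule, checked in the order
    ``call_freq``, ``maf``, ``missing_homozygote``.
    """
    report = QCReport(thresholds={"call_freq_min": call_freq_min,
                                  "maf_min": maf_min,
                                  "require_both_homozygotes":
                                      require_both_homozygotes})
    cf = g.call_frequency()
    maf = g.minor_allele_frequency()
    c = g.calls.to_numpy()
    has_qq_major = (c == QQ).any(axis=0)
    has_qq_minor = (c == qq).any(axis=0)
    keep = []
    for j, lid in enumerate(g.calls.columns):
        if cf.iloc[j] < call_freq_min:
            report.removed_loci.append((lid, "call_freq"))
        elif not np.isfinite(maf.iloc[j]) or maf.iloc[j] < maf_min:
            report.removed_loci.append((lid, "maf"))
        elif require_both_homozygotes and not (has_qq_major[j] and has_qq_minor[j]):
            report.removed_loci.append((lid, "missing_homozygote"))
        else:
            keep.append(lid)
    if not keep:
        report.notes.append("degenerate: no locus passed QC")
        empty = GenotypeMatrix(
            calls=g.calls.iloc[:, :0].copy(), loci=[],
            subject_class=g.subject_class.copy())
        return empty, report
    return g.subset_loci(keep), report


def filter_phenotype_outliers(p: PhenotypeTable, missing_max: float = 0.1,
                              z_max: float = 3.0
                              ) -> tuple[PhenotypeTable, QCReport]:
    """Per-trait missingness screen then standardized-residual outlier screen.

    Residual of a record = value minus the mean of its (subject, environment,
    trait) cell over replicates; residuals are standardized per trait.  A trait
    whose residual spread is zero is left untouched (guard, logged).
    """
    if z_max <= 0:
        raise ValueError("z_max must be positive")
    report = QCReport(thresholds={"missing_max": missing_max, "z_max": z_max})
    report.notes.append(
        "residual = record - (subject, environment, trait) replicate-cell mean")
    df = p.records.copy()
    keep = np.ones(len(df), dtype=bool)

    for trait, sub in df.groupby("trait", sort=True):
        n_expected = (sub["environment"].nunique() * sub["replicate"].nunique())
        observed = sub[sub["value"].notna()].groupby("subject").size()
        frac_missing = 1.0 - observed.reindex(
            sub["subject"].unique(), fill_value=0) / max(n_expected, 1)
        drop_subjects = set(frac_missing[frac_missing > missing_max].index)
        for s in sorted(drop_subjects):
            report.removed_records.append(((s, trait), "missingness"))
        mask_missing = sub["subject"].isin(drop_subjects)
        keep[sub.index[mask_missing]] = False

        live = sub[~mask_missing & sub["value"].notna()]
        if live.empty:
            continue
        cell_mean = live.groupby(["subject", "environment"])["value"].transform("mean")
        resid = live["value"] - cell_mean
        mu, sigma = resid.mean(), resid.std(ddof=1)
        if not np.isfinite(sigma) or sigma == 0:
            report.notes.append(f"trait {trait}: zero residual spread, outlier "
                                "screen skipped")
            continue
        z = (resid - mu).abs() / sigma
        for idx in live.index[z > z_max]:
            row = df.loc[idx]
            report.removed_records.append(
                ((row["subject"], row["environment"], row["replicate"], trait),
                 "outlier"))
            keep[idx] = False

    filtered = PhenotypeTable(records=df[keep].reset_index(drop=True))
    return filtered, report


# ---------------------------------------------------------------------------
# F1 derivation


def derive_f1_genotypes(parents: GenotypeMatrix, plan: CrossPlan
                        ) -> GenotypeMatrix:
    """Derive F1 hybrid genotypes from homozygous inbred parents.

    QQ x QQ -> QQ; qq x qq -> qq; differing homozygotes -> Qq; a missing call
    in either parent propagates as missing.  A heterozygous parent call is a
    contract violation and raises ``GenotypeError``.
    """
    plan.validate_parents(parents)
    calls = parents.calls
    cols = calls.columns
    rows = {}
    for female, male, hybrid in plan.crosses:
        pf = calls.loc[female].to_numpy()
        pm = calls.loc[male].to_numpy()
        for pid, pc in ((female, pf), (male, pm)):
            het = np.nonzero(pc == QH)[0]
            if het.size:
                raise GenotypeError(
                    f"parent {pid!r} is heterozygous at locus "
                    f"{cols[het[0]]!r}; inbred parents must be homozygous")
        f1 = np.where((pf == MISSING) | (pm == MISSING), MISSING,
                      np.where(pf == pm, pf, QH)).astype(np.int8)
        rows[hybrid] = f1
    hyb = pd.DataFrame.from_dict(rows, orient="index", columns=cols).astype(np.int8)
    return GenotypeMatrix(
        calls=hyb, loci=list(parents.loci),
        subject_class=pd.Series("f1_hybrid", index=hyb.index, dtype=object))


def classify_subjects(g: GenotypeMatrix, plan: CrossPlan) -> GenotypeMatrix:
    """Label subjects as hybrids or inbreds from a cross plan.

    The genotype table format does not carry subject classes; after reading
    one back, subjects named as hybrid ids in the plan become ``f1_hybrid``
    and everything else ``inbred_line``.
    """
    hybrids = {h for _, _, h in plan.crosses}
    cls = pd.Series(["f1_hybrid" if s in hybrids else "inbred_line"
                     for s in g.calls.index], index=g.calls.index,
                    dtype=object)
    return GenotypeMatrix(calls=g.calls.copy(), loci=list(g.loci),
                          subject_class=cls)


def concat_genotypes(*matrices: GenotypeMatrix) -> GenotypeMatrix:
    """Stack genotype matrices sharing the same loci (e.g. parents + hybrids)."""
    first = matrices[0]
    for m in matrices[1:]:
        if list(m.calls.columns) != list(first.calls.columns):
            raise IntegrityError("cannot concatenate matrices with different loci")
    return GenotypeMatrix(
        calls=pd.concat([m.calls for m in matrices]),
        loci=list(first.loci),
        subject_class=pd.concat([m.subject_class for m in matrices]))
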