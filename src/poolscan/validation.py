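"""Pool-vs-genotype allele-frequency concordance checks.

Individual genotypes (RR/RS/SS at a focal locus, e.g. a kdr mutation in the
sodium channel) give a direct allele-frequency estimate for the mosquitoes
in each pool; comparing those against the pooled read counts tests whether
library sequencing estimated the population frequencies accurately.  Each
comparison reports a Fisher exact p and a Pearson heterogeneity chi-square p
on the 2 x 2 (resistant allele vs other) count table; the two estimates are
called concordant when both are above the threshold (default 0.05).

Library-side counts enter the table as raw read counts, not rescaled to
pool chromosomes; read depth can exceed the 2 x 25 chromosomes actually
pooled, which inflates the power of the comparison (documented caveat).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .association import pearson_chi2
from .enrichment import fisher_exact_2x2

GENOTYPES = ("RR", "RS", "SS")


@dataclass(slots=True)
class GenotypeTable:
    """Individual genotypes at one locus, with library membership."""

    locus: str
    individuals: pd.DataFrame  # columns: individual, library, genotype

    def __post_init__(self) -> None:
        required = {"individual", "library", "genotype"}
        if not required.issubset(self.individuals.columns):
            raise ValueError(f"genotype table needs columns {sorted(required)}")
        bad = set(self.individuals.genotype) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype codes: {sorted(bad)}")
        if self.individuals.individual.duplicated().any():
            raise ValueError("each individual must be assigned to exactly one library")


def read_genotype_table(path, locus: str = "locus") -> GenotypeTable:
    df = pd.read_csv(path, sep="\t")
    return GenotypeTable(locus, df)


def genotype_allele_counts(
    table: GenotypeTable, library: Optional[str] = None
) -> tuple[int, int, float]:
    """(resistant allele count, total alleles, frequency) for one library
    (or all individuals when ``library`` is None).

    Each individual contributes two alleles: count = 2*RR + RS.
    """
    df = table.individuals
    if library is not None:
        df = df[df.library == library]
    n = len(df)
    if n == 0:
        raise ValueError(f"no individuals for library {library!r}")
    rr = int((df.genotype == "RR").sum())
    rs = int((df.genotype == "RS").sum())
    count = 2 * rr + rs
    total = 2 * n
    return count, total, count / total


@dataclass(slots=True)
class ConcordanceResult:
    fisher_p: float
    chi2_p: float
    concordant: bool


def frequency_concordance(
    counts_a: tuple[int, int],
    counts_b: tuple[int, int],
    threshold: float = 0.05,
) -> ConcordanceResult:
    """Compare two (resistant allele count, total) estimates.

    Symmetric in its arguments.  Raises on a zero total in either source.
    """
    (ka, na), (kb, nb) = counts_a, counts_b
    if na <= 0 or nb <= 0:
        raise ValueError("both sources need a positive allele total")
    if not (0 <= ka <= na and 0 <= kb <= nb):
        raise ValueError("count exceeds total")
    fisher_p = fisher_exact_2x2(ka, na - ka, kb, nb - kb)
    _, _, chi2_p = pearson_chi2([[ka, na - ka], [kb, nb - kb]])
    return ConcordanceResult(
        fisher_p, chi2_p, fisher_p >= threshold and chi2_p >= threshold
    )


def concordance_report(
    genotype: GenotypeTable,
    library_read_counts: dict[str, tuple[int, int]],
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Pairwise concordance rows: replicate-vs-replicate within each
    technique and genotyping-vs-reads within each library."""
    libs = sorted(library_read_counts)
    geno = {l: genotype_allele_counts(genotype, l)[:2] for l in libs}
    rows = []

    def add(kind, a_name, a, b_name, b):
        r = frequency_concordance(a, b, threshold)
        rows.append(
            {
                "comparison": kind,
                "a": a_name,
                "b": b_name,
                "freq_a": a[0] / a[1],
                "freq_b": b[0] / b[1],
                "fisher_p": r.fisher_p,
                "chi2_p": r.chi2_p,
                "concordant": r.concordant,
            }
        )

    for i, la in enumerate(libs):
        add("genotype_vs_reads", f"geno:{la}", geno[la], f"reads:{la}", library_read_counts[la])
        for lb in libs[i + 1 :]:
            add("reads_vs_reads", f"reads:{la}", library_read_counts[la], f"reads:{lb}", library_read_counts[lb])
            add("genotype_vs_genotype", f"geno:{la}", geno[la], f"geno:{lb}", geno[lb])
    return pd.DataFrame(rows)
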