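"""SNP functional annotation: feature class, coding effect, aggregation.

Coding effects use the standard genetic code on the canonical transcript's
CDS; residue numbering is local to that CDS (cross-species numbering
conventions are a reporting concern outside this module's scope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .association import AssociationRecord
from .genes import CDS, INTERGENIC, GeneIndex, GeneModel
from .models import SiteKey

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NOT_APPLICABLE = "not_applicable"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(slots=True)
class SnpAnnotation:
    key: SiteKey
    gene_id: str  # gene id or "intergenic"
    feature_class: str
    substitution_type: str = NOT_APPLICABLE
    residue_number: Optional[int] = None
    codon_position: Optional[int] = None
    label: Optional[str] = None
    alt_base: Optional[str] = None
    secondary_alts: tuple[str, ...] = ()


def classify_site(key: SiteKey, index: GeneIndex) -> list[tuple[Optional[str], str]]:
    """(gene id, feature class) for every gene containing the position.

    Outside all genes the single pair ``(None, "intergenic")`` is returned.
    Overlapping loci produce one entry per gene, with a warning.
    """
    hits = index.overlapping(key.chrom, key.pos)
    out = []
    for g in hits:
        feat = g.feature_at(key.pos)
        if feat is not None:
            out.append((g.gene_id, feat))
    if not out:
        return [(None, INTERGENIC)]
    if len(out) > 1:
        warnings.warn(
            f"site {key.chrom}:{key.pos} lies in {len(out)} overlapping genes; "
            "emitting one annotation per gene"
        )
    return out


def substitution_effect(
    cds_sequence: str,
    cds_offset: int,
    ref_base: str,
    alt_base: str,
    strand: str = "+",
) -> SnpAnnotation:
    """Coding effect of a single-base substitution.

    ``cds_sequence`` is the spliced coding sequence 5'->3'; ``cds_offset`` is
    the 0-based position of the site within it.  ``ref_base``/``alt_base``
    are given on the genomic plus strand and are complemented for minus-
    strand genes before comparison with the CDS.
    """
    if not (0 <= cds_offset < len(cds_sequence)):
        raise ValueError(f"cds_offset {cds_offset} outside CDS of length {len(cds_sequence)}")
    cds = cds_sequence.upper()
    if strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    if cds[cds_offset] != ref_base:
        raise ValueError(
            f"reference base mismatch at CDS offset {cds_offset}: "
            f"CDS has {cds[cds_offset]}, expected {ref_base}"
        )
    codon_index = cds_offset // 3
    codon_position = cds_offset % 3 + 1
    residue_number = codon_index + 1
    codon = cds[codon_index * 3 : codon_index * 3 + 3]
    key = SiteKey("cds", cds_offset + 1, "A")  # placeholder key for the bare op
    if len(codon) < 3:
        warnings.warn("partial terminal codon; substitution effect not applicable")
        return SnpAnnotation(key, "cds", CDS, NOT_APPLICABLE, None, None, None, alt_base)
    mutated = codon[: codon_position - 1] + alt_base + codon[codon_position:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    subst = SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS
    label = f"{aa_ref}{residue_number}{aa_alt}" if subst == NONSYNONYMOUS else f"{aa_ref}{residue_number}"
    return SnpAnnotation(
        key,
        "cds",
        CDS,
        subst,
        residue_number,
        codon_position,
        label,
        alt_base,
    )


def annotate_sites(
    records: Sequence[AssociationRecord],
    genes: Sequence[GeneModel] | GeneIndex,
    fasta=None,
) -> list[SnpAnnotation]:
    """Classify each associated SNP and, for CDS SNPs, compute the coding
    effect of the most frequent alternate allele.

    ``fasta`` is a pyfaidx.Fasta (or any mapping of chrom -> sequence
    supporting slicing); without it CDS SNPs keep ``not_applicable`` effects.
    Multi-allelic sites list the remaining alternates in ``secondary_alts``.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    gene_by_id = {g.gene_id: g for g in index.genes()}
    cds_cache: dict[str, str] = {}

    def cds_seq(gene: GeneModel) -> Optional[str]:
        if fasta is None or not gene.cds_ok:
            return None
        if gene.gene_id not in cds_cache:
            parts = []
            for iv in sorted(
                (iv for iv in gene.intervals if iv.kind == CDS), key=lambda iv: iv.start
            ):
                seq = str(fasta[gene.chrom][iv.start - 1 : iv.end]).upper()
                parts.append(seq)
            seq = "".join(parts)
            if gene.strand == "-":
                seq = seq.translate(_COMPLEMENT)[::-1]
            cds_cache[gene.gene_id] = seq
        return cds_cache[gene.gene_id]

    annotations = []
    for rec in records:
        pooled = (rec.resistant + rec.susceptible).as_array()
        alts = sorted(
            (b for b in "ACGT" if b != rec.key.ref and pooled["ACGT".index(b)] > 0),
            key=lambda b: -pooled["ACGT".index(b)],
        )
        alt = alts[0] if alts else None
        secondary = tuple(alts[1:])
        for gene_id, feat in classify_site(rec.key, index):
            ann = SnpAnnotation(
                rec.key,
                gene_id if gene_id is not None else INTERGENIC,
                feat,
                alt_base=alt,
                secondary_alts=secondary,
            )
            if feat == CDS and gene_id is not None and alt is not None:
                gene = gene_by_id[gene_id]
                seq = cds_seq(gene)
                if seq is not None:
                    offset = gene.genomic_to_cds_offset(rec.key.pos)
                    eff = substitution_effect(seq, offset, rec.key.ref, alt, gene.strand)
                    ann.substitution_type = eff.substitution_type
                    ann.residue_number = eff.residue_number
                    ann.codon_position = eff.codon_position
                    ann.label = eff.label
            annotations.append(ann)
    return annotations


def aggregate(
    annotations: Sequence[SnpAnnotation],
    records: Sequence[AssociationRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene and per-category summaries of annotated SNPs.

    Per gene: SNP count, max -log10(p), nonsynonymous count.  Per category
    (the tag set of the containing gene): SNP count and percentage share of
    all gene-assigned SNPs.
    """
    score = {(r.key.chrom, r.key.pos): r.neg_log10_p for r in records}
    rows = []
    for ann in annotations:
        rows.append(
            {
                "gene": ann.gene_id,
                "chromosome": ann.key.chrom,
                "neg_log10_p": score.get((ann.key.chrom, ann.key.pos), float("nan")),
                "nonsynonymous": ann.substitution_type == NONSYNONYMOUS,
            }
        )
    if not rows:
        empty_gene = pd.DataFrame(
            columns=["gene", "chromosome", "n_snps", "max_neg_log10_p", "n_nonsynonymous"]
        )
        empty_cat = pd.DataFrame(columns=["n_snps", "share_pct"])
        return empty_gene, empty_cat
    df = pd.DataFrame(rows)
    per_gene = (
        df[df.gene != INTERGENIC]
        .groupby(["gene", "chromosome"])
        .agg(
            n_snps=("neg_log10_p", "size"),
            max_neg_log10_p=("neg_log10_p", "max"),
            n_nonsynonymous=("nonsynonymous", "sum"),
        )
        .reset_index()
    )
    return per_gene, _category_shares(annotations)


def category_of(annotations: Sequence[SnpAnnotation], genes: Sequence[GeneModel]):
    tags = {g.gene_id: sorted(g.categories)[0] for g in genes}
    return [tags.get(a.gene_id, "other") for a in annotations]


def _category_shares(annotations: Sequence[SnpAnnotation]) -> pd.DataFrame:
    counts = (
        pd.Series([a.feature_class for a in annotations]).value_counts().rename("n_snps")
    )
    df = counts.to_frame()
    df["share_pct"] = 100 * df.n_snps / max(len(annotations), 1)
    return df


def category_share_table(
    annotations: Sequence[SnpAnnotation], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """SNP count and percentage share per gene-category tag (detox families
    etc.), over SNPs that fall inside tagged genes."""
    tags = {g.gene_id: sorted(g.categories)[0] for g in genes}
    cat = [tags[a.gene_id] for a in annotations if a.gene_id in tags]
    if not cat:
        return pd.DataFrame(columns=["n_snps", "share_pct"])
    counts = pd.Series(cat).value_counts().rename("n_snps").to_frame()
    counts["share_pct"] = 100 * counts.n_snps / counts.n_snps.sum()
    return counts
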