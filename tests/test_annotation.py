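"""Feature classification and codon-level substitution effects."""

import itertools

import pytest

from poolscan.annotation import (
    NONSYNONYMOUS,
    NOT_APPLICABLE,
    SYNONYMOUS,
    classify_site,
    substitution_effect,
)
from poolscan.genes import (
    CDS,
    FIVE_PRIME_UTR,
    INTERGENIC,
    GeneIndex,
    GeneModel,
    Interval,
)
from poolscan.models import SiteKey

# independent genetic-code oracle: the classic 64-codon table over TCAG
_ORACLE_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_TCAG = "TCAG"
ORACLE_CODE = {
    a + b + c: _ORACLE_AA[16 * i + 4 * j + k]
    for i, a in enumerate(_TCAG)
    for j, b in enumerate(_TCAG)
    for k, c in enumerate(_TCAG)
}


@pytest.fixture
def toy_gene_index():
    gene = GeneModel(
        "geneA",
        "chr1",
        "+",
        [
            Interval(1001, 1100, FIVE_PRIME_UTR),
            Interval(1101, 1900, CDS),
            Interval(1901, 2000, "three_prime_utr"),
        ],
    )
    return GeneIndex([gene])


class TestClassifySite:
    @pytest.mark.parametrize(
        "pos,expected",
        [(1050, FIVE_PRIME_UTR), (1500, CDS), (500, INTERGENIC), (2500, INTERGENIC)],
    )
    def test_feature_assignment(self, toy_gene_index, pos, expected):
        [(gene, feat)] = classify_site(SiteKey("chr1", pos, "A"), toy_gene_index)
        assert feat == expected
        assert (gene is None) == (expected == INTERGENIC)

    def test_overlapping_genes_get_one_annotation_each(self):
        g1 = GeneModel("g1", "chr1", "+", [Interval(100, 500, CDS), Interval(501, 501, "three_prime_utr")])
        g2 = GeneModel("g2", "chr1", "-", [Interval(300, 700, CDS)])
        index = GeneIndex([g1, g2])
        with pytest.warns(UserWarning, match="overlapping"):
            hits = classify_site(SiteKey("chr1", 400, "A"), index)
        assert {g for g, _ in hits} == {"g1", "g2"}


class TestSubstitutionEffect:
    def test_valine_to_leucine_nonsynonymous(self):
        ann = substitution_effect("GTA", 0, "G", "T")
        assert ann.substitution_type == NONSYNONYMOUS
        assert ann.label == "V1L"
        assert ann.codon_position == 1 and ann.residue_number == 1

    def test_lysine_synonymous_at_wobble(self):
        ann = substitution_effect("AAA", 2, "A", "G")
        assert ann.substitution_type == SYNONYMOUS
        assert ann.residue_number == 1 and ann.codon_position == 3

    def test_reference_mismatch_names_position(self):
        with pytest.raises(ValueError, match="offset 1"):
            substitution_effect("GTA", 1, "A", "C")

    def test_partial_terminal_codon_not_applicable(self):
        with pytest.warns(UserWarning, match="partial"):
            ann = substitution_effect("GTAAC", 4, "C", "T")
        assert ann.substitution_type == NOT_APPLICABLE

    def test_minus_strand_equals_reverse_complement_classification(self):
        """Genomic plus-strand bases are complemented for minus-strand CDS:
        the effect must match classifying the substitution directly on the
        coding sequence."""
        cds = "ATGGCTTTAGGG"
        # plus-strand genomic ref 'T' complements to CDS 'A' at offset 0,
        # alt 'G' complements to 'C'
        ann_minus = substitution_effect(cds, 0, "T", "G", strand="-")
        ann_direct = substitution_effect(cds, 0, "A", "C", strand="+")
        assert ann_minus.substitution_type == ann_direct.substitution_type
        assert ann_minus.label == ann_direct.label

    def test_exhaustive_codon_scan_matches_oracle(self):
        """Every single-base mutation of every codon in a 30-codon CDS,
        classified identically to a translate-and-compare oracle."""
        import numpy as np

        rng = np.random.default_rng(1)
        bases = "ACGT"
        codons = ["".join(rng.choice(list(bases), 3)) for _ in range(30)]
        cds = "".join(codons)
        checked = 0
        for offset in range(len(cds)):
            ref = cds[offset]
            codon_i = offset // 3
            within = offset % 3
            for alt in bases:
                if alt == ref:
                    continue
                ann = substitution_effect(cds, offset, ref, alt)
                codon = codons[codon_i]
                mutated = codon[:within] + alt + codon[within + 1 :]
                expected = (
                    SYNONYMOUS
                    if ORACLE_CODE[codon] == ORACLE_CODE[mutated]
                    else NONSYNONYMOUS
                )
                assert ann.substitution_type == expected, (codon, mutated)
                assert ann.residue_number == codon_i + 1
                assert ann.codon_position == within + 1
                checked += 1
        assert checked == 270


class TestAggregation:
    def test_per_gene_max_and_count(self):
        from poolscan.annotation import SnpAnnotation, aggregate
        from poolscan.association import AssociationRecord
        from poolscan.models import NucleotideCounts

        recs = []
        anns = []
        for pos, score in [(10, 2.0), (20, 5.0), (30, 11.0)]:
            key = SiteKey("1", pos, "A")
            recs.append(
                AssociationRecord(
                    key,
                    NucleotideCounts(a=5, c=5),
                    NucleotideCounts(a=5, c=5),
                    0.0,
                    1,
                    1.0,
                    score,
                )
            )
            anns.append(SnpAnnotation(key, "geneX", CDS))
        per_gene, _ = aggregate(anns, recs)
        row = per_gene.iloc[0]
        assert row.gene == "geneX" and row.n_snps == 3
        assert row.max_neg_log10_p == pytest.approx(11.0)

    def test_empty_annotations_give_empty_summaries(self):
        from poolscan.annotation import aggregate

        per_gene, per_cat = aggregate([], [])
        assert per_gene.empty and per_cat.empty
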