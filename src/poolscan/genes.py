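"""Gene models: stranded feature intervals plus functional category tags.

Genes are read from GFF3 (via gffutils) against one canonical transcript per
gene (the transcript with the longest total CDS).  Introns are derived as the
gaps between consecutive exons of that transcript.  A separate two-column
table (gene id <TAB> tag) assigns functional categories; genes absent from
the table are tagged ``other``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Optional

import gffutils

FIVE_PRIME_UTR = "five_prime_utr"
THREE_PRIME_UTR = "three_prime_utr"
CDS = "cds"
INTRON = "intron"
NCRNA = "ncrna"
INTERGENIC = "intergenic"

FEATURE_CLASSES = (FIVE_PRIME_UTR, THREE_PRIME_UTR, CDS, INTRON, NCRNA, INTERGENIC)

#: allowed category tags; CYP/CCE/GST/Redox together form the detox group
ALLOWED_TAGS = ("CYP", "CCE", "GST", "Redox", "neuro", "cuticle", "other")
DETOX_TAGS = frozenset({"CYP", "CCE", "GST", "Redox"})


@dataclass(slots=True)
class Interval:
    """1-based inclusive typed interval."""

    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.kind not in (FIVE_PRIME_UTR, THREE_PRIME_UTR, CDS, INTRON, NCRNA):
            raise ValueError(f"unknown interval kind {self.kind!r}")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(slots=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    intervals: list[Interval]
    categories: frozenset[str] = frozenset({"other"})
    #: False when the CDS length is not a multiple of 3; such genes are
    #: excluded from codon-effect calls but still classify features.
    cds_ok: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"gene {self.gene_id}: overlapping intervals "
                    f"{(a.start, a.end)} and {(b.start, b.end)}"
                )
        self.intervals = ivs
        cds_len = sum(len(iv) for iv in ivs if iv.kind == CDS)
        if cds_len % 3 != 0:
            self.cds_ok = False

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0].start, self.intervals[-1].end

    def feature_at(self, pos: int) -> Optional[str]:
        """Feature class at a 1-based position, or None outside the gene.
        Positions inside the gene span but in no typed interval (possible
        with partial annotations) fall back to intron."""
        lo, hi = self.span
        if not (lo <= pos <= hi):
            return None
        for iv in self.intervals:
            if pos in iv:
                return iv.kind
        return INTRON

    def cds_intervals(self) -> list[Interval]:
        """CDS intervals in transcription order (reversed for minus strand)."""
        ivs = [iv for iv in self.intervals if iv.kind == CDS]
        return ivs[::-1] if self.strand == "-" else ivs

    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.intervals if iv.kind == CDS)

    def genomic_to_cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic position within the coding sequence,
        reading in transcription order."""
        offset = 0
        for iv in self.cds_intervals():
            if pos in iv:
                within = (iv.end - pos) if self.strand == "-" else (pos - iv.start)
                return offset + within
            offset += len(iv)
        raise ValueError(f"position {pos} is not in the CDS of {self.gene_id}")

    def is_detox(self) -> bool:
        return bool(self.categories & DETOX_TAGS)


def read_category_table(path) -> dict[str, str]:
    tags: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"category table line {lineno}: expected 2 columns")
            gene_id, tag = parts
            if tag not in ALLOWED_TAGS:
                raise ValueError(
                    f"category table line {lineno}: unknown tag {tag!r}; "
                    f"allowed: {', '.join(ALLOWED_TAGS)}"
                )
            tags[gene_id] = tag
    return tags


def _canonical_transcript(db: gffutils.FeatureDB, gene) -> Optional[gffutils.Feature]:
    transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
    if not transcripts:
        return None

    def cds_len(tx) -> int:
        return sum(c.end - c.start + 1 for c in db.children(tx, featuretype="CDS"))

    return max(transcripts, key=cds_len)


def read_gene_models(gff3_path, category_table_path=None) -> list[GeneModel]:
    """Build GeneModels from GFF3 plus an optional category table.

    Raises if a CDS extends outside its gene span or a category tag is not
    in the allowed set.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    tags = read_category_table(category_table_path) if category_table_path else {}
    models = []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        intervals: list[Interval] = []
        tx = _canonical_transcript(db, gene)
        if tx is None:
            nc = list(db.children(gene, featuretype=("ncRNA", "ncRNA_gene", "rRNA", "tRNA")))
            for f in nc or [gene]:
                intervals.append(Interval(f.start, f.end, NCRNA))
        else:
            kinds = {
                "five_prime_UTR": FIVE_PRIME_UTR,
                "three_prime_UTR": THREE_PRIME_UTR,
                "CDS": CDS,
            }
            for ft, kind in kinds.items():
                for f in db.children(tx, featuretype=ft):
                    if f.start < gene.start or f.end > gene.end:
                        raise ValueError(
                            f"gene {gid}: {ft} {f.start}-{f.end} extends outside "
                            f"gene span {gene.start}-{gene.end}"
                        )
                    intervals.append(Interval(f.start, f.end, kind))
            exons = sorted(db.children(tx, featuretype="exon"), key=lambda f: f.start)
            for a, b in zip(exons, exons[1:]):
                if b.start > a.end + 1:
                    intervals.append(Interval(a.end + 1, b.start - 1, INTRON))
        category = tags.get(gid, "other")
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                intervals=intervals,
                categories=frozenset({category}),
            )
        )
    return models


class GeneIndex:
    """Per-chromosome interval lookup over gene spans (handles overlap)."""

    def __init__(self, genes: Iterable[GeneModel]) -> None:
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        for chrom, glist in self.by_chrom.items():
            glist.sort(key=lambda g: g.span[0])
            self._starts[chrom] = [g.span[0] for g in glist]

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        glist = self.by_chrom.get(chrom, [])
        if not glist:
            return []
        hi = bisect.bisect_right(self._starts[chrom], pos)
        # scan left while spans may still cover pos; gene spans are short
        # relative to chromosomes so the scan is effectively bounded
        out = []
        for g in reversed(glist[:hi]):
            if g.span[1] >= pos:
                out.append(g)
            elif pos - g.span[0] > 10_000_000:
                break
        return out[::-1]

    def genes(self) -> list[GeneModel]:
        return [g for glist in self.by_chrom.values() for g in glist]


def write_gene_models_gff3(genes: Iterable[GeneModel], path) -> None:
    """Emit a minimal GFF3 (gene/mRNA/exon/CDS/UTR rows) for round-tripping
    synthetic layouts through standard tooling."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tpoolscan\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            has_coding = any(iv.kind == CDS for iv in g.intervals)
            if not has_coding:
                for iv in g.intervals:
                    fh.write(
                        f"{g.chrom}\tpoolscan\tncRNA\t{iv.start}\t{iv.end}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.nc;Parent={g.gene_id}\n"
                    )
                continue
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tpoolscan\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            exon_kinds = (FIVE_PRIME_UTR, CDS, THREE_PRIME_UTR)
            # merge adjacent exonic intervals into exon rows
            exonic = [iv for iv in g.intervals if iv.kind in exon_kinds]
            merged: list[list[int]] = []
            for iv in exonic:
                if merged and iv.start == merged[-1][1] + 1:
                    merged[-1][1] = iv.end
                else:
                    merged.append([iv.start, iv.end])
            for i, (s, e) in enumerate(merged, start=1):
                fh.write(
                    f"{g.chrom}\tpoolscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
            type_map = {
                FIVE_PRIME_UTR: "five_prime_UTR",
                THREE_PRIME_UTR: "three_prime_UTR",
                CDS: "CDS",
            }
            for i, iv in enumerate(g.intervals, start=1):
                if iv.kind not in type_map:
                    continue
                frame = "0" if iv.kind == CDS else "."
                fh.write(
                    f"{g.chrom}\tpoolscan\t{type_map[iv.kind]}\t{iv.start}\t{iv.end}"
                    f"\t.\t{g.strand}\t{frame}\tID={tid}.{iv.kind}{i};Parent={tid}\n"
                )


def write_category_table(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for tag in sorted(g.categories):
                fh.write(f"{g.gene_id}\t{tag}\n")
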