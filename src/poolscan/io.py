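"""Readers and writers for the pipeline's text formats.

Two count-table dialects are supported:

* native TSV -- header ``chrom  pos  ref  <lib1>  <lib2> ...``; each library
  field is ``A:C:G:T`` (optionally ``A:C:G:T:depth``, validated), ``.`` for a
  missing library;
* popoolation2 sync -- no header, ``chrom  pos  ref`` then one
  ``A:T:C:G:N:del`` column per library (N and deletion counts are ignored).

Coordinates are 1-based inclusive in both count dialects and in GFF3; BED
output is 0-based half-open.  All readers accept gzip-compressed input
(detected by a ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from typing import IO, Iterable, Optional, Sequence

import pandas as pd

from .models import (
    BASES,
    LibraryMeta,
    NucleotideCounts,
    SiteKey,
    SiteRecord,
    SiteTable,
)

#: column order of the sync dialect
_SYNC_ORDER = ("A", "T", "C", "G")

RESULT_COLUMNS = [
    "chromosome",
    "position",
    "ref",
    "alt",
    "feature_class",
    "substitution_type",
    "residue",
    "codon_position",
    "freq_resistant",
    "freq_susceptible",
    "chi2",
    "df",
    "neg_log10_p",
    "fdr_pass",
]


def _open(path, mode: str = "rt") -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_count_field(field: str, lineno: int, fmt: str) -> Optional[NucleotideCounts]:
    if fmt == "tsv" and field == ".":
        return None
    parts = field.split(":")
    try:
        values = [int(v) for v in parts]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed count field {field!r}") from exc
    if fmt == "sync":
        if len(values) != 6:
            raise ValueError(
                f"line {lineno}: sync field {field!r} must have 6 values (A:T:C:G:N:del)"
            )
        a, t, c, g = values[:4]  # N and del ignored
        return NucleotideCounts(a, c, g, t)
    if len(values) == 5:
        a, c, g, t, depth = values
        if a + c + g + t != depth:
            raise ValueError(
                f"line {lineno}: depth {depth} inconsistent with counts {a}:{c}:{g}:{t}"
            )
        return NucleotideCounts(a, c, g, t)
    if len(values) != 4:
        raise ValueError(
            f"line {lineno}: tsv count field {field!r} must be A:C:G:T or A:C:G:T:depth"
        )
    a, c, g, t = values
    return NucleotideCounts(a, c, g, t)


def read_site_counts(
    path, format: str = "tsv", libraries: Optional[Sequence[LibraryMeta]] = None
) -> list[SiteRecord]:
    """Parse a count table into SiteRecords, preserving input order.

    Errors name the offending line; duplicate (chromosome, position) pairs
    and unknown reference bases are rejected.
    """
    if format not in ("tsv", "sync"):
        raise ValueError(f"unknown count format {format!r}")
    records: list[SiteRecord] = []
    seen: set[tuple[str, int]] = set()
    with _open(path) as fh:
        lib_ids: Optional[list[str]] = None
        if format == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["chrom", "pos", "ref"]:
                raise ValueError("tsv header must start with 'chrom\\tpos\\tref'")
            lib_ids = header[3:]
            if libraries is not None and lib_ids != [l.id for l in libraries]:
                raise ValueError(
                    f"tsv header libraries {lib_ids} do not match metadata "
                    f"{[l.id for l in libraries]}"
                )
        start_line = 2 if format == "tsv" else 1
        for lineno, line in enumerate(fh, start=start_line):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: expected >= 4 columns")
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad position {pos_s!r}") from exc
            if ref not in BASES:
                raise ValueError(f"line {lineno}: unknown base character {ref!r}")
            if (chrom, pos) in seen:
                raise ValueError(f"line {lineno}: duplicate site {chrom}:{pos}")
            seen.add((chrom, pos))
            count_fields = fields[3:]
            if lib_ids is None:
                if libraries is None:
                    raise ValueError("sync format requires library metadata")
                lib_ids = [l.id for l in libraries]
            if len(count_fields) != len(lib_ids):
                raise ValueError(
                    f"line {lineno}: expected {len(lib_ids)} count columns, "
                    f"got {len(count_fields)}"
                )
            counts = {
                lid: _parse_count_field(f, lineno, format)
                for lid, f in zip(lib_ids, count_fields)
            }
            records.append(SiteRecord(SiteKey(chrom, pos, ref), counts))
    return records


def write_site_counts(
    records: Iterable[SiteRecord],
    path,
    format: str = "tsv",
    libraries: Optional[Sequence[LibraryMeta]] = None,
) -> None:
    records = list(records)
    if libraries is not None:
        lib_ids = [l.id for l in libraries]
    elif records:
        lib_ids = list(records[0].counts)
    else:
        lib_ids = []
    with _open(path, "wt") as fh:
        if format == "tsv":
            fh.write("\t".join(["chrom", "pos", "ref", *lib_ids]) + "\n")
            for rec in records:
                fields = [rec.key.chrom, str(rec.key.pos), rec.key.ref]
                for lid in lib_ids:
                    c = rec.counts.get(lid)
                    fields.append("." if c is None else f"{c.a}:{c.c}:{c.g}:{c.t}")
                fh.write("\t".join(fields) + "\n")
        elif format == "sync":
            for rec in records:
                fields = [rec.key.chrom, str(rec.key.pos), rec.key.ref]
                for lid in lib_ids:
                    c = rec.counts.get(lid)
                    if c is None:
                        raise ValueError(
                            "sync format cannot represent missing libraries "
                            f"(site {rec.key.chrom}:{rec.key.pos})"
                        )
                    fields.append(f"{c.a}:{c.t}:{c.c}:{c.g}:0:0")
                fh.write("\t".join(fields) + "\n")
        else:
            raise ValueError(f"unknown count format {format!r}")


def write_site_table(table: SiteTable, path, format: str = "tsv") -> None:
    write_site_counts(table.to_records(), path, format, table.libraries)


def read_site_table(
    path, libraries: Sequence[LibraryMeta], format: str = "tsv"
) -> SiteTable:
    return SiteTable.from_records(
        read_site_counts(path, format, libraries), list(libraries)
    )


def results_frame(rows: Iterable[dict]) -> pd.DataFrame:
    """Normalise result-row dicts to the canonical column set."""
    df = pd.DataFrame(list(rows))
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[RESULT_COLUMNS]


def write_results(rows: Iterable[dict], path, format: str = "tsv") -> None:
    """Write annotated association rows as TSV (full schema) or BED.

    BED intervals are 0-based half-open: a SNP at 1-based position p becomes
    ``start = p - 1, end = p``; the score column carries -log10(p).
    """
    df = results_frame(rows)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "bed":
        with _open(path, "wt") as fh:
            for _, r in df.iterrows():
                name = r["alt"] if pd.notna(r["alt"]) else "."
                score = r["neg_log10_p"] if pd.notna(r["neg_log10_p"]) else 0.0
                fh.write(
                    f"{r['chromosome']}\t{int(r['position']) - 1}\t{int(r['position'])}"
                    f"\t{name}\t{score:.4f}\n"
                )
    else:
        raise ValueError(f"unknown results format {format!r}")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
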