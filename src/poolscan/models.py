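"""Core domain types shared across the pipeline.

Counts are always stored in A, C, G, T order.  Positions are 1-based
inclusive everywhere inside the library; conversion to 0-based half-open
happens only at the BED boundary (see :mod:`poolscan.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

RESISTANT = "resistant"
SUSCEPTIBLE = "susceptible"
GROUPS = (RESISTANT, SUSCEPTIBLE)


@dataclass(frozen=True, slots=True)
class SiteKey:
    """Genomic site identity: chromosome, 1-based position, reference base."""

    chrom: str
    pos: int
    ref: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome identifier must be non-empty")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in BASES:
            raise ValueError(f"reference base must be one of {BASES}, got {self.ref!r}")


@dataclass(frozen=True, slots=True)
class NucleotideCounts:
    """Read counts for the four nucleotides at one site in one library."""

    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0

    def __post_init__(self) -> None:
        for v in (self.a, self.c, self.g, self.t):
            if v < 0:
                raise ValueError(f"negative nucleotide count: {self}")

    @property
    def depth(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def n_alleles(self) -> int:
        """Number of bases observed at least once (0..4)."""
        return sum(1 for v in (self.a, self.c, self.g, self.t) if v > 0)

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.c, self.g, self.t], dtype=np.int64)

    @classmethod
    def from_array(cls, arr: Iterable[int]) -> "NucleotideCounts":
        a, c, g, t = (int(v) for v in arr)
        return cls(a, c, g, t)

    def count(self, base: str) -> int:
        return (self.a, self.c, self.g, self.t)[BASE_INDEX[base]]

    def __add__(self, other: "NucleotideCounts") -> "NucleotideCounts":
        return NucleotideCounts(
            self.a + other.a, self.c + other.c, self.g + other.g, self.t + other.t
        )

    def frequencies(self) -> np.ndarray:
        d = self.depth
        if d == 0:
            return np.zeros(4)
        return self.as_array() / d


@dataclass(frozen=True, slots=True)
class LibraryMeta:
    """One sequencing library: a phenotype group x replicate pool."""

    id: str
    group: str
    replicate: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


def check_libraries(libraries: Iterable[LibraryMeta]) -> None:
    libs = list(libraries)
    ids = [l.id for l in libs]
    if len(set(ids)) != len(ids):
        raise ValueError("library ids must be unique")
    pairs = [(l.group, l.replicate) for l in libs]
    if len(set(pairs)) != len(pairs):
        raise ValueError("(group, replicate) pairs must be unique")
    for g in GROUPS:
        if not any(l.group == g for l in libs):
            raise ValueError(f"at least one {g} library is required")


@dataclass(slots=True)
class SiteRecord:
    """Per-site nucleotide counts for every library.

    A library mapped to ``None`` is explicitly missing at this site; such
    records are excluded by the depth filter.
    """

    key: SiteKey
    counts: dict[str, Optional[NucleotideCounts]]

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.counts.values())

    def pooled(self, library_ids: Optional[Iterable[str]] = None) -> NucleotideCounts:
        ids = list(library_ids) if library_ids is not None else list(self.counts)
        total = NucleotideCounts()
        for i in ids:
            c = self.counts[i]
            if c is not None:
                total = total + c
        return total


class SiteTable:
    """Columnar container for many sites: the pipeline's working format.

    Wraps parallel arrays (chrom, pos, ref) plus a counts tensor of shape
    ``(n_sites, n_libraries, 4)``.  ``SiteRecord`` lists are the row-wise
    view used at I/O boundaries and in the per-site operations.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        counts: np.ndarray,
        libraries: list[LibraryMeta],
        missing: Optional[np.ndarray] = None,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.libraries = list(libraries)
        n, l = len(self.pos), len(self.libraries)
        if self.counts.shape != (n, l, 4):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{n} sites x {l} libraries x 4 bases"
            )
        # missing[i, j] marks library j absent at site i (counts are zero there)
        self.missing = (
            np.zeros((n, l), dtype=bool) if missing is None else np.asarray(missing, bool)
        )
        check_libraries(self.libraries)

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def library_ids(self) -> list[str]:
        return [l.id for l in self.libraries]

    def group_indices(self, group: str) -> list[int]:
        return [i for i, l in enumerate(self.libraries) if l.group == group]

    def group_counts(self, group: str) -> np.ndarray:
        """Replicate-summed counts for one group, shape (n_sites, 4)."""
        return self.counts[:, self.group_indices(group), :].sum(axis=1)

    def depths(self) -> np.ndarray:
        """Per-site per-library depth, shape (n_sites, n_libraries)."""
        return self.counts.sum(axis=2)

    def subset(self, mask: np.ndarray) -> "SiteTable":
        mask = np.asarray(mask)
        return SiteTable(
            self.chrom[mask],
            self.pos[mask],
            self.ref[mask],
            self.counts[mask],
            self.libraries,
            self.missing[mask],
        )

    def keys(self) -> list[SiteKey]:
        return [
            SiteKey(str(c), int(p), str(r))
            for c, p, r in zip(self.chrom, self.pos, self.ref)
        ]

    def to_records(self) -> list[SiteRecord]:
        out = []
        for i, key in enumerate(self.keys()):
            counts: dict[str, Optional[NucleotideCounts]] = {}
            for j, lib in enumerate(self.libraries):
                if self.missing[i, j]:
                    counts[lib.id] = None
                else:
                    counts[lib.id] = NucleotideCounts.from_array(self.counts[i, j])
            out.append(SiteRecord(key, counts))
        return out

    @classmethod
    def from_records(
        cls, records: Iterable[SiteRecord], libraries: list[LibraryMeta]
    ) -> "SiteTable":
        records = list(records)
        n, l = len(records), len(libraries)
        chrom = np.empty(n, dtype=object)
        pos = np.zeros(n, dtype=np.int64)
        ref = np.empty(n, dtype=object)
        counts = np.zeros((n, l, 4), dtype=np.int64)
        missing = np.zeros((n, l), dtype=bool)
        for i, rec in enumerate(records):
            chrom[i], pos[i], ref[i] = rec.key.chrom, rec.key.pos, rec.key.ref
            for j, lib in enumerate(libraries):
                c = rec.counts.get(lib.id)
                if c is None:
                    missing[i, j] = True
                else:
                    counts[i, j] = c.as_array()
        return cls(chrom, pos, ref, counts, libraries, missing)
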