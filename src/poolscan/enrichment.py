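"""Gene-category polymorphism enrichment via Fisher's exact test.

The unit of observation is the analysed (filter-passing) site: for a
category (e.g. the detox families CYP/CCE/GST/Redox) and a chromosome, the
2 x 2 table counts polymorphic vs non-polymorphic sites inside vs outside
category-tagged genes, and the exact hypergeometric p is computed (the
min-likelihood two-sided convention).  Denominators are all analysed sites,
including monomorphic ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .genes import DETOX_TAGS, GeneIndex, GeneModel
from .models import SiteKey

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two_sided"
) -> float:
    """Exact hypergeometric p for the 2 x 2 table [[a, b], [c, d]].

    Two-sided p sums all table probabilities at most as likely as the
    observed table.  Exact for arbitrarily large margins.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    return float(
        stats.fisher_exact([[a, b], [c, d]], alternative=_ALTERNATIVES[alternative]).pvalue
    )


@dataclass(slots=True)
class EnrichmentResult:
    category: str
    chromosome: str
    a: int  # polymorphic, in category
    b: int  # non-polymorphic analysed, in category
    c: int  # polymorphic, outside
    d: int  # non-polymorphic analysed, outside
    fisher_p: Optional[float]  # None when the table is degenerate

    @property
    def proportion_in(self) -> float:
        return self.a / (self.a + self.b) if (self.a + self.b) else float("nan")

    @property
    def proportion_out(self) -> float:
        return self.c / (self.c + self.d) if (self.c + self.d) else float("nan")

    @property
    def defined(self) -> bool:
        return self.fisher_p is not None


def _category_mask(
    keys: Sequence[SiteKey], index: GeneIndex, tags: frozenset[str]
) -> np.ndarray:
    mask = np.zeros(len(keys), dtype=bool)
    for i, key in enumerate(keys):
        for g in index.overlapping(key.chrom, key.pos):
            if g.categories & tags:
                mask[i] = True
                break
    return mask


def category_polymorphism_enrichment(
    analysed_keys: Sequence[SiteKey],
    polymorphic_flags: Sequence[bool],
    genes: Sequence[GeneModel] | GeneIndex,
    category: str | Iterable[str] = "detox",
    per_chromosome: bool = True,
    alternative: str = "two_sided",
) -> list[EnrichmentResult]:
    """Build the per-chromosome 2 x 2 tables and test enrichment.

    ``category`` may be a single tag, an iterable of tags, or the shorthand
    ``"detox"`` for the CYP/CCE/GST/Redox group.  A chromosome with no
    analysed site in the category yields a result with ``fisher_p = None``.
    """
    if isinstance(category, str):
        tags = DETOX_TAGS if category == "detox" else frozenset({category})
        label = category
    else:
        tags = frozenset(category)
        label = "+".join(sorted(tags))
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    poly = np.asarray(polymorphic_flags, dtype=bool)
    if len(poly) != len(analysed_keys):
        raise ValueError("polymorphic_flags length must match analysed_keys")
    in_cat = _category_mask(analysed_keys, index, tags)
    chroms = np.array([k.chrom for k in analysed_keys], dtype=object)

    groups = sorted(set(chroms)) if per_chromosome else ["all"]
    out = []
    for chrom in groups:
        sel = np.ones(len(poly), bool) if chrom == "all" else (chroms == chrom)
        a = int((sel & in_cat & poly).sum())
        b = int((sel & in_cat & ~poly).sum())
        c = int((sel & ~in_cat & poly).sum())
        d = int((sel & ~in_cat & ~poly).sum())
        if a + b == 0 or c + d == 0:
            p = None
        else:
            p = fisher_exact_2x2(a, b, c, d, alternative)
        out.append(EnrichmentResult(label, str(chrom), a, b, c, d, p))
    return out
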