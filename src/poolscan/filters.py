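"""Site-selection cascade: depth window, replicate concordance, cross-group
intersection, and the polymorphism call.

Stage order mirrors the analysis this package reproduces:

1. per-library depth window (default 25 <= depth <= 1000; the ceiling is a
   repetitive-DNA proxy, the floor a precision floor for pool frequencies);
2. within-group replicate heterogeneity chi-square -- replicate-discordant
   sites are library artifacts and are removed;
3. intersection of the two groups' retained sites;
4. polymorphism call on the counts pooled over all libraries.

All filters are pure selections: counts are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import pearson_chi2, pearson_chi2_batch
from .models import GROUPS, NucleotideCounts, SiteTable


@dataclass(frozen=True, slots=True)
class FilterConfig:
    min_depth: int = 25
    max_depth: int = 1000
    #: Replicate-discordance removal level.  This targets gross library
    #: artifacts, so a genome-scale threshold is used rather than a raw
    #: per-site 0.05 (which would discard ~5% of perfectly concordant sites
    #: at every polymorphic locus); see docs/methods.md.
    heterogeneity_alpha: float = 1e-6
    min_minor_count: int = 2
    min_minor_freq: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.min_depth <= self.max_depth):
            raise ValueError("require 0 < min_depth <= max_depth")
        if not (0 < self.heterogeneity_alpha < 1):
            raise ValueError("heterogeneity_alpha must be in (0, 1)")


@dataclass(slots=True)
class FilterReport:
    """Counts of sites surviving each stage of the cascade."""

    n_input: int = 0
    depth_pass: dict[str, int] = field(default_factory=dict)
    heterogeneity_pass: dict[str, int] = field(default_factory=dict)
    n_common: int = 0
    n_polymorphic: int = 0

    def as_rows(self) -> list[dict]:
        rows = [{"stage": "input", "group": "all", "sites": self.n_input}]
        for g, n in self.depth_pass.items():
            rows.append({"stage": "depth", "group": g, "sites": n})
        for g, n in self.heterogeneity_pass.items():
            rows.append({"stage": "heterogeneity", "group": g, "sites": n})
        rows.append({"stage": "common", "group": "both", "sites": self.n_common})
        rows.append({"stage": "polymorphic", "group": "both", "sites": self.n_polymorphic})
        return rows


def depth_filter(record, config: FilterConfig, library_ids=None) -> bool:
    """Keep iff every considered library has min_depth <= depth <= max_depth.

    A missing library (``None`` counts) fails the filter: only sites covered
    in every library are comparable across pools.
    """
    ids = list(library_ids) if library_ids is not None else list(record.counts)
    for i in ids:
        c = record.counts.get(i)
        if c is None:
            return False
        if not (config.min_depth <= c.depth <= config.max_depth):
            return False
    return True


def replicate_heterogeneity_test(
    counts_rep1: NucleotideCounts, counts_rep2: NucleotideCounts
) -> tuple[float, int, float]:
    """Pearson chi-square comparing nucleotide proportions between two
    replicate libraries, with (n - 1) degrees of freedom where n is the
    number of bases observed in either replicate.

    Monomorphic sites (n = 1) return (0, 0, 1) by convention.
    """
    if counts_rep1.depth == 0 or counts_rep2.depth == 0:
        raise ValueError("heterogeneity test requires positive depth in both replicates")
    table = np.stack([counts_rep1.as_array(), counts_rep2.as_array()])
    return pearson_chi2(table)


def polymorphic_call(pooled: NucleotideCounts, config: FilterConfig) -> bool:
    """A site is polymorphic iff the second-most-frequent base in the pooled
    counts reaches both the minor-count and minor-frequency thresholds."""
    arr = np.sort(pooled.as_array())[::-1]
    depth = arr.sum()
    if depth == 0:
        return False
    minor = arr[1]
    return minor >= config.min_minor_count and minor / depth >= config.min_minor_freq


def _group_masks(table: SiteTable, config: FilterConfig):
    """Depth and heterogeneity pass masks per group (vectorised)."""
    depths = table.depths()
    present = ~table.missing
    masks = {}
    for group in GROUPS:
        idx = table.group_indices(group)
        d = depths[:, idx]
        ok = present[:, idx].all(axis=1) & (
            ((d >= config.min_depth) & (d <= config.max_depth)).all(axis=1)
        )
        masks[group] = {"depth": ok}
    for group in GROUPS:
        idx = table.group_indices(group)
        dmask = masks[group]["depth"]
        het = dmask.copy()
        if dmask.any() and len(idx) >= 2:
            sub = table.counts[dmask][:, idx, :]
            _, _, p = pearson_chi2_batch(sub)
            het[dmask] = p >= config.heterogeneity_alpha
        masks[group]["het"] = het
    return masks


def select_common_polymorphic_sites(
    table: SiteTable, config: FilterConfig | None = None
) -> tuple[SiteTable, FilterReport]:
    """Run the full cascade; returns the retained polymorphic sites and a
    report with every stage tally.

    An empty intersection yields an empty table, not an error.
    """
    config = config or FilterConfig()
    report = FilterReport(n_input=len(table))
    masks = _group_masks(table, config)
    for g in GROUPS:
        report.depth_pass[g] = int(masks[g]["depth"].sum())
        report.heterogeneity_pass[g] = int(masks[g]["het"].sum())
    common = masks[GROUPS[0]]["het"] & masks[GROUPS[1]]["het"]
    report.n_common = int(common.sum())

    pooled = table.counts.sum(axis=1)  # (n, 4)
    sorted_counts = np.sort(pooled, axis=1)[:, ::-1]
    depth = pooled.sum(axis=1)
    minor = sorted_counts[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        minor_freq = np.where(depth > 0, minor / np.maximum(depth, 1), 0.0)
    poly = common & (minor >= config.min_minor_count) & (minor_freq >= config.min_minor_freq)
    report.n_polymorphic = int(poly.sum())
    return table.subset(poly), report
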