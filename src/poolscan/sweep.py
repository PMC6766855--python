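"""Selective-sweep diagnostics from expected heterozygosity.

At each significant SNP the expected heterozygosity H_exp = 1 - sum(p_i^2)
is computed per phenotype group from the replicate-summed read counts.  A
recent sweep in the survivors depresses their diversity, so the per-site
difference Het(alive) - Het(dead) should be negative around the selected
locus; a one-sample t test of the differences against zero summarises each
chromosome, and a chromosome is flagged as swept when the mean difference
is negative and p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationRecord
from .models import SiteKey


def site_heterozygosity(frequencies: Sequence[float], tol: float = 1e-9) -> float:
    """H_exp = 1 - sum(p_i^2) over the allele frequencies at one site."""
    p = np.asarray(frequencies, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")
    return float(1.0 - (p**2).sum())


@dataclass(slots=True)
class SweepRecord:
    key: SiteKey
    het_resistant: float  # Het(alive)
    het_susceptible: float  # Het(dead)

    @property
    def diff(self) -> float:
        return self.het_resistant - self.het_susceptible


def sweep_records(records: Sequence[AssociationRecord]) -> list[SweepRecord]:
    """Per-site heterozygosities from replicate-summed group counts."""
    out = []
    for rec in records:
        hr = site_heterozygosity(rec.resistant.frequencies())
        hs = site_heterozygosity(rec.susceptible.frequencies())
        out.append(SweepRecord(rec.key, hr, hs))
    return out


@dataclass(slots=True)
class SweepTestResult:
    chromosome: str
    n: int
    mean: float
    cl_low: float
    cl_high: float
    t: float
    p: float
    sweep: bool  # mean < 0 and p < 0.05


def het_difference_test(
    records: Sequence[SweepRecord], chromosome: str = "", alpha: float = 0.05
) -> SweepTestResult:
    """One-sample t test of Het(alive) - Het(dead) against zero.

    Degenerate inputs: zero variance with nonzero mean gives p = 0; all
    diffs exactly zero give t = 0, p = 1, no sweep.
    """
    diffs = np.array([r.diff for r in records], dtype=float)
    diffs = diffs[np.isfinite(diffs)]
    n = len(diffs)
    if n < 2:
        raise ValueError("het_difference_test requires >= 2 finite differences")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return SweepTestResult(chromosome, n, 0.0, 0.0, 0.0, 0.0, 1.0, False)
        inf = math.inf if mean > 0 else -math.inf
        return SweepTestResult(chromosome, n, mean, mean, mean, inf, 0.0, mean < 0)
    se = sd / math.sqrt(n)
    t = mean / se
    p = float(2 * stats.t.sf(abs(t), n - 1))
    half = float(stats.t.ppf(1 - 0.05 / 2, n - 1)) * se
    return SweepTestResult(
        chromosome, n, mean, mean - half, mean + half, t, p, mean < 0 and p < alpha
    )


def chromosome_sweep_tests(
    records: Sequence[SweepRecord], alpha: float = 0.05
) -> list[SweepTestResult]:
    """Per-chromosome t tests; chromosomes with < 2 usable sites yield an
    undefined (no-sweep) row with nan statistics."""
    by_chrom: dict[str, list[SweepRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.key.chrom, []).append(r)
    out = []
    for chrom in sorted(by_chrom):
        recs = by_chrom[chrom]
        if len(recs) < 2:
            out.append(
                SweepTestResult(
                    chrom, len(recs), math.nan, math.nan, math.nan, math.nan, math.nan, False
                )
            )
        else:
            out.append(het_difference_test(recs, chrom, alpha))
    return out


def region_profile(
    sweep_recs: Sequence[SweepRecord],
    assoc_recs: Sequence[AssociationRecord],
    focal_span: tuple[str, int, int],
    flank_bases: int = 1_400_000,
) -> pd.DataFrame:
    """Ordered per-SNP table around a focal gene span for sweep plotting.

    Returns all provided SNPs inside [start - flank, end + flank] on the
    focal chromosome, sorted by position, with both group heterozygosities
    and the association score.
    """
    chrom, start, end = focal_span
    if flank_bases < 0:
        raise ValueError("flank_bases must be >= 0")
    lo, hi = start - flank_bases, end + flank_bases
    score = {(r.key.chrom, r.key.pos): r.neg_log10_p for r in assoc_recs}
    rows = []
    for r in sweep_recs:
        if r.key.chrom == chrom and lo <= r.key.pos <= hi:
            rows.append(
                {
                    "position": r.key.pos,
                    "het_resistant": r.het_resistant,
                    "het_susceptible": r.het_susceptible,
                    "diff": r.diff,
                    "neg_log10_p": score.get((r.key.chrom, r.key.pos), math.nan),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["position", "het_resistant", "het_susceptible", "diff", "neg_log10_p"],
    )
    return df.sort_values("position").reset_index(drop=True)


def sweep_table(results: Sequence[SweepTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": r.chromosome,
                "N": r.n,
                "mean": r.mean,
                "cl_low": r.cl_low,
                "cl_high": r.cl_high,
                "t": r.t,
                "p": r.p,
                "sweep": "Y" if r.sweep else "N",
            }
            for r in results
        ]
    )
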