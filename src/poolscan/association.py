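"""Group-vs-group allele-count association and per-chromosome FDR control.

The association statistic is the Pearson contingency chi-square on the
2 x n table of replicate-summed nucleotide counts (resistant row,
susceptible row; one column per base observed in the pooled table), with
n - 1 degrees of freedom.  P-values are controlled per chromosome with the
Benjamini-Hochberg step-up procedure at alpha = 0.01 by default.

No continuity correction and no pseudocounts are applied; base columns with
zero total count are dropped before computing the statistic, which reduces
the degrees of freedom accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .models import BASES, NucleotideCounts, SiteKey, SiteTable

#: -log10(p) reported when p underflows to zero (the true value is larger).
NEG_LOG10_CAP = 320.0


def pearson_chi2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square for an r x c count table.

    Columns whose total is zero are dropped; df = (r - 1) * (c' - 1) over the
    remaining c' columns.  A table with fewer than two non-empty columns is
    the monomorphic degenerate case and returns (0.0, 0, 1.0).

    Raises
    ------
    ValueError
        If any row total is zero (no reads in one library/group).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("expected a 2-D count table")
    row = t.sum(axis=1)
    if np.any(row == 0):
        raise ValueError("all-zero row in contingency table")
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] <= 1:
        return 0.0, 0, 1.0
    col = t.sum(axis=0)
    grand = t.sum()
    expected = np.outer(row, col) / grand
    chi2 = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def pearson_chi2_batch(
    tables: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`pearson_chi2` over a stack of 2 x 4 tables.

    Parameters
    ----------
    tables:
        Integer array of shape ``(n, r, 4)``.

    Returns
    -------
    (chi2, df, p) arrays of length n.  Sites with an all-zero row get
    ``nan`` statistics (callers are expected to have filtered those).
    """
    t = np.asarray(tables, dtype=float)
    n = t.shape[0]
    row = t.sum(axis=2)  # (n, r)
    col = t.sum(axis=1)  # (n, 4)
    grand = row.sum(axis=1)  # (n,)
    bad = np.any(row == 0, axis=1)
    n_alleles = (col > 0).sum(axis=1)
    df = (t.shape[1] - 1) * np.maximum(n_alleles - 1, 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row[:, :, None] * col[:, None, :] / grand[:, None, None]
        terms = (t - expected) ** 2 / expected
    terms = np.nan_to_num(terms, nan=0.0, posinf=0.0)
    chi2 = terms.sum(axis=(1, 2))

    p = np.ones(n)
    m = df > 0
    p[m] = stats.chi2.sf(chi2[m], df[m])
    chi2[df == 0] = 0.0
    chi2[bad] = np.nan
    p[bad] = np.nan
    return chi2, df.astype(int), p


def neg_log10(p: float, cap: float = NEG_LOG10_CAP) -> tuple[float, bool]:
    """-log10(p), capped when p underflows; returns (value, capped?)."""
    if p <= 0.0:
        return cap, True
    return min(-math.log10(p), cap), -math.log10(p) > cap


@dataclass(slots=True)
class AssociationRecord:
    """Association result at one site."""

    key: SiteKey
    resistant: NucleotideCounts
    susceptible: NucleotideCounts
    chi2: float
    df: int
    p: float
    neg_log10_p: float
    p_capped: bool = False
    fdr_pass: bool = False

    def group_frequencies(self) -> dict[str, dict[str, float]]:
        return {
            "resistant": dict(zip(BASES, self.resistant.frequencies())),
            "susceptible": dict(zip(BASES, self.susceptible.frequencies())),
        }

    def alt_base(self) -> str:
        """Most frequent non-reference base in the overall pooled counts."""
        pooled = (self.resistant + self.susceptible).as_array()
        order = np.argsort(pooled)[::-1]
        for i in order:
            if BASES[i] != self.key.ref:
                return BASES[i]
        return self.key.ref  # unreachable for polymorphic input


def association_test(
    resistant_counts: Sequence[NucleotideCounts],
    susceptible_counts: Sequence[NucleotideCounts],
    key: Optional[SiteKey] = None,
    cap: float = NEG_LOG10_CAP,
) -> AssociationRecord:
    """Score one site: replicates are summed within group, then the 2 x n
    group-by-allele table is tested with Pearson chi-square.

    Raises
    ------
    ValueError
        If the pooled table is monomorphic (filters should have removed it).
    """
    res = sum(resistant_counts, NucleotideCounts())
    sus = sum(susceptible_counts, NucleotideCounts())
    table = np.stack([res.as_array(), sus.as_array()])
    if (table.sum(axis=0) > 0).sum() <= 1:
        raise ValueError("monomorphic pooled table; site should have been filtered")
    chi2, df, p = pearson_chi2(table)
    nl, capped = neg_log10(p, cap)
    return AssociationRecord(
        key=key if key is not None else SiteKey("unknown", 1, "A"),
        resistant=res,
        susceptible=sus,
        chi2=chi2,
        df=df,
        p=p,
        neg_log10_p=nl,
        p_capped=capped,
    )


@dataclass(slots=True)
class FDRResult:
    """Benjamini-Hochberg summary for one chromosome."""

    chromosome: str
    alpha: float
    m: int
    k: int
    threshold_neg_log10: Optional[float]


def bh_mask(pvalues: Sequence[float], alpha: float) -> np.ndarray:
    """Boolean discovery mask of the BH step-up procedure.

    Finds the largest k with p_(k) <= k * alpha / m and flags every p at or
    below p_(k) (standard step-up tie handling).
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.sort(p)
    crit = alpha * np.arange(1, m + 1) / m
    ok = np.nonzero(order <= crit)[0]
    if len(ok) == 0:
        return np.zeros(m, dtype=bool)
    threshold = order[ok[-1]]
    return p <= threshold


def bh_thresholds(
    pvalues_by_chrom: Mapping[str, Sequence[float]], alpha: float = 0.01
) -> list[FDRResult]:
    """Per-chromosome BH summaries (m, k, -log10 of the passing threshold)."""
    out = []
    for chrom, pvals in pvalues_by_chrom.items():
        p = np.asarray(pvals, dtype=float)
        if len(p) == 0:
            out.append(FDRResult(chrom, alpha, 0, 0, None))
            continue
        mask = bh_mask(p, alpha)
        k = int(mask.sum())
        thr = float(-np.log10(p[mask].max())) if k else None
        out.append(FDRResult(chrom, alpha, len(p), k, thr))
    return out


def associate_sites(
    table: SiteTable,
    alpha: float = 0.01,
    per_chromosome: bool = True,
    cap: float = NEG_LOG10_CAP,
) -> tuple[list[AssociationRecord], list[FDRResult]]:
    """Vectorised association over a filtered site table plus FDR flags."""
    res = table.group_counts("resistant")
    sus = table.group_counts("susceptible")
    stacked = np.stack([res, sus], axis=1)  # (n, 2, 4)
    chi2, df, p = pearson_chi2_batch(stacked)

    records = []
    for i, key in enumerate(table.keys()):
        nl, capped = neg_log10(float(p[i]), cap)
        records.append(
            AssociationRecord(
                key=key,
                resistant=NucleotideCounts.from_array(res[i]),
                susceptible=NucleotideCounts.from_array(sus[i]),
                chi2=float(chi2[i]),
                df=int(df[i]),
                p=float(p[i]),
                neg_log10_p=nl,
                p_capped=capped,
            )
        )

    if per_chromosome:
        groups: dict[str, list[int]] = {}
        for i, rec in enumerate(records):
            groups.setdefault(rec.key.chrom, []).append(i)
    else:
        groups = {"all": list(range(len(records)))}

    fdr_results = []
    for chrom, idx in groups.items():
        pvals = np.array([records[i].p for i in idx])
        mask = bh_mask(pvals, alpha)
        for j, i in enumerate(idx):
            records[i].fdr_pass = bool(mask[j])
        k = int(mask.sum())
        thr = float(-np.log10(pvals[mask].max())) if k else None
        fdr_results.append(FDRResult(chrom, alpha, len(idx), k, thr))
    return records, fdr_results
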