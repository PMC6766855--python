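"""Forward simulation of the pooled exome study design.

The generator emulates the experiment the pipeline analyses: a field cohort
of mosquitoes segregating a biallelic resistance locus, phenotyped with a
discriminating insecticide dose, with survivors and knocked-down females
pooled (25 per pool, two replicate pools per phenotype) and sequenced to a
per-site depth with a small base-miscall rate.

Model
-----
* Each individual carries two haplotypes.  At the causal site the resistant
  allele has population frequency ``resistant_allele_freq``.
* Soft-sweep haplotype structure: a fraction ``founder_fidelity`` of
  resistant haplotypes descend from one major founder lineage that carries
  its own allele at every polymorphic site within ``linked_block_size`` of
  the causal locus.  Recombination since the sweep is modelled as a per-site
  probability of switching back to the population background, proportional
  to distance (d / linked_block_size, capped at 1), which yields
  allele-frequency divergence between phenotype groups that decays with
  distance from the causal site.
* Survival under exposure is Bernoulli per individual given its causal
  genotype; a genotype-independent ``recovered_fraction`` of individuals is
  labelled recovered and excluded from pooling, mirroring the discriminating-
  dose design.
* Sequencing: per site and library the depth is negative binomial
  (``depth_mean``, ``depth_dispersion``); read alleles are drawn with
  replacement from the pool's 2 x pool_size chromosomes; each read is
  miscalled to a uniformly chosen different base with probability
  ``error_rate``.

Identical seed + config give bit-identical outputs; independent named
substreams are used per stage so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genes import CDS, GeneModel, Interval
from .models import (
    BASES,
    LibraryMeta,
    SiteKey,
    SiteTable,
)

RESISTANT, SUSCEPTIBLE, RECOVERED = "resistant", "susceptible", "recovered"


def default_gene_layout(
    n_chromosomes: int = 3,
    chromosome_length: int = 30_000_000,
    genes_per_chromosome: int = 60,
    gene_length: int = 10_002,
) -> list[GeneModel]:
    """A deterministic exome-like layout: evenly spaced single-CDS genes with
    functional category tags (detox families, neuro, cuticle, other).

    The gene nearest the midpoint of the last chromosome is tagged ``neuro``
    and is the default host of the causal locus (a neural target-site gene,
    by analogy with the voltage-gated sodium channel).
    """
    rng = np.random.default_rng(190283)  # layout constant, not a simulation stream
    tags = ["CYP"] * 5 + ["CCE"] * 3 + ["GST"] * 1 + ["Redox"] * 1 + ["neuro"] * 6 + ["cuticle"] * 3 + ["other"] * 41
    genes = []
    spacing = chromosome_length // (genes_per_chromosome + 1)
    for ci in range(n_chromosomes):
        chrom = str(ci + 1)
        order = rng.permutation(genes_per_chromosome)
        for gi in range(genes_per_chromosome):
            start = spacing * (gi + 1)
            tag = tags[order[gi] % len(tags)]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"g{chrom}_{gi + 1:03d}",
                    chrom=chrom,
                    strand=strand,
                    intervals=[Interval(start, start + gene_length - 1, CDS)],
                    categories=frozenset({tag}),
                )
            )
    # host gene for the causal locus: nearest the midpoint of the last chromosome
    mid = chromosome_length // 2
    host = min(
        (g for g in genes if g.chrom == str(n_chromosomes)),
        key=lambda g: abs((g.span[0] + g.span[1]) // 2 - mid),
    )
    host.categories = frozenset({"neuro"})
    return genes


@dataclass
class SimulationConfig:
    """Full specification of a synthetic pooled-exome experiment."""

    n_chromosomes: int = 3
    sites_per_chromosome: int = 3000
    chromosome_length: int = 30_000_000
    gene_layout: Optional[list[GeneModel]] = None
    causal_site: Optional[tuple[str, int]] = None  # default: centre of the host gene
    resistant_allele_freq: float = 0.6
    #: survival probability under exposure per causal genotype; the default
    #: is strongly recessive protection, which reproduces survivor pools
    #: nearly fixed for the resistant allele while knocked-down pools retain
    #: heterozygote carriers
    survival_probs: dict[str, float] = field(
        default_factory=lambda: {"RR": 0.995, "RS": 0.05, "SS": 0.005}
    )
    recovered_fraction: float = 0.24
    linked_block_size: int = 4_200_000
    #: fraction of resistant haplotypes descending from the major founder
    #: lineage (a nearly hard sweep); linked markers tag the lineage, not
    #: the causal allele, so their phenotype association stays strictly
    #: below the causal site's
    founder_fidelity: float = 0.95
    polymorphic_fraction: float = 0.064
    #: per-category multiplier on the polymorphism probability of sites in
    #: tagged genes (the detox families are more variable in this design)
    polymorphism_boost: dict[str, float] = field(
        default_factory=lambda: {"CYP": 1.5, "CCE": 1.5, "GST": 1.5, "Redox": 1.5}
    )
    exonic_site_fraction: float = 0.8
    n_individuals_exposed: int = 390
    pool_size: int = 25
    n_replicates: int = 2
    depth_mean: float = 60.0
    depth_dispersion: Optional[float] = 60.0  # None = constant depth
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_layout is None:
            self.gene_layout = default_gene_layout(
                self.n_chromosomes, self.chromosome_length
            )
        if self.causal_site is None:
            host = self._host_gene()
            lo, hi = host.span
            self.causal_site = (host.chrom, (lo + hi) // 2)
        self.validate()

    def _host_gene(self) -> GeneModel:
        if self.causal_site is not None:
            chrom, pos = self.causal_site
            for g in self.gene_layout:
                if g.chrom == chrom and g.span[0] <= pos <= g.span[1]:
                    return g
            raise ValueError("causal_site must lie inside a gene span")
        neuro = [g for g in self.gene_layout if "neuro" in g.categories]
        pool = neuro or self.gene_layout
        mid = self.chromosome_length // 2
        last = str(self.n_chromosomes)
        on_last = [g for g in pool if g.chrom == last] or pool
        return min(on_last, key=lambda g: abs((g.span[0] + g.span[1]) // 2 - mid))

    def validate(self) -> None:
        probs = [
            self.resistant_allele_freq,
            self.recovered_fraction,
            self.error_rate,
            self.polymorphic_fraction,
            *self.survival_probs.values(),
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if set(self.survival_probs) != {"RR", "RS", "SS"}:
            raise ValueError("survival_probs must map exactly RR, RS, SS")
        if self.pool_size * self.n_replicates * 2 > self.n_individuals_exposed:
            raise ValueError(
                "pool_size x n_replicates x 2 exceeds the number of exposed individuals"
            )
        self._host_gene()  # raises if causal site is outside all genes


@dataclass
class TruthTable:
    """Ground truth for recovery tests: one row per simulated site."""

    table: pd.DataFrame  # chrom,pos,ref,alt,pop_freq,freq_resistant,freq_susceptible,causal,dist_to_causal,category
    causal: SiteKey

    def __post_init__(self) -> None:
        n_causal = int(self.table.causal.sum())
        if n_causal != 1:
            raise ValueError(f"expected exactly one causal site, found {n_causal}")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class Cohort:
    """Simulated individuals: haplotypes, phenotypes and ground truth."""

    config: SimulationConfig
    sites: pd.DataFrame  # chrom, pos, ref, alt, pop_freq, category, gene_id
    alt_haplotypes: np.ndarray  # bool, (2 * n_individuals, n_sites)
    phenotype: np.ndarray  # str per individual
    truth: TruthTable

    @property
    def n_individuals(self) -> int:
        return self.alt_haplotypes.shape[0] // 2

    def haplotype_indices(self, individuals: np.ndarray) -> np.ndarray:
        return np.ravel(np.column_stack([2 * individuals, 2 * individuals + 1]))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("sites", "haplotypes", "phenotype", "pools", "sequencing")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _place_sites(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = config.gene_layout
    rows = []
    causal_chrom, causal_pos = config.causal_site
    for ci in range(config.n_chromosomes):
        chrom = str(ci + 1)
        chrom_genes = [g for g in genes if g.chrom == chrom]
        n = config.sites_per_chromosome
        n_exonic = int(round(n * config.exonic_site_fraction)) if chrom_genes else 0
        positions = []
        if n_exonic:
            gidx = rng.integers(0, len(chrom_genes), size=n_exonic)
            for gi in gidx:
                lo, hi = chrom_genes[gi].span
                positions.append(int(rng.integers(lo, hi + 1)))
        positions.extend(
            int(p) for p in rng.integers(1, config.chromosome_length + 1, size=n - n_exonic)
        )
        if chrom == causal_chrom:
            positions.append(causal_pos)
        for pos in sorted(set(positions)):
            rows.append({"chrom": chrom, "pos": pos})
    df = pd.DataFrame(rows)

    # containing gene / category per site
    gene_id = np.full(len(df), "", dtype=object)
    category = np.full(len(df), "intergenic", dtype=object)
    for g in genes:
        lo, hi = g.span
        m = (df.chrom.values == g.chrom) & (df.pos.values >= lo) & (df.pos.values <= hi)
        gene_id[m] = g.gene_id
        category[m] = sorted(g.categories)[0]
    df["gene_id"], df["category"] = gene_id, category

    ref_idx = rng.integers(0, 4, size=len(df))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(df))) % 4
    df["ref"] = [BASES[i] for i in ref_idx]
    df["alt"] = [BASES[i] for i in alt_idx]

    boost = np.array(
        [config.polymorphism_boost.get(c, 1.0) for c in df.category], dtype=float
    )
    p_poly = np.clip(config.polymorphic_fraction * boost, 0, 1)
    poly = rng.random(len(df)) < p_poly
    freq = np.where(poly, rng.uniform(0.05, 0.5, size=len(df)), 0.0)

    causal_mask = (df.chrom.values == causal_chrom) & (df.pos.values == causal_pos)
    freq[causal_mask] = config.resistant_allele_freq
    df["pop_freq"] = freq
    df["causal"] = causal_mask
    return df


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw haplotypes and phenotype every individual.

    Raises later (at pooling) if a phenotype class is too small; phenotyping
    itself always succeeds.
    """
    streams = _streams(config.seed)
    sites = _place_sites(config, streams["sites"])
    rng = streams["haplotypes"]

    n_hap = 2 * config.n_individuals_exposed
    n_sites = len(sites)
    freq = sites.pop_freq.values
    causal_idx = int(np.nonzero(sites.causal.values)[0][0])
    causal_chrom, causal_pos = config.causal_site

    # background population draw at every site
    alt = rng.random((n_hap, n_sites)) < freq[None, :]

    # causal allele and founder lineage
    r_hap = rng.random(n_hap) < config.resistant_allele_freq
    founder = r_hap & (rng.random(n_hap) < config.founder_fidelity)
    alt[:, causal_idx] = r_hap

    # hitchhiking block: founder haplotypes keep the founder's alleles at
    # linked polymorphic sites unless recombination has switched them back
    dist = np.abs(sites.pos.values - causal_pos)
    linked = (
        (sites.chrom.values == causal_chrom)
        & (dist <= config.linked_block_size)
        & (freq > 0)
        & ~sites.causal.values
    )
    linked_idx = np.nonzero(linked)[0]
    if len(linked_idx):
        founder_allele = rng.random(len(linked_idx)) < freq[linked_idx]
        switch_p = np.minimum(dist[linked_idx] / config.linked_block_size, 1.0)
        retained = founder[:, None] & (
            rng.random((n_hap, len(linked_idx))) >= switch_p[None, :]
        )
        block = alt[:, linked_idx]
        block[retained] = np.broadcast_to(founder_allele, retained.shape)[retained]
        alt[:, linked_idx] = block

    # phenotype: survival depends on causal genotype; a genotype-independent
    # fraction is labelled recovered and later excluded from pooling
    geno = r_hap.reshape(-1, 2).sum(axis=1)  # 0, 1, 2 resistant alleles
    s = np.array(
        [config.survival_probs["SS"], config.survival_probs["RS"], config.survival_probs["RR"]]
    )[geno]
    u = streams["phenotype"].random(config.n_individuals_exposed)
    rc = config.recovered_fraction
    phenotype = np.where(
        u < s * (1 - rc), RESISTANT, np.where(u < s * (1 - rc) + rc, RECOVERED, SUSCEPTIBLE)
    ).astype(object)

    truth_df = sites[["chrom", "pos", "ref", "alt", "pop_freq", "causal", "category"]].copy()
    for label, col in ((RESISTANT, "freq_resistant"), (SUSCEPTIBLE, "freq_susceptible")):
        members = np.nonzero(phenotype == label)[0]
        if len(members):
            hap_idx = np.ravel(np.column_stack([2 * members, 2 * members + 1]))
            truth_df[col] = alt[hap_idx, :].mean(axis=0)
        else:
            truth_df[col] = np.nan
    truth_df["dist_to_causal"] = np.where(
        truth_df.chrom.values == causal_chrom, np.abs(truth_df.pos.values - causal_pos), -1
    )
    causal_ref = str(sites.ref.values[causal_idx])
    truth = TruthTable(truth_df, SiteKey(causal_chrom, causal_pos, causal_ref))
    return Cohort(config, sites, alt, phenotype, truth)


def assign_pools(
    cohort: Cohort,
    rng: Optional[np.random.Generator] = None,
    shared_replicates: bool = False,
) -> dict[str, np.ndarray]:
    """Draw pool membership: ``pool_size`` individuals per replicate per
    phenotype group, without replacement.

    ``shared_replicates=True`` re-uses the same individuals in every
    replicate of a group (technical replicates), which is the null design
    for sequencing-noise-only calibration checks.

    Raises
    ------
    ValueError
        Naming the deficient phenotype class when too few individuals exist.
    """
    config = cohort.config
    rng = rng if rng is not None else _streams(config.seed)["pools"]
    pools: dict[str, np.ndarray] = {}
    for group, label in (("res", RESISTANT), ("sus", SUSCEPTIBLE)):
        members = np.nonzero(cohort.phenotype == label)[0]
        needed = config.pool_size * (1 if shared_replicates else config.n_replicates)
        if len(members) < needed:
            raise ValueError(
                f"phenotype class {label!r} has {len(members)} individuals, "
                f"need {needed} for pooling"
            )
        chosen = rng.choice(members, size=needed, replace=False)
        for rep in range(config.n_replicates):
            if shared_replicates:
                pool = chosen
            else:
                pool = chosen[rep * config.pool_size : (rep + 1) * config.pool_size]
            pools[f"{group}_{rep + 1}"] = np.sort(pool)
    return pools


def _libraries(config: SimulationConfig) -> list[LibraryMeta]:
    libs = []
    for group, gname in (("res", RESISTANT), ("sus", SUSCEPTIBLE)):
        for rep in range(1, config.n_replicates + 1):
            libs.append(LibraryMeta(f"{group}_{rep}", gname, rep))
    return libs


def sequence_pools(
    cohort: Cohort,
    pools: dict[str, np.ndarray],
    rng: Optional[np.random.Generator] = None,
) -> SiteTable:
    """Simulate pooled sequencing of every library.

    Per site and library: depth from the negative binomial depth model,
    read alleles binomial in the pool allele frequency, then uniform
    miscalls at ``error_rate``.  Counts always sum to the drawn depth;
    depth 0 yields an all-zero site (removed later by the depth filter).
    """
    config = cohort.config
    rng = rng if rng is not None else _streams(config.seed)["sequencing"]
    libs = _libraries(config)
    sites = cohort.sites
    n_sites = len(sites)
    ref_idx = np.array([BASES.index(b) for b in sites.ref.values])
    alt_idx = np.array([BASES.index(b) for b in sites.alt.values])

    counts = np.zeros((n_sites, len(libs), 4), dtype=np.int64)
    for j, lib in enumerate(libs):
        hap_idx = cohort.haplotype_indices(pools[lib.id])
        q = cohort.alt_haplotypes[hap_idx, :].mean(axis=0)
        if config.depth_dispersion is None:
            depth = np.full(n_sites, int(round(config.depth_mean)), dtype=np.int64)
        else:
            r = config.depth_dispersion
            depth = rng.negative_binomial(r, r / (r + config.depth_mean), size=n_sites)
        alt_reads = rng.binomial(depth, q)
        ref_reads = depth - alt_reads
        lib_counts = np.zeros((n_sites, 4), dtype=np.int64)
        np.add.at(lib_counts, (np.arange(n_sites), ref_idx), ref_reads)
        np.add.at(lib_counts, (np.arange(n_sites), alt_idx), alt_reads)
        if config.error_rate > 0:
            for b in range(4):
                errs = rng.binomial(lib_counts[:, b], config.error_rate)
                if errs.sum() == 0:
                    continue
                lib_counts[:, b] -= errs
                dest = rng.multinomial(errs, [1 / 3] * 3)
                others = [x for x in range(4) if x != b]
                for k, ob in enumerate(others):
                    lib_counts[:, ob] += dest[:, k]
        counts[:, j, :] = lib_counts

    return SiteTable(
        sites.chrom.values.astype(object),
        sites.pos.values,
        sites.ref.values.astype(object),
        counts,
        libs,
    )


@dataclass
class SimulatedExperiment:
    table: SiteTable
    truth: TruthTable
    cohort: Cohort
    pools: dict[str, np.ndarray]

    @property
    def libraries(self) -> list[LibraryMeta]:
        return self.table.libraries


def simulate_experiment(
    config: SimulationConfig, shared_replicates: bool = False
) -> SimulatedExperiment:
    """Cohort -> pools -> sequencing, with one seed governing everything."""
    cohort = simulate_cohort(config)
    streams = _streams(config.seed)
    pools = assign_pools(cohort, streams["pools"], shared_replicates)
    table = sequence_pools(cohort, pools, streams["sequencing"])
    return SimulatedExperiment(table, cohort.truth, cohort, pools)


def write_reference_fasta(cohort: Cohort, path, line_width: int = 70) -> None:
    """Reference sequence consistent with the simulated sites: random bases
    everywhere except site positions, which carry the site's reference base.
    Intended for scaled-down configs (length ~ chromosome_length)."""
    rng = np.random.default_rng(np.random.SeedSequence(cohort.config.seed).spawn(6)[5])
    with open(path, "w") as fh:
        for ci in range(cohort.config.n_chromosomes):
            chrom = str(ci + 1)
            length = cohort.config.chromosome_length
            seq = np.array(list("ACGT"))[rng.integers(0, 4, size=length)]
            m = cohort.sites.chrom.values == chrom
            seq[cohort.sites.pos.values[m] - 1] = cohort.sites.ref.values[m]
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, length, line_width):
                fh.write(s[i : i + line_width] + "\n")
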