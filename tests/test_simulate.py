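"""The synthetic cohort / pooled sequencing generator."""

import numpy as np
import pytest

from poolscan import (
    FilterConfig,
    SimulationConfig,
    assign_pools,
    select_common_polymorphic_sites,
    sequence_pools,
    simulate_cohort,
    simulate_experiment,
)


def small_config(**kw):
    base = dict(seed=3, sites_per_chromosome=200, n_chromosomes=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_probabilities_bounded(self):
        with pytest.raises(ValueError, match="probabilities"):
            small_config(resistant_allele_freq=1.4)

    def test_pool_demand_bounded_by_cohort(self):
        with pytest.raises(ValueError, match="exceeds"):
            small_config(n_individuals_exposed=90, pool_size=25, n_replicates=2)

    def test_causal_site_must_lie_in_a_gene(self):
        with pytest.raises(ValueError, match="gene span"):
            small_config(causal_site=("1", 7))  # far from any gene span


class TestCohort:
    def test_deterministic_survival_partitions_genotypes(self):
        """With survival RR=RS=1, SS=0 every survivor carries the resistant
        allele and every knocked-down individual is SS."""
        cfg = small_config(
            survival_probs={"RR": 1.0, "RS": 1.0, "SS": 0.0}, recovered_fraction=0.1
        )
        cohort = simulate_cohort(cfg)
        causal_idx = int(np.nonzero(cohort.sites.causal.values)[0][0])
        r = cohort.alt_haplotypes[:, causal_idx].reshape(-1, 2).sum(axis=1)
        assert (r[cohort.phenotype == "resistant"] >= 1).all()
        assert (r[cohort.phenotype == "susceptible"] == 0).all()

    def test_recovered_fraction_excluded_and_near_nominal(self):
        cfg = small_config(n_individuals_exposed=2000)
        cohort = simulate_cohort(cfg)
        frac = (cohort.phenotype == "recovered").mean()
        assert frac == pytest.approx(0.24, abs=0.04)

    def test_survivor_frequency_exceeds_knockdown_at_causal(self):
        """Monte-Carlo check of the survival model: across seeds the
        survivor resistant-allele frequency always exceeds the knocked-down
        frequency at the causal site."""
        for seed in range(25):
            cohort = simulate_cohort(small_config(seed=seed))
            t = cohort.truth.table
            row = t[t.causal].iloc[0]
            assert row.freq_resistant > row.freq_susceptible

    def test_null_survival_gives_no_systematic_divergence(self):
        diffs = []
        for seed in range(20):
            cfg = small_config(seed=seed, survival_probs={"RR": 0.4, "RS": 0.4, "SS": 0.4})
            t = simulate_cohort(cfg).truth.table
            row = t[t.causal].iloc[0]
            diffs.append(row.freq_resistant - row.freq_susceptible)
        # genetic sampling only: mean near zero, spread ~ p(1-p)/class size
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.01

    def test_divergence_decays_with_distance(self):
        """Group allele-frequency divergence is largest at the causal site,
        intermediate in the linked block and smallest at unlinked sites, in
        expectation over seeds."""
        near, far, unlinked = [], [], []
        for seed in range(40):
            cfg = small_config(seed=seed)
            t = simulate_cohort(cfg).truth.table
            poly = t[(t.pop_freq > 0) & ~t.causal]
            d = poly.dist_to_causal.values
            div = np.abs(poly.freq_resistant.values - poly.freq_susceptible.values)
            L = cfg.linked_block_size
            near.extend(div[(d >= 0) & (d < 0.3 * L)])
            far.extend(div[(d >= 0.3 * L) & (d <= L)])
            unlinked.extend(div[(d > L) | (d < 0)])
        assert np.mean(near) > np.mean(far) > np.mean(unlinked)

    def test_exactly_one_causal_site(self):
        t = simulate_cohort(small_config()).truth.table
        assert int(t.causal.sum()) == 1


class TestPoolsAndSequencing:
    def test_insufficient_class_error_names_the_class(self):
        cfg = small_config(survival_probs={"RR": 0.0, "RS": 0.0, "SS": 0.0})
        cohort = simulate_cohort(cfg)
        with pytest.raises(ValueError, match="resistant"):
            assign_pools(cohort)

    def test_pools_disjoint_within_group(self):
        exp = simulate_experiment(small_config())
        res = set(exp.pools["res_1"]) | set(exp.pools["res_2"])
        assert len(res) == 2 * exp.cohort.config.pool_size

    def test_shared_replicates_reuse_individuals(self):
        exp = simulate_experiment(small_config(), shared_replicates=True)
        assert np.array_equal(exp.pools["res_1"], exp.pools["res_2"])

    def test_counts_sum_to_depth_and_conserve_reads(self):
        cfg = small_config(error_rate=0.01, depth_mean=50.0, depth_dispersion=None)
        exp = simulate_experiment(cfg)
        depths = exp.table.depths()
        assert (depths == 50).all()  # constant depth model, miscalls conserve reads

    def test_error_free_monomorphic_site_is_pure_reference(self):
        cfg = small_config(error_rate=0.0, depth_mean=100.0, depth_dispersion=None)
        exp = simulate_experiment(cfg)
        sites = exp.cohort.sites
        mono = np.nonzero((sites.pop_freq.values == 0))[0]
        i = mono[0]
        ref_i = "ACGT".index(sites.ref.values[i])
        for j in range(4):
            c = exp.table.counts[i, j]
            assert c[ref_i] == 100 and c.sum() == 100

    def test_constant_depth_24_fails_depth_filter_everywhere(self):
        cfg = small_config(depth_mean=24.0, depth_dispersion=None)
        exp = simulate_experiment(cfg)
        kept, report = select_common_polymorphic_sites(exp.table, FilterConfig())
        assert len(kept) == 0
        assert report.depth_pass["resistant"] == 0

    def test_identical_seed_bit_identical_outputs(self):
        a = simulate_experiment(small_config(seed=12))
        b = simulate_experiment(small_config(seed=12))
        assert np.array_equal(a.table.counts, b.table.counts)
        assert a.truth.table.equals(b.truth.table)
        c = simulate_experiment(small_config(seed=13))
        assert not np.array_equal(a.table.counts, c.table.counts)

    def test_truth_tsv_round_trip(self, tmp_path):
        import pandas as pd

        exp = simulate_experiment(small_config())
        path = tmp_path / "truth.tsv"
        exp.truth.to_tsv(path)
        back = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        assert len(back) == len(exp.truth.table)
        assert int(back.causal.sum()) == 1
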