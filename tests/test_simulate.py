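import numpy as np
import pandas as pd
import pytest

from phylopop.simulate import (
    CorruptionSpec,
    DemographicModel,
    Pulse,
    Split,
    corrupt_for_qc,
    inject_clones_and_selfs,
    simulate_cp_pileup,
    simulate_coalescent,
    simulate_pav,
    two_population_model,
)
from phylopop.types import MISSING, ConfigurationError


def per_locus_pi(dataset):
    """Per-locus pairwise diversity per bp (independent of popstats)."""
    table = dataset.genotypes
    n_loci, locus_length = len(set(table.sites["chrom"])), None
    g = table.genotypes
    n = g.shape[1] * 2
    alt = (g > 0).sum(axis=(1, 2)).astype(float)
    pi_site = 2 * alt * (n - alt) / (n * (n - 1))
    out = pd.Series(pi_site, index=table.sites["chrom"].values).groupby(level=0).sum()
    return out


class TestModelValidation:
    def test_bad_split_topology(self):
        with pytest.raises(ConfigurationError):
            DemographicModel(
                populations={"A": 100, "B": 100},
                splits=[Split("A", "C", 100.0)],
            )

    def test_splits_must_merge_everything(self):
        with pytest.raises(ConfigurationError):
            DemographicModel(
                populations={"A": 100, "B": 100, "C": 100},
                splits=[Split("A", "B", 100.0)],
            )

    def test_child_cannot_split_twice(self):
        with pytest.raises(ConfigurationError):
            DemographicModel(
                populations={"A": 100, "B": 100, "C": 100},
                splits=[Split("A", "B", 100.0), Split("A", "C", 200.0)],
            )

    def test_admixture_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            DemographicModel(
                populations={"A": 100},
                admixture_pulses=[Pulse("A", "A", 10.0, 1.5)],
            )

    def test_negative_mutation_rate(self):
        with pytest.raises(ConfigurationError):
            DemographicModel(populations={"A": 100}, mutation_rate=-1e-9)

    def test_unmergeable_lineages_raise_at_simulation(self):
        model = DemographicModel(populations={"A": 100, "B": 100})
        with pytest.raises(ConfigurationError):
            simulate_coalescent(model, {"A": 2, "B": 2}, seed=0)


class TestCoalescent:
    def test_zero_mutation_rate_no_variants(self):
        model = DemographicModel(
            populations={"A": 1000}, mutation_rate=0.0, locus_spec=(20, 500)
        )
        ds = simulate_coalescent(model, {"A": 4}, seed=1)
        assert ds.genotypes.n_sites == 0

    def test_determinism(self):
        model = two_population_model(5000, 8000, n_loci=30, locus_length=1000)
        a = simulate_coalescent(model, {"A": 3, "B": 3}, seed=7)
        b = simulate_coalescent(model, {"A": 3, "B": 3}, seed=7)
        assert a.genotypes.sites.equals(b.genotypes.sites)
        assert (a.genotypes.genotypes == b.genotypes.genotypes).all()
        c = simulate_coalescent(model, {"A": 3, "B": 3}, seed=8)
        assert not c.genotypes.sites.equals(a.genotypes.sites)

    def test_positions_increasing_within_chrom(self, two_pop_dataset):
        s = two_pop_dataset.genotypes.sites
        for _, grp in s.groupby("chrom"):
            assert (np.diff(grp["pos"].to_numpy()) > 0).all()

    def test_truth_labels_complete(self, two_pop_dataset):
        t = two_pop_dataset.truth
        assert set(t.samples) == set(two_pop_dataset.genotypes.samples)
        assert {v.population for v in t.samples.values()} == {"A", "B"}

    def test_expected_diversity_matches_theta(self):
        # E[pi] = 4 Ne mu per site for a panmictic population
        ne, mu = 10000, 1e-8
        model = DemographicModel(
            populations={"A": ne}, mutation_rate=mu, locus_spec=(10000, 1000)
        )
        ds = simulate_coalescent(model, {"A": 2}, seed=11)
        pi = per_locus_pi(ds)
        full = pi.reindex(
            [f"locus_{i + 1:05d}" for i in range(10000)], fill_value=0.0
        ) / 1000.0
        theta = 4 * ne * mu
        se = full.std(ddof=1) / np.sqrt(len(full))
        assert abs(full.mean() - theta) < 3 * se

    def test_expected_divergence_isolation_model(self):
        # E[d_xy] = 2 mu (T + 2 Ne) for one haploid lineage per population
        ne, mu, T = 5000, 1e-8, 20000
        model = two_population_model(ne, T, mutation_rate=mu,
                                     n_loci=10000, locus_length=1000)
        ds = simulate_coalescent(model, {"A": 1, "B": 1}, seed=13)
        g = ds.genotypes.genotypes
        # one diploid per pop = two haploid lineages; use haploid 0 of each
        ga = g[:, 0, 0]
        gb = g[:, 1, 0]
        diff = (ga != gb).astype(float)
        per_locus = (
            pd.Series(diff, index=ds.genotypes.sites["chrom"].values)
            .groupby(level=0)
            .sum()
            .reindex([f"locus_{i + 1:05d}" for i in range(10000)], fill_value=0.0)
            / 1000.0
        )
        expected = 2 * mu * (T + 2 * ne)
        se = per_locus.std(ddof=1) / np.sqrt(len(per_locus))
        assert abs(per_locus.mean() - expected) < 3 * se

    def test_msprime_cross_check(self):
        # same isolation model through an established simulator
        msprime = pytest.importorskip("msprime")
        ne, mu, n_loci, L = 8000, 1e-8, 4000, 1000
        model = DemographicModel(
            populations={"A": ne}, mutation_rate=mu, locus_spec=(n_loci, L)
        )
        ds = simulate_coalescent(model, {"A": 2}, seed=17)
        ours = per_locus_pi(ds).reindex(
            [f"locus_{i + 1:05d}" for i in range(n_loci)], fill_value=0.0
        ) / L
        ref = []
        for i, ts in enumerate(
            msprime.sim_ancestry(
                samples=2, population_size=ne, sequence_length=L,
                num_replicates=n_loci, random_seed=17,
            )
        ):
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=i + 1)
            ref.append(mts.diversity(mode="site"))
        ref = np.array(ref)
        se = np.sqrt(ours.var(ddof=1) / len(ours) + ref.var(ddof=1) / len(ref))
        assert abs(ours.mean() - ref.mean()) < 3 * se


class TestClonesAndSelfs:
    def test_error_free_clone_is_identical(self, two_pop_dataset):
        inj = inject_clones_and_selfs(two_pop_dataset, 1, 0, 0.0, seed=3)
        clone = [s for s in inj.genotypes.samples if "_clone" in s][0]
        src = clone.rsplit("_clone", 1)[0]
        gi = inj.genotypes.genotypes[:, inj.genotypes.sample_index(src)]
        gj = inj.genotypes.genotypes[:, inj.genotypes.sample_index(clone)]
        assert (gi == gj).all()

    def test_selfed_offspring_het_subset_of_parent(self, two_pop_dataset):
        inj = inject_clones_and_selfs(two_pop_dataset, 0, 1, 0.0, seed=4)
        child = [s for s in inj.genotypes.samples if "_self" in s][0]
        parent = inj.truth.samples[child].selfed_from
        het = inj.genotypes.het_mask()
        hc = het[:, inj.genotypes.sample_index(child)]
        hp = het[:, inj.genotypes.sample_index(parent)]
        assert (~hc | hp).all()  # child het only where parent het

    def test_error_rate_validation(self, two_pop_dataset):
        with pytest.raises(ConfigurationError):
            inject_clones_and_selfs(two_pop_dataset, 1, 0, 1.5, seed=0)

    def test_truth_groups_disjoint(self, two_pop_dataset):
        inj = inject_clones_and_selfs(two_pop_dataset, 3, 2, 0.0, seed=5)
        groups = inj.truth.clone_groups()
        seen = set()
        for members in groups.values():
            assert not (set(members) & seen)
            seen |= set(members)

    def test_study_ledger_composition(self):
        # 190 samples: 163 originals + 17 clone copies + 10 selfed
        model = two_population_model(8000, 10000, n_loci=30, locus_length=1000)
        base = simulate_coalescent(model, {"A": 82, "B": 81}, seed=6)
        inj = inject_clones_and_selfs(base, 17, 10, 0.0, seed=6)
        assert inj.genotypes.n_samples == 190
        assert len([s for s in inj.truth.samples.values() if s.selfed_from]) == 10
        copies = [s for s in inj.genotypes.samples if "_clone" in s]
        assert len(copies) == 17


class TestCorruption:
    def test_zero_spec_is_identity(self, two_pop_dataset):
        out = corrupt_for_qc(two_pop_dataset, CorruptionSpec(), seed=1)
        assert out.genotypes.sites.equals(two_pop_dataset.genotypes.sites)
        assert (out.genotypes.genotypes == two_pop_dataset.genotypes.genotypes).all()

    def test_exact_mq_failures(self, two_pop_dataset):
        out = corrupt_for_qc(two_pop_dataset, CorruptionSpec(n_mq=4), seed=2)
        tags = out.genotypes.sites["fail_tag"]
        assert (tags == "mq").sum() == 4
        assert (out.genotypes.sites.loc[tags == "mq", "MQ"] < 40.0).all()

    def test_exact_high_missing_count(self, two_pop_dataset):
        spec = CorruptionSpec(n_high_missing_samples=3, missing_rate=0.3)
        out = corrupt_for_qc(two_pop_dataset, spec, seed=3)
        assert len(out.truth.high_missing_samples) == 3
        miss = out.genotypes.missing_mask().mean(axis=0)
        rates = dict(zip(out.genotypes.samples, miss))
        for s in out.truth.high_missing_samples:
            assert rates[s] > 0.15

    def test_invalid_missing_rate(self, two_pop_dataset):
        with pytest.raises(ConfigurationError):
            corrupt_for_qc(
                two_pop_dataset, CorruptionSpec(missing_rate=1.2,
                                                n_high_missing_samples=1), seed=0
            )

    def test_indels_inserted_within_window(self, two_pop_dataset):
        out = corrupt_for_qc(two_pop_dataset, CorruptionSpec(n_near_indel=2), seed=4)
        s = out.genotypes.sites
        snps = s[s["fail_tag"] == "near_indel"]
        indels = s[s["vartype"] == "indel"]
        assert len(snps) == 2 and len(indels) == 2
        for _, snp in snps.iterrows():
            d = (indels["chrom"] == snp["chrom"]) & (
                (indels["pos"] - snp["pos"]).abs() <= 20
            )
            assert d.any()


class TestCpPileup:
    def test_zero_variable_single_haplotype(self):
        pileups, truth = simulate_cp_pileup(6, 5000, 0, 0, 0, 100, seed=1)
        assert truth.variable_positions == []
        assert len(set(truth.haplotypes.values())) == 1

    def test_artifact_counts_and_masks(self):
        pileups, truth = simulate_cp_pileup(8, 20000, 30, 4, 5, 150, seed=2)
        assert len(truth.variable_positions) == 30
        assert len(truth.microsat_positions) == 4
        assert len(truth.hairpin_positions) == 5
        assert len(truth.retained_positions) == 21
        assert len(truth.masks) == 9

    def test_artifacts_must_fit(self):
        with pytest.raises(ConfigurationError):
            simulate_cp_pileup(4, 1000, 3, 2, 2, 100, seed=0)

    def test_counts_bounded_by_coverage(self):
        pileups, _ = simulate_cp_pileup(3, 2000, 10, 1, 1, 80, seed=3)
        for p in pileups.values():
            assert (p.counts.sum(axis=1) <= p.coverage).all()


class TestPav:
    def test_all_core_fraction(self):
        hits, truth, classes, _ = simulate_pav(50, (0, 0, 1.0), 10, seed=1)
        assert (classes == "core").all()
        assert truth.to_numpy().mean() > 0.9

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            simulate_pav(10, (0.5, 0.2, 0.2), 5, seed=0)

    def test_low_quality_sample_engineered(self):
        hits, truth, classes, low_q = simulate_pav(
            200, (0.1, 0.2, 0.7), 20, seed=2, low_quality_samples=1
        )
        assert len(low_q) == 1
        counts = truth.sum(axis=0)
        others = counts.drop(low_q[0])
        assert counts[low_q[0]] < others.min()
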