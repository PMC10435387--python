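import itertools

import numpy as np
import pandas as pd
import pytest

from phylopop import popstats
from phylopop.simulate import (
    DemographicModel,
    Pulse,
    Split,
    simulate_coalescent,
)
from phylopop.types import MISSING

from conftest import make_table


def brute_force_pi(alleles):
    """Average pairwise difference over all allele pairs at one site."""
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def brute_force_wc(genotype_lists):
    """Independent scalar implementation of the 1984 variance components.

    ``genotype_lists``: per site, list of per-population lists of diploid
    genotypes as (a, b) tuples.  Returns theta as ratio of sums.
    """
    A = B = C = 0.0
    for pops in genotype_lists:
        r = len(pops)
        n = [len(p) for p in pops]
        nbar = sum(n) / r
        nsum = sum(n)
        nc = (nsum - sum(x * x for x in n) / nsum) / (r - 1)
        p = [sum(a + b for a, b in pop) / (2 * len(pop)) for pop in pops]
        h = [sum(1 for a, b in pop if a != b) / len(pop) for pop in pops]
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / nsum
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / nsum
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A / (A + B + C)


class TestDiversity:
    def test_monomorphic_zero(self):
        t = make_table([[[0, 0], [0, 0]]] * 3)
        pi = popstats.nucleotide_diversity(t, t.samples)
        assert (pi == 0).all()

    def test_single_site_enumeration(self):
        # two diploids both 0/1: alleles {0,1,0,1} -> brute force 4/6
        t = make_table([[[0, 1], [0, 1]]])
        pi = popstats.nucleotide_diversity(t, t.samples)
        assert pi.iloc[0] == pytest.approx(brute_force_pi([0, 1, 0, 1]))
        assert pi.iloc[0] == pytest.approx(2 / 3)

    def test_matches_brute_force_random_sites(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 2, size=(20, 5, 2))
        t = make_table(g.tolist())
        pi = popstats.nucleotide_diversity(t, t.samples, per_chromosome=False)
        expected = np.mean(
            [brute_force_pi(list(g[i].ravel())) for i in range(20)]
        )
        assert pi.iloc[0] == pytest.approx(expected)

    def test_missing_call_raises(self):
        t = make_table([[[0, 1], [0, 1]]])
        t.genotypes[0, 0] = MISSING
        with pytest.raises(ValueError, match="missing"):
            popstats.nucleotide_diversity(t, t.samples)

    def test_coalescent_expectation(self):
        ne, mu = 10000, 1e-8
        model = DemographicModel(
            populations={"A": ne}, mutation_rate=mu, locus_spec=(10000, 1000)
        )
        ds = simulate_coalescent(model, {"A": 5}, seed=3)
        t = ds.genotypes
        pi = popstats.nucleotide_diversity(
            t, t.samples, seq_length=t.seq_length
        ).iloc[0]
        # per-locus totals for an honest SE
        g = t.genotypes
        n = g.shape[1] * 2
        alt = (g > 0).sum(axis=(1, 2)).astype(float)
        pi_site = 2 * alt * (n - alt) / (n * (n - 1))
        totals = (
            pd.Series(pi_site, index=t.sites["chrom"].values)
            .groupby(level=0)
            .sum()
            .reindex([f"locus_{i + 1:05d}" for i in range(10000)], fill_value=0.0)
            / 1000.0
        )
        theta = 4 * ne * mu
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(pi - theta) < 3 * se

    def test_order_invariance(self, two_pop_dataset):
        t = two_pop_dataset.genotypes
        complete = t.subset_sites(~t.missing_mask().any(axis=1))
        a = popstats.nucleotide_diversity(complete, complete.samples)
        b = popstats.nucleotide_diversity(complete, complete.samples[::-1])
        pd.testing.assert_series_equal(a, b)


class TestHeterozygosity:
    def test_all_homozygous_zero(self):
        t = make_table([[[0, 0], [1, 1]]] * 4)
        assert popstats.individual_heterozygosity(t, "s0") == 0.0

    def test_three_of_ten(self):
        g = [[[0, 1]]] * 3 + [[[0, 0]]] * 7
        t = make_table(g)
        assert popstats.individual_heterozygosity(t, "s0") == pytest.approx(0.3)

    def test_missing_excluded_from_denominator(self):
        g = [[[0, 1]]] * 2 + [[[0, 0]]] * 2
        t = make_table(g)
        t.genotypes[3, 0] = MISSING
        assert popstats.individual_heterozygosity(t, "s0") == pytest.approx(2 / 3)

    def test_zero_called_raises(self):
        t = make_table([[[0, 1]]])
        t.genotypes[0, 0] = MISSING
        with pytest.raises(ValueError, match="zero called"):
            popstats.individual_heterozygosity(t, "s0")

    def test_hwe_expectation(self):
        model = DemographicModel(
            populations={"A": 10000}, mutation_rate=1e-8, locus_spec=(2000, 1000)
        )
        ds = simulate_coalescent(model, {"A": 10}, seed=5)
        t = ds.genotypes
        hobs = np.mean([popstats.individual_heterozygosity(t, s) for s in t.samples])
        p = t.allele_frequencies()
        expected = np.mean(2 * p * (1 - p))
        # random-mating pairing of lineages: H_obs ~ site-mean 2pq
        assert abs(hobs - expected) / expected < 0.1


class TestFst:
    def test_complete_fixation_theta_one(self):
        g = [[[0, 0], [0, 0], [1, 1], [1, 1]]] * 6
        t = make_table(g)
        res = popstats.pairwise_fst(t, ["s0", "s1"], ["s2", "s3"], n_boot=50, seed=0)
        assert res.theta == pytest.approx(1.0)

    def test_single_individual_population_raises(self):
        t = make_table([[[0, 1], [0, 1], [0, 1]]] * 3)
        with pytest.raises(ValueError, match=">= 2"):
            popstats.pairwise_fst(t, ["s0"], ["s1", "s2"])

    def test_matches_brute_force_oracle(self):
        # explicit 2 pops x 3 diploids x 2 loci worked instance
        site1 = [[0, 1], [0, 0], [1, 1], [0, 1], [1, 1], [1, 1]]
        site2 = [[0, 0], [0, 1], [0, 0], [1, 1], [0, 1], [1, 1]]
        t = make_table([site1, site2])
        a = ["s0", "s1", "s2"]
        b = ["s3", "s4", "s5"]
        res = popstats.pairwise_fst(t, a, b, n_boot=10, seed=0)
        oracle = brute_force_wc(
            [
                [[tuple(x) for x in site1[:3]], [tuple(x) for x in site1[3:]]],
                [[tuple(x) for x in site2[:3]], [tuple(x) for x in site2[3:]]],
            ]
        )
        assert res.theta == pytest.approx(oracle, abs=1e-12)

    def test_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            g = rng.integers(0, 2, size=(8, 7, 2))
            t = make_table(g.tolist())
            a = [f"s{i}" for i in range(3)]
            b = [f"s{i}" for i in range(3, 7)]
            res = popstats.pairwise_fst(t, a, b, n_boot=5, seed=0)
            sites = []
            for i in range(8):
                sites.append(
                    [
                        [tuple(g[i, j]) for j in range(3)],
                        [tuple(g[i, j]) for j in range(3, 7)],
                    ]
                )
            assert res.theta == pytest.approx(brute_force_wc(sites), abs=1e-12)

    def test_panmictic_null(self):
        # both "populations" from one pool: theta near 0, p > 0.05 mostly
        model = DemographicModel(
            populations={"A": 10000}, mutation_rate=1e-8, locus_spec=(150, 1000)
        )
        ok = 0
        reps = 20
        for seed in range(reps):
            ds = simulate_coalescent(model, {"A": 8}, seed=100 + seed)
            t = ds.genotypes
            res = popstats.pairwise_fst(
                t, t.samples[:4], t.samples[4:], n_boot=200, seed=seed
            )
            if res.p_value > 0.05:
                ok += 1
        assert ok >= 17  # ~0.95 expected; binomial slack

    def test_matrix_symmetry(self, two_pop_dataset):
        t = two_pop_dataset.genotypes
        pops = {
            "A": [s for s in t.samples if s.startswith("A")],
            "B": [s for s in t.samples if s.startswith("B")],
        }
        theta, pval = popstats.fst_matrix(t, pops, n_boot=50, seed=0)
        assert theta.equals(theta.T)
        assert theta.loc["A", "B"] > 0


def _d_freqs(rows):
    return pd.DataFrame(rows, columns=["P1", "P2", "P3", "O"])


class TestPattersonD:
    def test_abba_baba_hand_count(self):
        # ABBA x3, BABA x1 -> D = (3-1)/(3+1) = 0.5
        rows = [[0, 1, 1, 0]] * 3 + [[1, 0, 1, 0]]
        res = popstats.patterson_d(_d_freqs(rows), "P1", "P2", "P3", "O", blocks=2)
        assert res.d == pytest.approx(0.5)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        rows = rng.random((100, 4))
        f = _d_freqs(rows)
        a = popstats.patterson_d(f, "P1", "P2", "P3", "O")
        b = popstats.patterson_d(f, "P2", "P1", "P3", "O")
        assert a.d == pytest.approx(-b.d)

    def test_zero_denominator_raises(self):
        rows = [[0, 0, 0, 0]] * 5
        with pytest.raises(ValueError, match="denominator 0"):
            popstats.patterson_d(_d_freqs(rows), "P1", "P2", "P3", "O")

    def test_null_calibration(self):
        # symmetric topology, no admixture: ~5% rejection at alpha=0.05
        def null_model():
            return DemographicModel(
                populations={"P1": 10000, "P2": 10000, "P3": 10000, "O": 10000},
                splits=[
                    Split("P1", "P2", 2000, parent="a12"),
                    Split("a12", "P3", 4000, parent="a123"),
                    Split("a123", "O", 8000, parent="root"),
                ],
                mutation_rate=1e-8,
                locus_spec=(200, 1000),
            )

        reps, rej = 200, 0
        for seed in range(reps):
            ds = simulate_coalescent(
                null_model(), {"P1": 4, "P2": 4, "P3": 4, "O": 4}, seed=40000 + seed
            )
            t = ds.genotypes
            pm = {
                p: [s for s in t.samples if s.startswith(p + "_")]
                for p in ["P1", "P2", "P3", "O"]
            }
            f = popstats.population_frequencies(t, pm)
            res = popstats.patterson_d(f, "P1", "P2", "P3", "O")
            if res.p_value < 0.05:
                rej += 1
        # binomial(200, 0.05): 3 sigma ~ [0.005, 0.10]
        assert 1 <= rej <= 20

    def test_admixture_power_and_monotonicity(self):
        def model(frac):
            return DemographicModel(
                populations={"P1": 10000, "P2": 10000, "P3": 10000, "O": 10000},
                splits=[
                    Split("P1", "P2", 4000, parent="a12"),
                    Split("a12", "P3", 8000, parent="a123"),
                    Split("a123", "O", 16000, parent="root"),
                ],
                admixture_pulses=[Pulse("P3", "P2", 1000, frac)] if frac else [],
                mutation_rate=1e-8,
                locus_spec=(700, 1000),
            )

        mean_d = {}
        for frac in (0.0, 0.15, 0.4):
            ds_list = [
                simulate_coalescent(
                    model(frac), {"P1": 5, "P2": 5, "P3": 5, "O": 4}, seed=900 + s
                )
                for s in range(4)
            ]
            vals = []
            for ds in ds_list:
                t = ds.genotypes
                pm = {
                    p: [s for s in t.samples if s.startswith(p + "_")]
                    for p in ["P1", "P2", "P3", "O"]
                }
                f = popstats.population_frequencies(t, pm)
                vals.append(popstats.patterson_d(f, "P1", "P2", "P3", "O").d)
            mean_d[frac] = np.mean(vals)
        assert mean_d[0.4] > mean_d[0.15] > mean_d[0.0] - 0.02
        assert mean_d[0.4] > 0.1


class TestHeatmap:
    def _mk(self, p1, d, p):
        return popstats.TrioDResult(
            p1=p1, p2="X", p3="Y", outgroup="O", d=d, se=0.1,
            z=d / 0.1, p_value=p, n_blocks=20, n_sites=100,
        )

    def test_single_candidate(self):
        r = self._mk("A", 0.2, 0.3)
        out = popstats.d_heatmap_summarize([r])
        assert out.iloc[0]["P1"] == "A"
        assert out.iloc[0]["D"] == pytest.approx(0.2)

    def test_most_significant_wins(self):
        out = popstats.d_heatmap_summarize(
            [self._mk("A", 0.1, 0.20), self._mk("B", 0.5, 0.001)]
        )
        assert out.iloc[0]["P1"] == "B"
        assert out.iloc[0]["D"] == pytest.approx(0.5)

    def test_admixture_detected_in_heatmap(self):
        model = DemographicModel(
            populations={"P1": 10000, "P2": 10000, "P3": 10000, "O": 10000},
            splits=[
                Split("P1", "P2", 4000, parent="a12"),
                Split("a12", "P3", 8000, parent="a123"),
                Split("a123", "O", 16000, parent="root"),
            ],
            admixture_pulses=[Pulse("P3", "P2", 1000, 0.35)],
            mutation_rate=1e-8,
            locus_spec=(1500, 1000),
        )
        ds = simulate_coalescent(model, {"P1": 6, "P2": 6, "P3": 6, "O": 4}, seed=77)
        t = ds.genotypes
        pm = {
            p: [s for s in t.samples if s.startswith(p + "_")]
            for p in ["P1", "P2", "P3", "O"]
        }
        trios = popstats.patterson_d_table(t, pm, outgroup="O")
        heat = popstats.d_heatmap_summarize(trios)
        cell = heat[(heat["P2"] == "P2") & (heat["P3"] == "P3")].iloc[0]
        assert abs(cell["Z"]) > 3
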