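"""Diversity and divergence statistics."""

import math

import numpy as np
import pytest

from lactopop import popgen, simdata
from lactopop.formats import MISSING, SequenceSet, VariantTable
from lactopop.popgen import (
    DistanceMatrix,
    consensus_sequences,
    diversity_summary,
    heterozygosity_fraction,
    hudson_fst,
    nucleotide_diversity,
    pairwise_divergence_matrix,
    segregating_sites,
    tajimas_d,
    watterson_theta,
)


def make_table(genotypes, het=None, pos=None, samples=None):
    g = np.asarray(genotypes, dtype=np.int16)
    n_sites, n_samples = g.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 3
    names = samples or [f"s{i}" for i in range(n_samples)]
    return VariantTable(
        sample_names=names,
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=[("T", "G")] * n_sites,
        genotypes=g,
        het_flags=None if het is None else np.asarray(het, dtype=bool),
    )


class TestSegregatingSites:
    def test_monomorphic_is_zero(self):
        t = make_table([[0, 0, 0], [1, 1, 1]])
        assert segregating_sites(t) == 0

    def test_counts_polymorphic_site(self):
        t = make_table([[0, 0, 1]])
        assert segregating_sites(t) == 1

    def test_subset_excludes_outside_variation(self):
        t = make_table([[0, 0, 1]])
        assert segregating_sites(t, ["s0", "s1"]) == 0

    def test_missing_not_an_allele(self):
        t = make_table([[0, 0, MISSING]])
        assert segregating_sites(t) == 0

    def test_unknown_sample_raises(self):
        t = make_table([[0, 1]])
        with pytest.raises(KeyError, match="nope"):
            segregating_sites(t, ["nope"])


class TestNucleotideDiversity:
    def test_two_strains_three_diffs(self):
        t = make_table([[0, 1]] * 3, pos=[10, 20, 30])
        assert nucleotide_diversity(t, L=100) == pytest.approx(0.03)

    def test_three_strains_single_site(self):
        t = make_table([[0, 0, 1]])
        assert nucleotide_diversity(t, L=10) == pytest.approx((2 / 3) / 10)

    def test_identical_strains_zero(self):
        t = make_table([[1, 1], [0, 0]])
        assert nucleotide_diversity(t, L=50) == 0.0

    def test_missing_site_skipped_for_pair_only(self):
        t = make_table([[0, 1, MISSING]])
        # pairs: (0,1) differ; (0,2) and (1,2) skip the site
        assert nucleotide_diversity(t, L=10) == pytest.approx((1 / 3) / 10)

    def test_needs_two_samples(self):
        t = make_table([[0]])
        with pytest.raises(ValueError, match=">= 2"):
            nucleotide_diversity(t, ["s0"], L=10)


class TestWattersonTheta:
    @pytest.mark.parametrize(
        "S,n,L,expect",
        [
            (5, 2, 100, 0.05),
            (10, 5, 1000, 10 / ((1 + 1 / 2 + 1 / 3 + 1 / 4) * 1000)),
            (0, 7, 100, 0.0),
        ],
    )
    def test_closed_form(self, S, n, L, expect):
        assert watterson_theta(S, n, L) == pytest.approx(expect, rel=1e-6)

    def test_invalid_L(self):
        with pytest.raises(ValueError):
            watterson_theta(1, 5, 0)


class TestTajimasD:
    def test_zero_numerator_gives_zero(self):
        # n=2: pi*L = S/a_1 = S always, so D = 0
        t = make_table([[0, 1]] * 4)
        with pytest.warns(UserWarning, match="unstable"):
            assert tajimas_d(t, L=100) == pytest.approx(0.0)

    def test_no_segregating_sites_is_nan(self):
        t = make_table([[0, 0], [1, 1]])
        with pytest.warns(UserWarning, match="unstable"):
            assert math.isnan(tajimas_d(t, L=100))

    def test_small_n_warns(self):
        t = make_table([[0, 1, 1]])
        with pytest.warns(UserWarning, match="unstable"):
            tajimas_d(t, L=100)

    def test_matches_direct_formula_on_haplotypes(self):
        import itertools

        s = simdata.simulate_coalescent(12, 0.01, 5000, seed=99)
        t = s.to_variant_table()
        d = tajimas_d(t, L=5000)
        # independent oracle: direct formula from S and mean pairwise diffs
        n = 12
        S = s.S
        diffs = [
            np.sum(a != b)
            for a, b in itertools.combinations(s.haplotypes, 2)
        ]
        pi_total = np.mean(diffs)
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expect = (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert d == pytest.approx(expect, rel=1e-10)


class TestEstimatorRecovery:
    def test_recovery_on_own_coalescent(self):
        pis, thetas = [], []
        for rep in range(200):
            s = simdata.simulate_coalescent(20, 0.01, 10_000, seed=rep)
            t = s.to_variant_table()
            pis.append(nucleotide_diversity(t, L=10_000))
            thetas.append(watterson_theta(s.S, 20, 10_000))
        assert np.mean(pis) == pytest.approx(0.01, rel=0.05)
        assert np.mean(thetas) == pytest.approx(0.01, rel=0.05)

    def test_recovery_on_msprime_data(self):
        # independent generator as the oracle for the estimators; the
        # recombination rate gives many marginal trees per replicate, so the
        # Monte-Carlo mean converges quickly
        msprime = pytest.importorskip("msprime")
        pis, thetas = [], []
        L, theta_site, n = 10_000, 0.01, 20
        for rep in range(200):
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=0.5,
                sequence_length=L, recombination_rate=0.01,
                random_seed=rep + 1,
            )
            mts = msprime.sim_mutations(
                ts, rate=theta_site, random_seed=rep + 1,
                model=msprime.BinaryMutationModel(), discrete_genome=False,
            )
            pis.append(mts.diversity(mode="site"))
            thetas.append(watterson_theta(mts.num_sites, n, L))
        assert np.mean(pis) == pytest.approx(0.01, rel=0.05)
        assert np.mean(thetas) == pytest.approx(0.01, rel=0.05)


class TestConsensusSequences:
    def setup_method(self):
        self.ref = SequenceSet({"chr1": "AAAAAAAAAA", "chr2": "CCCC"})

    def test_all_ref_reproduces_reference(self):
        t = make_table([[0, 0]], pos=[5])
        out = consensus_sequences(self.ref, t)
        assert out["s0"] == "AAAAAAAAAA" + "CCCC"

    def test_alt_substituted(self):
        t = make_table([[1, 0]], pos=[5])
        out = consensus_sequences(self.ref, t)
        assert out["s0"][4] == "T"
        assert out["s1"] == "AAAAAAAAAA" + "CCCC"

    def test_missing_becomes_n(self):
        t = make_table([[MISSING, 0]], pos=[7])
        out = consensus_sequences(self.ref, t)
        assert out["s0"][6] == "N"

    def test_ref_mismatch_names_position(self):
        t = VariantTable(
            sample_names=["s0"],
            chrom=np.array(["chr1"], dtype=object),
            pos=np.array([3]),
            ref=np.array(["G"], dtype=object),
            alt=[("T",)],
            genotypes=np.array([[1]], dtype=np.int16),
        )
        with pytest.raises(ValueError, match="chr1:3"):
            consensus_sequences(self.ref, t)

    def test_pi_equals_brute_force_over_consensus(self, rng):
        # oracle equivalence on 50 random small cohorts
        for _ in range(50):
            n, n_sites, L = 4, int(rng.integers(1, 12)), 60
            pos = np.sort(rng.choice(L, size=n_sites, replace=False)) + 1
            g = rng.integers(0, 2, size=(n_sites, n)).astype(np.int16)
            ref = SequenceSet({"chr1": "A" * L})
            t = VariantTable(
                sample_names=[f"s{i}" for i in range(n)],
                chrom=np.array(["chr1"] * n_sites, dtype=object),
                pos=pos.astype(np.int64),
                ref=np.array(["A"] * n_sites, dtype=object),
                alt=[("T",)] * n_sites,
                genotypes=g,
            )
            seqs = consensus_sequences(ref, t)
            diffs = []
            names = t.sample_names
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = seqs[names[i]], seqs[names[j]]
                    diffs.append(sum(x != y for x, y in zip(a, b)))
            brute = np.mean(diffs) / L
            assert nucleotide_diversity(t, L=L) == pytest.approx(brute, abs=1e-12)


class TestDivergenceMatrix:
    def test_three_diffs_over_genome(self):
        t = make_table([[0, 1]] * 3, pos=[10, 20, 30])
        d = pairwise_divergence_matrix(t, 100)
        assert d.values[0, 1] == pytest.approx(0.03)

    def test_symmetric_zero_diagonal(self, cohort_divergence):
        d = cohort_divergence
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        assert np.all(d.values >= 0)

    def test_missing_site_excluded_from_pair(self):
        t = make_table([[MISSING, 1], [0, 1]], pos=[10, 20])
        d = pairwise_divergence_matrix(t, 100)
        assert d.values[0, 1] == pytest.approx(0.01)

    def test_genome_shorter_than_positions_rejected(self):
        t = make_table([[0, 1]], pos=[500])
        with pytest.raises(ValueError, match="genome_length"):
            pairwise_divergence_matrix(t, 100)

    def test_phylip_round_trip(self, tmp_path):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.25], [0.25, 0.0]]))
        p = tmp_path / "d.phylip"
        d.to_phylip(p)
        back = DistanceMatrix.from_phylip(p)
        assert back.names == d.names
        assert np.allclose(back.values, d.values)


class TestHudsonFst:
    def test_fixed_difference_gives_one(self):
        t = make_table([[0, 0, 1, 1]])
        labels = {"s0": "p1", "s1": "p1", "s2": "p2", "s3": "p2"}
        assert hudson_fst(t, labels) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # pop1 {0,0,1,1}, pop2 {1,1,1,1}: Hw = (4/6 + 0)/2, Hb = 8/16
        t = make_table([[0, 0, 1, 1, 1, 1, 1, 1]])
        labels = {f"s{i}": ("p1" if i < 4 else "p2") for i in range(8)}
        assert hudson_fst(t, labels) == pytest.approx(1 - (1 / 3) / 0.5)

    def test_undifferentiated_populations_centered_at_zero(self):
        # two random halves of one panmictic sample are exchangeable, so
        # within-pair and between-pair differences have the same expectation
        vals = []
        for rep in range(300):
            s = simdata.simulate_coalescent(16, 0.01, 4000, seed=3000 + rep)
            if s.S == 0:
                continue
            t = s.to_variant_table()
            labels = {
                name: ("p1" if i % 2 == 0 else "p2")
                for i, name in enumerate(t.sample_names)
            }
            vals.append(hudson_fst(t, labels))
        assert abs(np.mean(vals)) < 0.02

    def test_panmictic_population_near_zero(self):
        vals = []
        for rep in range(200):
            s = simdata.simulate_coalescent(20, 0.005, 5000, seed=rep)
            if s.S == 0:
                continue
            t = s.to_variant_table()
            labels = {
                name: ("p1" if i < 10 else "p2")
                for i, name in enumerate(t.sample_names)
            }
            vals.append(hudson_fst(t, labels))
        assert abs(np.mean(vals)) < 0.05

    def test_monomorphic_data_is_nan(self):
        t = make_table([[0, 0, 0, 0]])
        labels = {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
        assert math.isnan(hudson_fst(t, labels))

    def test_requires_two_populations(self):
        t = make_table([[0, 1]])
        with pytest.raises(ValueError, match="2 populations"):
            hudson_fst(t, {"s0": "a", "s1": "a"})


class TestHeterozygosity:
    def test_no_het_calls(self):
        t = make_table([[0], [1]], het=[[False], [False]])
        frac, label = heterozygosity_fraction(t, "s0")
        assert frac == 0.0 and label == "homozygous-consistent"

    def test_below_one_percent_is_homozygous_consistent(self):
        n_sites = 400
        g = np.ones((n_sites, 1), dtype=np.int16)
        het = np.zeros((n_sites, 1), dtype=bool)
        het[:2, 0] = True  # 0.5%
        g[:2, 0] = MISSING  # het calls are recorded missing in haploid mode
        t = make_table(g, het=het, pos=np.arange(1, n_sites + 1))
        frac, label = heterozygosity_fraction(t, "s0")
        assert frac == pytest.approx(0.005)
        assert label == "homozygous-consistent"

    def test_five_percent_is_heterozygous(self):
        n_sites = 100
        g = np.ones((n_sites, 1), dtype=np.int16)
        het = np.zeros((n_sites, 1), dtype=bool)
        het[:5, 0] = True
        g[:5, 0] = MISSING
        t = make_table(g, het=het, pos=np.arange(1, n_sites + 1))
        frac, label = heterozygosity_fraction(t, "s0")
        assert frac == pytest.approx(0.05)
        assert label == "heterozygous"

    def test_no_called_sites_undefined(self):
        t = make_table([[MISSING]], het=[[False]])
        frac, label = heterozygosity_fraction(t, "s0")
        assert math.isnan(frac) and label == "undefined"


def test_diversity_summary_consistency(cohort):
    spec, table, _, truth = cohort
    dairy = [s for s in truth.strains if truth.dairy[s]]
    summary = diversity_summary(table, dairy, L=spec.genome_length)
    assert summary.S == segregating_sites(table, dairy)
    assert summary.pi == pytest.approx(
        nucleotide_diversity(table, dairy, L=spec.genome_length)
    )
    # the dairy clade is the low-diversity domesticated group
    assert summary.pi < 0.002
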