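"""Microsatellite statistics: diversity, F-statistics, AMOVA, distances, trees, tests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import kstest

import hybridscan as hs
from hybridscan.popgen import _wc_components_locus, g_statistic
from hybridscan.synthetic import SiteMix, StudyConfig, make_divergence_profiles


def _matrix(calls, loci=None, group="g"):
    calls = np.asarray(calls)
    inds = [f"i{k}" for k in range(calls.shape[0])]
    loci = loci or [f"L{j}" for j in range(calls.shape[1])]
    return hs.GenotypeMatrix(inds, loci, calls, {i: group for i in inds})


class TestDiversitySummary:
    def test_monomorphic_locus(self):
        g = _matrix([[[92, 92]], [[92, 92]], [[92, 92]]])
        cell = hs.diversity_summary(g).table["g"]["L0"]
        assert cell["He"] == 0.0 and cell["Ho"] == 0.0 and cell["Na"] == 1

    def test_single_heterozygote_unbiased_he(self):
        g = _matrix([[[100, 104]]])
        cell = hs.diversity_summary(g).table["g"]["L0"]
        assert cell["Ho"] == 1.0
        assert cell["He"] == pytest.approx(2.0 * (1 - 0.5))  # = 1.0 at n=1

    def test_he_matches_brute_force_tally(self):
        g = hs.sample_purebreds(hs.make_species_profiles(seed=2), "A", 50,
                                dropout_on=False, seed=5)
        summ = hs.diversity_summary(g)
        locus = g.loci[4]
        copies = g.calls[:, 4, :].ravel()
        _, counts = np.unique(copies, return_counts=True)
        p = counts / counts.sum()
        expected = (100 / 99) * (1 - (p**2).sum())
        assert summ.table["A"][locus]["He"] == pytest.approx(expected, abs=1e-12)

    def test_richness_rarefied_to_smallest_sample(self):
        # group h has fewer typed individuals; Ar for both rarefies to 2*4 copies
        calls_big = np.array([[[100 + 2 * (k % 5), 100 + 2 * ((k + 1) % 5)]]
                              for k in range(20)])
        calls_small = np.array([[[100, 102]], [[104, 104]], [[100, 100]], [[102, 106]]])
        g = hs.GenotypeMatrix(
            [f"a{k}" for k in range(20)] + [f"b{k}" for k in range(4)],
            ["L0"],
            np.concatenate([calls_big, calls_small]),
            {**{f"a{k}": "big" for k in range(20)}, **{f"b{k}": "small" for k in range(4)}},
        )
        summ = hs.diversity_summary(g)
        ar_big = summ.table["big"]["L0"]["Ar"]
        assert ar_big <= summ.table["big"]["L0"]["Na"]
        assert summ.table["small"]["L0"]["Ar"] == pytest.approx(
            summ.table["small"]["L0"]["Na"]
        )


class TestPrivateAlleles:
    def _tables(self, pa, pb):
        fa = hs.AlleleFrequencyTable("Az", {"L": pa}, {"L": 100})
        fb = hs.AlleleFrequencyTable("At", {"L": pb}, {"L": 100})
        return fa, fb

    def test_absent_from_other_species(self):
        fa, fb = self._tables({108: 0.784, 100: 0.216}, {92: 1.0})
        out = hs.private_alleles(fa, fb)
        assert ("L", 108, "Az") in out
        assert ("L", 92, "At") in out

    def test_below_one_percent_counts_as_private(self):
        fa, fb = self._tables({127: 0.4057, 129: 0.5943},
                              {127: 0.0047, 131: 0.9953})
        out = hs.private_alleles(fa, fb)
        assert ("L", 127, "Az") in out

    def test_shared_common_allele_not_private(self):
        fa, fb = self._tables({100: 0.5, 102: 0.5}, {100: 0.5, 102: 0.5})
        assert hs.private_alleles(fa, fb) == []


class TestWCFst:
    def test_no_differentiation_near_zero(self):
        prof = hs.make_species_profiles(seed=3, private_fraction=0.0,
                                        n_diagnostic=0)
        g1 = hs.sample_purebreds(prof, "A", 250, False, seed=1, prefix="x", group="p1")
        g2 = hs.sample_purebreds(prof, "A", 250, False, seed=2, prefix="y", group="p2")
        theta = hs.wc_fst(g1.concat(g2))
        assert abs(theta) < 0.01

    def test_fixed_differences_give_one(self):
        calls1 = np.tile(np.array([[[100, 100]]]), (30, 1, 1))
        calls2 = np.tile(np.array([[[120, 120]]]), (30, 1, 1))
        g = hs.GenotypeMatrix(
            [f"a{k}" for k in range(30)] + [f"b{k}" for k in range(30)],
            ["L0"],
            np.concatenate([calls1, calls2]),
            {**{f"a{k}": "p1" for k in range(30)}, **{f"b{k}": "p2" for k in range(30)}},
        )
        assert hs.wc_fst(g) == pytest.approx(1.0)

    def test_toy_counts_match_component_arithmetic(self):
        # pop1: 30 x (1,1); pop2: 15 x (1,1) + 15 x (2,2)
        calls1 = np.tile(np.array([[[1, 1]]]), (30, 1, 1))
        calls2 = np.concatenate(
            [np.tile(np.array([[[1, 1]]]), (15, 1, 1)),
             np.tile(np.array([[[2, 2]]]), (15, 1, 1))]
        )
        g = hs.GenotypeMatrix(
            [f"a{k}" for k in range(30)] + [f"b{k}" for k in range(30)],
            ["L0"],
            np.concatenate([calls1, calls2]),
            {**{f"a{k}": "p1" for k in range(30)}, **{f"b{k}": "p2" for k in range(30)}},
        )
        theta = hs.wc_fst(g)
        # independent brute-force evaluation of the variance components
        comps = _wc_components_locus(
            [g.calls[:30, 0, :], g.calls[30:, 0, :]]
        )
        num = sum(a for a, _, _ in comps)
        den = sum(a + b + c for a, b, c in comps)
        assert theta == pytest.approx(num / den, abs=1e-10)
        r, n = 2, 30.0
        nbar, nc = n, (r * n - (2 * n * n) / (r * n)) / (r - 1)
        for allele, pbar_pair in ((1, (1.0, 0.5)), (2, (0.0, 0.5))):
            p1, p2 = pbar_pair
            pbar = (p1 + p2) / 2
            s2 = ((p1 - pbar) ** 2 + (p2 - pbar) ** 2) / ((r - 1) * nbar)
            s2 *= nbar  # matches definition sum n_i (p_i - pbar)^2 / ((r-1) nbar)
            hbar = 0.0
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
            c = hbar / 2
            got = comps[allele - 1]
            assert got == pytest.approx((a, b, c), abs=1e-10)

    def test_invariant_under_allele_relabelling(self):
        prof = hs.make_species_profiles(seed=9)
        g1 = hs.sample_purebreds(prof, "A", 60, False, seed=1, prefix="x", group="p1")
        g2 = hs.sample_purebreds(prof, "B", 60, False, seed=2, prefix="y", group="p2")
        g = g1.concat(g2)
        theta = hs.wc_fst(g)
        relabelled = hs.GenotypeMatrix(
            g.individuals, g.loci, np.where(g.calls > 0, g.calls + 500, 0),
            dict(g.group_of),
        )
        assert hs.wc_fst(relabelled) == pytest.approx(theta, abs=1e-12)

    def test_monotone_in_divergence(self):
        thetas = []
        for fst in (0.05, 0.15, 0.30):
            vals = []
            for seed in range(5):
                prof = make_divergence_profiles(8, 6, fst, seed=seed + 40)
                g1 = hs.sample_purebreds(prof, "A", 80, False, seed=seed, prefix="x", group="p1")
                g2 = hs.sample_purebreds(prof, "B", 80, False, seed=seed + 99, prefix="y", group="p2")
                vals.append(hs.wc_fst(g1.concat(g2)))
            thetas.append(np.mean(vals))
        assert thetas[0] < thetas[1] < thetas[2]


class TestAmova:
    @staticmethod
    def _study(fct, fsc, seed, n=50):
        prof = make_divergence_profiles(10, 8, fct, seed=seed + 500)
        sites = [SiteMix("A1", "x", {"A": n}), SiteMix("A2", "x", {"A": n}),
                 SiteMix("B1", "y", {"B": n}), SiteMix("B2", "y", {"B": n})]
        cfg = StudyConfig(sites=sites, profile=prof, fst_within=fsc,
                          misid_base=0.0, seed=seed)
        st = hs.make_study(cfg)
        tr = st.truth
        return (st.genotypes,
                dict(zip(tr["individual"], tr["genetic_species"])),
                dict(zip(tr["individual"], tr["site"])))

    def test_identical_homozygotes_zero_components(self):
        calls = np.tile(np.array([[[100, 100], [110, 110]]]), (24, 1, 1))
        inds = [f"i{k}" for k in range(24)]
        g = hs.GenotypeMatrix(inds, ["L0", "L1"], calls,
                              {i: "g" for i in inds})
        species = {i: ("s1" if k < 12 else "s2") for k, i in enumerate(inds)}
        pops = {i: f"{species[i]}-p{k % 2}" for k, i in enumerate(inds)}
        vc = hs.amova_two_level(g, species, pops, n_perm=0)
        assert vc.sigma_among_groups == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma_among_pops == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma_within == pytest.approx(0.0, abs=1e-12)

    def test_identical_heterozygotes_no_between_variance(self):
        # identical het individuals: only within-individual allele variance remains
        calls = np.tile(np.array([[[100, 102], [110, 110]]]), (24, 1, 1))
        inds = [f"i{k}" for k in range(24)]
        g = hs.GenotypeMatrix(inds, ["L0", "L1"], calls,
                              {i: "g" for i in inds})
        species = {i: ("s1" if k < 12 else "s2") for k, i in enumerate(inds)}
        pops = {i: f"{species[i]}-p{k % 2}" for k, i in enumerate(inds)}
        vc = hs.amova_two_level(g, species, pops, n_perm=0)
        assert vc.F_CT == pytest.approx(0.0, abs=1e-12)
        assert vc.F_SC == pytest.approx(0.0, abs=1e-12)
        assert vc.F_ST == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma_within > 0

    def test_panmictic_null(self):
        # one species' data split arbitrarily: F_CT ~ 0 and p > 0.05 mostly
        near_zero, nonsig = 0, 0
        reps = 10
        for seed in range(reps):
            prof = hs.make_species_profiles(seed=77, private_fraction=0.0,
                                            n_diagnostic=0)
            g = hs.sample_purebreds(prof, "A", 200, False, seed=seed, prefix="i")
            rng = np.random.default_rng(seed)
            perm = rng.permutation(g.individuals)
            species = {ind: ("s1" if k < 100 else "s2") for k, ind in enumerate(perm)}
            pops = {ind: f"{species[ind]}-p{k % 2}" for k, ind in enumerate(perm)}
            vc = hs.amova_two_level(g, species, pops, n_perm=99, seed=seed)
            if abs(vc.F_CT) <= 0.02:
                near_zero += 1
            if vc.p_F_CT > 0.05:
                nonsig += 1
        assert near_zero >= 9
        assert nonsig >= 9

    def test_two_diagnostic_species_fct_equals_fst(self, diagnostic_profile):
        ga = hs.sample_purebreds(diagnostic_profile, "A", 60, False, 1, "a", "pa1")
        gb = hs.sample_purebreds(diagnostic_profile, "B", 60, False, 2, "b", "pb1")
        g = ga.concat(gb)
        species = {i: ("A" if i.startswith("a") else "B") for i in g.individuals}
        pops = {i: f"{species[i]}-{int(i.split('-')[1]) % 2}" for i in g.individuals}
        vc = hs.amova_two_level(g, species, pops, n_perm=0)
        assert vc.F_SC == pytest.approx(0.0, abs=0.02)
        assert vc.F_CT == pytest.approx(vc.F_ST, abs=0.02)
        assert vc.F_CT == pytest.approx(1.0, abs=0.02)

    def test_parameter_recovery(self):
        fcts, fscs = [], []
        for seed in range(10):
            g, species, pops = self._study(0.25, 0.05, seed)
            vc = hs.amova_two_level(g, species, pops, n_perm=0)
            fcts.append(vc.F_CT)
            fscs.append(vc.F_SC)
        assert np.mean(fcts) == pytest.approx(0.25, abs=0.04)
        assert np.mean(fscs) == pytest.approx(0.05, abs=0.04)

    def test_identities_hold(self):
        g, species, pops = self._study(0.2, 0.05, 3)
        vc = hs.amova_two_level(g, species, pops, n_perm=0)
        total = vc.sigma_among_groups + vc.sigma_among_pops + vc.sigma_within
        assert vc.F_CT == pytest.approx(vc.sigma_among_groups / total, abs=1e-12)
        assert vc.F_SC == pytest.approx(
            vc.sigma_among_pops / (vc.sigma_among_pops + vc.sigma_within), abs=1e-12
        )
        assert vc.F_ST == pytest.approx(
            (vc.sigma_among_groups + vc.sigma_among_pops) / total, abs=1e-12
        )
        assert vc.pct_among_groups + vc.pct_among_pops + vc.pct_within == pytest.approx(100.0)


class TestNeiDistance:
    def _table(self, group, locus_freqs):
        return hs.AlleleFrequencyTable(
            group, {l: dict(f) for l, f in locus_freqs.items()},
            {l: 10 for l in locus_freqs},
        )

    def test_identical_tables_zero(self):
        fa = self._table("A", {"L1": {1: 0.5, 2: 0.5}})
        fb = self._table("B", {"L1": {1: 0.5, 2: 0.5}})
        assert hs.nei_standard_distance(fa, fb) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_infinite(self):
        fa = self._table("A", {"L1": {1: 1.0}})
        fb = self._table("B", {"L1": {2: 1.0}})
        assert math.isinf(hs.nei_standard_distance(fa, fb))

    def test_two_locus_hand_arithmetic(self):
        # locus1 both 0.5/0.5 same alleles; locus2 fixed for different alleles
        fa = self._table("A", {"L1": {1: 0.5, 2: 0.5}, "L2": {3: 1.0}})
        fb = self._table("B", {"L1": {1: 0.5, 2: 0.5}, "L2": {4: 1.0}})
        # J_AB = 0.5 + 0; J_A = J_B = 0.5 + 1 = 1.5; I = 0.5/1.5
        expected = -math.log(0.5 / 1.5)
        assert hs.nei_standard_distance(fa, fb) == pytest.approx(expected, abs=1e-12)


class TestUpgma:
    def test_two_taxa(self):
        d = hs.GeneticDistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        tree = hs.upgma(d)
        assert tree.newick() == "(A:0.200000,B:0.200000);"

    def test_three_taxa_hand_computation(self):
        m = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = hs.upgma(hs.GeneticDistanceMatrix(["A", "B", "C"], m))
        assert tree.height == pytest.approx(0.3)
        assert {frozenset(c) for c in tree.clades()} == {
            frozenset({"A", "B"}), frozenset({"A", "B", "C"})
        }

    def test_label_order_invariant_topology(self, rng):
        labels = list("ABCDE")
        m = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        vals = rng.uniform(0.1, 1.0, size=len(iu[0]))
        m[iu] = vals
        m += m.T
        t1 = hs.upgma(hs.GeneticDistanceMatrix(labels, m))
        perm = [3, 1, 4, 0, 2]
        m2 = m[np.ix_(perm, perm)]
        t2 = hs.upgma(hs.GeneticDistanceMatrix([labels[i] for i in perm], m2))
        assert set(t1.clades()) == set(t2.clades())

    def test_ultrametric_and_matches_scipy_average_linkage(self, rng):
        labels = [f"t{k}" for k in range(6)]
        m = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        m[iu] = rng.uniform(0.1, 2.0, size=len(iu[0]))
        m += m.T
        tree = hs.upgma(hs.GeneticDistanceMatrix(labels, m))

        def tip_depths(node, acc=None):
            if not node.children:
                return [node.height]
            out = []
            for c in node.children:
                out.extend(tip_depths(c))
            return out

        root_to_tip = [tree.height - h for h in tip_depths(tree)]
        assert max(root_to_tip) - min(root_to_tip) < 1e-9
        Z = hierarchy.average(squareform(m))
        assert tree.height == pytest.approx(Z[-1, 2] / 2, abs=1e-12)

    def test_infinite_entry_instructs_capping(self):
        m = np.array([[0, np.inf], [np.inf, 0]])
        with pytest.raises(ValueError, match="cap"):
            hs.upgma(hs.GeneticDistanceMatrix(["A", "B"], m))


class TestBootstrapUpgma:
    def test_species_split_high_support(self, diagnostic_profile):
        parts = []
        for k, (sp, pop) in enumerate(
            [("A", "pa1"), ("A", "pa2"), ("B", "pb1"), ("B", "pb2")]
        ):
            parts.append(
                hs.sample_purebreds(diagnostic_profile, sp, 25, False,
                                    seed=k, prefix=pop, group=pop)
            )
        g = parts[0]
        for p in parts[1:]:
            g = g.concat(p)
        tree = hs.bootstrap_upgma(g, n_boot=100, seed=1)
        support = {node.leaves(): node.support for node in tree.internal_nodes()}
        assert support[frozenset({"pa1", "pa2"})] >= 0.99
        assert support[frozenset({"pb1", "pb2"})] >= 0.99

    def test_single_bootstrap_supports_binary(self, default_study):
        g = default_study.genotypes
        tree = hs.bootstrap_upgma(g, n_boot=1, seed=0)
        for node in tree.internal_nodes():
            assert node.support in (0.0, 1.0)

    def test_duplicated_loci_give_full_support(self):
        prof = hs.make_species_profiles(n_loci=1, seed=5, n_diagnostic=0,
                                        private_fraction=0.0)
        base = {
            grp: hs.sample_purebreds(prof, "A", 15, False, seed=s, prefix=grp, group=grp)
            for grp, s in [("g1", 1), ("g2", 2), ("g3", 3)]
        }
        g = base["g1"].concat(base["g2"]).concat(base["g3"])
        calls = np.repeat(g.calls, 20, axis=1)
        g20 = hs.GenotypeMatrix(g.individuals, [f"L{j}" for j in range(20)],
                                calls, dict(g.group_of))
        tree = hs.bootstrap_upgma(g20, n_boot=50, seed=2)
        assert all(node.support == 1.0 for node in tree.internal_nodes())


class TestHWE:
    def test_uniform_under_null(self):
        # type-I error: p-values approximately uniform under HWE
        prof = hs.make_species_profiles(n_loci=1, seed=21, n_diagnostic=0,
                                        private_fraction=0.0)
        pvals = []
        for seed in range(200):
            g = hs.sample_purebreds(prof, "A", 50, False, seed=seed, prefix="i",
                                    group="g")
            pvals.append(hs.hwe_test(g, "g", g.loci[0], n_perm=99, seed=seed))
        assert kstest(pvals, "uniform").pvalue > 0.001

    def test_extreme_heterozygote_excess_detected(self):
        calls = np.tile(np.array([[[100, 104]]]), (50, 1, 1))
        inds = [f"i{k}" for k in range(50)]
        g = hs.GenotypeMatrix(inds, ["L"], calls, {i: "g" for i in inds})
        assert hs.hwe_test(g, "g", "L", n_perm=999, seed=0) <= 0.01

    def test_monomorphic_returns_one(self):
        calls = np.tile(np.array([[[100, 100]]]), (10, 1, 1))
        inds = [f"i{k}" for k in range(10)]
        g = hs.GenotypeMatrix(inds, ["L"], calls, {i: "g" for i in inds})
        assert hs.hwe_test(g, "g", "L", n_perm=99, seed=0) == 1.0


class TestLD:
    def test_uniform_under_independence(self):
        prof = hs.make_species_profiles(n_loci=2, seed=31, n_diagnostic=0,
                                        private_fraction=0.0, alleles_per_locus=4)
        pvals = []
        for seed in range(200):
            g = hs.sample_purebreds(prof, "A", 40, False, seed=seed, prefix="i",
                                    group="g")
            pvals.append(
                hs.ld_test(g, "g", g.loci[0], g.loci[1], n_perm=99, seed=seed)
            )
        assert kstest(pvals, "uniform").pvalue > 0.001

    def test_duplicated_locus_maximal_association(self):
        prof = hs.make_species_profiles(n_loci=1, seed=41, n_diagnostic=0,
                                        private_fraction=0.0)
        g1 = hs.sample_purebreds(prof, "A", 100, False, seed=1, prefix="i", group="g")
        calls = np.concatenate([g1.calls, g1.calls], axis=1)
        g = hs.GenotypeMatrix(g1.individuals, ["La", "Lb"], calls,
                              dict(g1.group_of))
        assert hs.ld_test(g, "g", "La", "Lb", n_perm=999, seed=0) <= 0.001

    def test_zero_permutations_rejected(self, default_study):
        g = default_study.genotypes
        with pytest.raises(ValueError):
            hs.ld_test(g, g.group_of[g.individuals[0]], g.loci[0], g.loci[1],
                       n_perm=0)


class TestSequentialBonferroni:
    def test_single_test_plain_alpha(self):
        assert hs.sequential_bonferroni([0.04]) == [True]
        assert hs.sequential_bonferroni([0.06]) == [False]

    def test_holm_steps_hand_evaluation(self):
        # 0.001 <= 0.05/3, 0.02 <= 0.025, 0.03 <= 0.05 -> all rejected
        assert hs.sequential_bonferroni([0.001, 0.02, 0.03]) == [True, True, True]

    def test_stops_at_first_failure(self):
        # 0.001 <= 0.0167 yes; 0.03 > 0.025 no; 0.01 <= ... but order matters
        assert hs.sequential_bonferroni([0.03, 0.001, 0.04]) == [False, True, False]

    def test_all_ones_no_rejections(self):
        assert hs.sequential_bonferroni([1.0, 1.0, 1.0]) == [False, False, False]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            hs.sequential_bonferroni([0.5, 1.5])
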