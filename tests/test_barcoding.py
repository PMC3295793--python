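"""mtDNA haplotype and divergence statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest

import hybridscan as hs
from hybridscan.barcoding import SaturationError


def _aln(seqs: dict[str, str]) -> hs.SequenceAlignment:
    return hs.SequenceAlignment(dict(seqs))


class TestCollapseHaplotypes:
    def test_identical_sequences_merge(self):
        aln = _aln({f"s{i}": "ACGTACGT" for i in range(3)})
        tab = hs.collapse_haplotypes(aln)
        assert tab.n_haplotypes == 1
        assert tab.count["H1"] == 3

    def test_distinct_patterns_counted(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=40))
        variants = [base]
        for k in range(5):
            s = list(base)
            s[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[k]]
            variants.append("".join(s))
        # 10 sequences over 6 patterns; oracle: direct string dedup
        seqs = {f"s{i}": variants[i % 6] for i in range(10)}
        tab = hs.collapse_haplotypes(_aln(seqs))
        assert tab.n_haplotypes == len(set(seqs.values())) == 6
        assert tab.n_individuals == 10

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            hs.SequenceAlignment({})


class TestK2P:
    def test_identical_sequences(self):
        r = hs.k2p_distance("ACGT" * 25, "ACGT" * 25)
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)
        assert r.sites_compared == 100

    def test_single_transition_closed_form(self):
        s1 = "A" * 100
        s2 = "G" + "A" * 99  # A->G is a transition
        r = hs.k2p_distance(s1, s2)
        assert r.P == pytest.approx(0.01)
        assert r.d == pytest.approx(-0.5 * math.log(0.98), abs=1e-12)

    def test_two_transitions_one_transversion_closed_form(self):
        s1 = "A" * 100
        s2 = "GG" + "C" + "A" * 97  # 2 transitions (A->G), 1 transversion (A->C)
        r = hs.k2p_distance(s1, s2)
        expected = -0.5 * math.log(1 - 0.05) - 0.25 * math.log(1 - 0.02)
        assert r.d == pytest.approx(expected, abs=1e-12)

    def test_ambiguous_sites_pairwise_deleted(self):
        r = hs.k2p_distance("ACGTN-", "ACGTAC")
        assert r.sites_compared == 4

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            hs.k2p_distance("A" * 10, "G" * 10)

    def test_symmetric_and_bounded_below_by_p_distance(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = list(a)
        for k in rng.choice(200, size=12, replace=False):
            b[k] = rng.choice([x for x in "ACGT" if x != b[k]])
        b = "".join(b)
        r1, r2 = hs.k2p_distance(a, b), hs.k2p_distance(b, a)
        assert r1.d == pytest.approx(r2.d, abs=1e-15)
        p_dist = (r1.P + r1.Q)
        assert r1.d >= p_dist - 1e-12
        assert r1.d == pytest.approx(p_dist, rel=0.05)  # first-order agreement


class TestGroupDivergence:
    def test_single_group_identical(self):
        tab = hs.HaplotypeTable({"H1": "ACGT" * 10}, {"H1": 5}, {"H1": "A"})
        intra, inter = hs.group_divergence(tab, n_boot=0)
        assert intra["A"][0] == 0.0
        assert math.isnan(inter[0])

    def test_two_fixed_groups_inter_equals_d(self):
        s1 = "A" * 100
        s2 = "G" * 5 + "A" * 95
        d = hs.k2p_distance(s1, s2).d
        tab = hs.HaplotypeTable(
            {"H1": s1, "H2": s2}, {"H1": 237, "H2": 15}, {"H1": "A", "H2": "B"}
        )
        _, (inter, _) = hs.group_divergence(tab, n_boot=0)
        assert inter == pytest.approx(d, abs=1e-15)

    def test_count_weighting(self):
        # two haplotypes in one group: mean over pairs weighted by counts
        s1, s2 = "A" * 100, "G" + "A" * 99
        d = hs.k2p_distance(s1, s2).d
        tab = hs.HaplotypeTable(
            {"H1": s1, "H2": s2}, {"H1": 3, "H2": 1}, {"H1": "A", "H2": "A"}
        )
        intra, _ = hs.group_divergence(tab, n_boot=0)
        # pairs: 3 identical (d=0), 3*1 cross (d), total 6 pairs
        assert intra["A"][0] == pytest.approx(3 * d / 6, abs=1e-15)

    def test_bootstrap_se_seeded(self):
        s1, s2 = "A" * 50, "GG" + "A" * 48
        tab = hs.HaplotypeTable(
            {"H1": s1, "H2": s2}, {"H1": 10, "H2": 10}, {"H1": "A", "H2": "B"}
        )
        _, (m1, se1) = hs.group_divergence(tab, n_boot=50, seed=1)
        _, (m2, se2) = hs.group_divergence(tab, n_boot=50, seed=1)
        assert (m1, se1) == (m2, se2)
        assert se1 > 0


class TestNucleotideDiversity:
    def test_single_haplotype_zero(self):
        tab = hs.HaplotypeTable({"H1": "ACGT"}, {"H1": 10})
        assert hs.nucleotide_diversity(tab) == 0.0

    def test_two_haplotypes_closed_form(self):
        s1 = "A" * 500
        s2 = "C" + "A" * 499
        tab = hs.HaplotypeTable({"H1": s1, "H2": s2}, {"H1": 50, "H2": 50})
        expected = (100 / 99) * 2 * 0.25 * (1 / 500)
        assert hs.nucleotide_diversity(tab) == pytest.approx(expected, abs=1e-15)

    def test_requires_two_individuals(self):
        tab = hs.HaplotypeTable({"H1": "ACGT"}, {"H1": 1})
        with pytest.raises(ValueError):
            hs.nucleotide_diversity(tab)


class TestFixedDifferences:
    def test_identical_groups_zero(self):
        aln = _aln({"a": "ACGT", "b": "ACGT"})
        assert hs.fixed_differences(aln, ["a"], ["b"]) == 0

    def test_single_fixed_column(self):
        aln = _aln({"a": "ACGT", "b": "AGGT"})
        assert hs.fixed_differences(aln, ["a"], ["b"]) == 1

    def test_shared_state_not_fixed(self):
        # column 0: A={A,A}, B={T} -> fixed; column 2: A={G,A}... oracle by scan
        aln = _aln({"a1": "ACGTA", "a2": "ACGTG", "b1": "TCATA"})
        assert hs.fixed_differences(aln, ["a1", "a2"], ["b1"]) == 2

    def test_ambiguity_ignored(self):
        aln = _aln({"a": "NCGT", "b": "ACGA"})
        assert hs.fixed_differences(aln, ["a"], ["b"]) == 1


class TestHaplogroups:
    def test_all_identical_one_group(self):
        tab = hs.HaplotypeTable({"H1": "ACGT" * 25}, {"H1": 4})
        assert set(hs.assign_haplogroups(tab).values()) == {"G1"}

    def test_two_separated_clusters(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=500))
        far = list(base)
        for k in rng.choice(500, size=45, replace=False):
            far[k] = rng.choice([x for x in "ACGT" if x != far[k]])
        far = "".join(far)

        def near(s, col):
            out = list(s)
            out[col] = {"A": "G", "G": "A", "C": "T", "T": "C"}[out[col]]
            return "".join(out)

        tab = hs.HaplotypeTable(
            {"H1": base, "H2": near(base, 3), "H3": far, "H4": near(far, 7)},
            {"H1": 200, "H2": 10, "H3": 50, "H4": 5},
        )
        labels = hs.assign_haplogroups(tab, threshold=0.02)
        assert labels["H1"] == labels["H2"] == "G1"  # larger group first
        assert labels["H3"] == labels["H4"] == "G2"

    def test_threshold_above_max_distance_one_group(self):
        tab = hs.HaplotypeTable(
            {"H1": "A" * 100, "H2": "G" + "A" * 99}, {"H1": 1, "H2": 1}
        )
        assert set(hs.assign_haplogroups(tab, threshold=0.5).values()) == {"G1"}


class TestBarcodingGapOnSyntheticStudy:
    def test_inter_to_intra_ratio_exceeds_50(self, default_study):
        tr = default_study.truth
        species = dict(zip(tr["individual"], tr["genetic_species"]))
        ids = [i for i, s in species.items() if s in ("A", "B")]
        aln = default_study.alignment.subset(ids)
        tab = hs.collapse_haplotypes(aln, {i: species[i] for i in ids})
        intra, (inter, _) = hs.group_divergence(tab, n_boot=0)
        worst_intra = max(m for m, _ in intra.values())
        assert inter / max(worst_intra, 1e-9) >= 50

    def test_generated_fixed_differences_match_config(self, default_study):
        tr = default_study.truth
        a = tr[tr["genetic_species"] == "A"]["individual"].tolist()
        b = tr[tr["genetic_species"] == "B"]["individual"].tolist()
        assert hs.fixed_differences(default_study.alignment, a, b) == 38

    def test_collapse_conserves_individual_count(self, default_study):
        tab = hs.collapse_haplotypes(default_study.alignment)
        assert tab.n_individuals == len(default_study.alignment)
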