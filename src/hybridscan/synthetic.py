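"""Synthetic two-species study generator.

Builds complete, fully-labelled studies of two hybridising fish species --
multilocus microsatellite genotypes, an aligned mtDNA barcoding fragment,
per-sample metadata with field phenotype labels, and a truth table -- with
the statistical structure the downstream analysis assumes:

* two species whose microsatellite allele pools overlap only partly
  (a configurable fraction of alleles private under the <1% rule), with a
  couple of fully diagnostic loci where one species is monomorphic for an
  allele the other (almost) never carries;
* locus- and species-specific amplification failure (some markers
  amplify in only a small fraction of one species);
* regional subpopulations with low within-species F_ST, induced by
  Balding-Nichols perturbation of the species base frequencies (the
  Dirichlet concentration (1-F)/F is the standard one-parameter knob
  analytically linked to the target F_ST);
* rare F1/F2/backcross hybrids generated by explicit Hardy-Weinberg /
  linkage-equilibrium crosses from the parental pools (the HYBRIDLAB
  scheme), carrying the mtDNA of their maternal species;
* an mtDNA alignment with a configured number of fixed differences
  between the species plus low-frequency intraspecific haplotypes;
* an asymmetric, optionally size-dependent misidentification process:
  genetic species A is always field-labelled A, while genetic species B
  (and hybrids) are mislabelled A with a configurable probability.

All randomness flows from one master seed: identical config + seed gives
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    AlleleFrequencyTable,
    GenotypeMatrix,
    SampleMetadata,
    SequenceAlignment,
)
from .popgen import private_alleles

__all__ = [
    "SpeciesProfile",
    "SiteMix",
    "StudyConfig",
    "StudyResult",
    "HYBRID_CLASSES",
    "make_species_profiles",
    "make_divergence_profiles",
    "sample_purebreds",
    "sample_hybrids",
    "make_study",
    "default_study_config",
]

SPECIES = ("A", "B")
HYBRID_CLASSES = ("F1", "F2", "BCxA", "BCxB")
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# species profiles
# ---------------------------------------------------------------------------


@dataclass
class SpeciesProfile:
    """Per-locus allele frequencies for species A and B plus assay properties."""

    freqs: dict[str, dict[str, dict[int, float]]]  # species -> locus -> allele -> p
    diagnostic_loci: list[str] = field(default_factory=list)
    dropout: dict[str, dict[str, float]] = field(default_factory=dict)
    # dropout: locus -> species -> P(amplification failure)

    def __post_init__(self) -> None:
        for sp, table in self.freqs.items():
            for locus, f in table.items():
                s = sum(f.values())
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(f"{sp}/{locus}: frequencies sum to {s}")
        for locus in self.diagnostic_loci:
            a = set(self.freqs["A"][locus])
            b = set(self.freqs["B"][locus])
            if a & b:
                raise ValueError(f"diagnostic locus {locus} has shared alleles")
        for locus, d in self.dropout.items():
            for sp, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"dropout[{locus}][{sp}] = {p} outside [0, 1]")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs["A"])

    def frequency_table(self, species: str) -> AlleleFrequencyTable:
        return AlleleFrequencyTable(
            group=species,
            freqs={l: dict(f) for l, f in self.freqs[species].items()},
            n_typed={l: 0 for l in self.freqs[species]},
        )

    def dropout_of(self, locus: str, species: str) -> float:
        return self.dropout.get(locus, {}).get(species, 0.0)

    def realised_private_fraction(self, threshold: float = 0.01) -> float:
        fa = self.frequency_table("A")
        fb = self.frequency_table("B")
        priv = private_alleles(fa, fb, threshold=threshold)
        total = sum(
            len(set(self.freqs["A"][l]) | set(self.freqs["B"][l]))
            for l in self.loci
        )
        return len(priv) / total


def _floored_dirichlet(rng: np.random.Generator, m: int) -> np.ndarray:
    """Dirichlet(1) frequencies with every entry lifted above ~3%.

    The floor keeps every designed allele above the 1% private-allele
    threshold, so the realised private fraction equals the designed one.
    """
    floor = min(0.03, 0.5 / m)
    raw = rng.dirichlet(np.ones(m))
    return floor + (1.0 - m * floor) * raw


def make_species_profiles(
    n_loci: int = 13,
    alleles_per_locus: int = 10,
    private_fraction: float = 0.70,
    n_diagnostic: int = 2,
    seed: int = 0,
    dropout: Mapping[str, Mapping[str, float]] | None = None,
) -> SpeciesProfile:
    """Construct species allele-frequency profiles hitting a private-allele target.

    ``private_fraction`` is the target fraction of the pooled allele list
    (union over species, per locus) that is private under the <1% rule.
    Diagnostic loci make species B monomorphic for an allele species A
    never carries, with all of A's alleles private in return. Non-diagnostic
    loci always keep at least one shared allele, so a target of 1 with any
    non-diagnostic locus is infeasible and raises.
    """
    if n_diagnostic > n_loci:
        raise ValueError("n_diagnostic > n_loci")
    if not 0.0 <= private_fraction <= 1.0:
        raise ValueError("private_fraction outside [0, 1]")
    if private_fraction == 0.0 and n_diagnostic > 0:
        raise ValueError("diagnostic loci force private alleles; target 0 infeasible")
    m = alleles_per_locus
    if m < 2:
        raise ValueError("need >= 2 alleles per locus")
    rng = np.random.default_rng(seed)
    loci = [f"ms{i + 1:02d}" for i in range(n_loci)]
    diag = loci[:n_diagnostic]
    nondiag = loci[n_diagnostic:]

    total_alleles = n_loci * m
    needed = round(private_fraction * total_alleles)
    needed_nondiag = needed - n_diagnostic * m  # diagnostics are all-private
    max_nondiag = len(nondiag) * (m - 1)
    if needed_nondiag > max_nondiag:
        raise ValueError(
            f"private fraction {private_fraction} infeasible: non-diagnostic "
            "loci must keep at least one shared allele"
        )
    needed_nondiag = max(needed_nondiag, 0)
    # spread private counts as evenly as possible over non-diagnostic loci
    per_locus = [0] * len(nondiag)
    k = 0
    while sum(per_locus) < needed_nondiag:
        if per_locus[k % len(nondiag)] < m - 1:
            per_locus[k % len(nondiag)] += 1
        k += 1

    freqs: dict[str, dict[str, dict[int, float]]] = {"A": {}, "B": {}}
    for j, locus in enumerate(loci):
        base = int(rng.integers(80, 220))
        sizes = [base + 2 * i for i in range(m)]  # dinucleotide ladder
        if locus in diag:
            # B monomorphic; all of A's alleles private
            freqs["B"][locus] = {sizes[0]: 1.0}
            pa = _floored_dirichlet(rng, m - 1)
            freqs["A"][locus] = {s: float(p) for s, p in zip(sizes[1:], pa)}
            continue
        n_priv = per_locus[j - n_diagnostic]
        n_priv_a = (n_priv + 1) // 2
        n_priv_b = n_priv - n_priv_a
        shared = sizes[: m - n_priv]
        priv_a = sizes[m - n_priv : m - n_priv + n_priv_a]
        priv_b = sizes[m - n_priv + n_priv_a :]
        if private_fraction == 0.0:
            p = _floored_dirichlet(rng, m)
            freqs["A"][locus] = {s: float(x) for s, x in zip(shared, p)}
            freqs["B"][locus] = dict(freqs["A"][locus])
            continue
        alleles_a = shared + priv_a
        alleles_b = shared + priv_b
        pa = _floored_dirichlet(rng, len(alleles_a))
        pb = _floored_dirichlet(rng, len(alleles_b))
        freqs["A"][locus] = {s: float(x) for s, x in zip(alleles_a, pa)}
        freqs["B"][locus] = {s: float(x) for s, x in zip(alleles_b, pb)}

    profile = SpeciesProfile(
        freqs=freqs,
        diagnostic_loci=list(diag),
        dropout={l: dict(d) for l, d in dropout.items()} if dropout else {},
    )
    realised = profile.realised_private_fraction()
    if abs(realised - private_fraction) > 0.05:
        raise ValueError(
            f"designed private fraction {realised:.3f} misses target "
            f"{private_fraction:.3f} by more than 5 points"
        )
    return profile


def make_divergence_profiles(
    n_loci: int = 10,
    alleles_per_locus: int = 8,
    fst_between: float = 0.25,
    seed: int = 0,
) -> SpeciesProfile:
    """Two species drawn from one ancestral pool at a target between-species F_ST.

    Both species' frequencies are Balding-Nichols draws around a common
    ancestral Dirichlet frequency vector with concentration
    (1 - F)/F * p, so the expected pairwise theta between the species is
    ``fst_between``. Used for calibrating hierarchical-variance analyses;
    no private-allele structure is enforced.
    """
    if not 0.0 < fst_between < 1.0:
        raise ValueError("fst_between must be in (0, 1)")
    rng = np.random.default_rng(seed)
    loci = [f"ms{i + 1:02d}" for i in range(n_loci)]
    c = (1.0 - fst_between) / fst_between
    freqs: dict[str, dict[str, dict[int, float]]] = {"A": {}, "B": {}}
    for locus in loci:
        base = int(rng.integers(80, 220))
        sizes = [base + 2 * i for i in range(alleles_per_locus)]
        anc = _floored_dirichlet(rng, alleles_per_locus)
        for sp in SPECIES:
            p = rng.dirichlet(np.maximum(anc * c, 1e-6))
            p = np.maximum(p, 1e-9)
            p = p / p.sum()
            freqs[sp][locus] = {s: float(x) for s, x in zip(sizes, p)}
    return SpeciesProfile(freqs=freqs)


# ---------------------------------------------------------------------------
# genotype sampling (HYBRIDLAB-style HWE + linkage-equilibrium draws)
# ---------------------------------------------------------------------------


def _locus_arrays(
    freqs: Mapping[str, Mapping[int, float]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for locus, f in freqs.items():
        alleles = np.array(sorted(f), dtype=np.int64)
        probs = np.array([f[a] for a in alleles])
        out[locus] = (alleles, probs / probs.sum())
    return out


def _draw(rng, arrays, locus, size) -> np.ndarray:
    alleles, probs = arrays[locus]
    return rng.choice(alleles, size=size, p=probs)


def _apply_dropout(
    rng: np.random.Generator,
    calls: np.ndarray,
    loci: Sequence[str],
    rate_of: Mapping[str, float],
) -> None:
    for j, locus in enumerate(loci):
        r = rate_of.get(locus, 0.0)
        if r > 0:
            drop = rng.random(calls.shape[0]) < r
            calls[drop, j, :] = 0


def sample_purebreds(
    profile: SpeciesProfile,
    species: str,
    n: int,
    dropout_on: bool = True,
    seed: int = 0,
    prefix: str | None = None,
    group: str | None = None,
) -> GenotypeMatrix:
    """Draw n purebred genotypes: two independent allele draws per locus (HWE)."""
    if species not in profile.freqs:
        raise ValueError(f"unknown species {species!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    loci = profile.loci
    arrays = _locus_arrays(profile.freqs[species])
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        calls[:, j, 0] = _draw(rng, arrays, locus, n)
        calls[:, j, 1] = _draw(rng, arrays, locus, n)
    if dropout_on:
        _apply_dropout(
            rng, calls, loci, {l: profile.dropout_of(l, species) for l in loci}
        )
    prefix = prefix if prefix is not None else f"P{species}"
    inds = [f"{prefix}-{i + 1:04d}" for i in range(n)]
    grp = group if group is not None else species
    return GenotypeMatrix(inds, loci, calls, {i: grp for i in inds})


def _gamete(rng: np.random.Generator, parent: np.ndarray) -> np.ndarray:
    """One transmitted allele per locus, equiprobable, for (n, L, 2) parents."""
    pick = rng.integers(0, 2, size=parent.shape[:2])
    return np.take_along_axis(parent, pick[:, :, None], axis=2)[:, :, 0]


def sample_hybrids(
    profile: SpeciesProfile,
    hybrid_class: str,
    n: int,
    maternal_species: str = "B",
    seed: int = 0,
    dropout_on: bool = False,
    prefix: str | None = None,
    group: str | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Draw n hybrid genotypes of a given class plus their mtDNA lineage tags.

    F1 crosses one allele from each species' pool per locus; F2 mates two
    freshly simulated F1 parents (each transmits one of its two alleles,
    equiprobably); BCxA / BCxB cross an F1 with a purebred A / B. The
    mtDNA tag of every hybrid equals ``maternal_species``.
    """
    if hybrid_class not in HYBRID_CLASSES:
        raise ValueError(f"unknown hybrid class {hybrid_class!r}")
    if maternal_species not in SPECIES:
        raise ValueError(f"unknown maternal species {maternal_species!r}")
    rng = np.random.default_rng(seed)
    loci = profile.loci
    arr_a = _locus_arrays(profile.freqs["A"])
    arr_b = _locus_arrays(profile.freqs["B"])

    def f1_block(count: int) -> np.ndarray:
        calls = np.zeros((count, len(loci), 2), dtype=np.int64)
        for j, locus in enumerate(loci):
            calls[:, j, 0] = _draw(rng, arr_a, locus, count)
            calls[:, j, 1] = _draw(rng, arr_b, locus, count)
        return calls

    def purebred_block(arrays, count: int) -> np.ndarray:
        calls = np.zeros((count, len(loci), 2), dtype=np.int64)
        for j, locus in enumerate(loci):
            calls[:, j, 0] = _draw(rng, arrays, locus, count)
            calls[:, j, 1] = _draw(rng, arrays, locus, count)
        return calls

    if hybrid_class == "F1":
        calls = f1_block(n)
    elif hybrid_class == "F2":
        p1, p2 = f1_block(n), f1_block(n)
        calls = np.stack([_gamete(rng, p1), _gamete(rng, p2)], axis=2)
    else:
        back = arr_a if hybrid_class == "BCxA" else arr_b
        p1 = f1_block(n)
        p2 = purebred_block(back, n)
        calls = np.stack([_gamete(rng, p1), _gamete(rng, p2)], axis=2)

    if dropout_on:
        rates = {
            l: 0.5 * (profile.dropout_of(l, "A") + profile.dropout_of(l, "B"))
            for l in loci
        }
        _apply_dropout(rng, calls, loci, rates)
    prefix = prefix if prefix is not None else hybrid_class
    inds = [f"{prefix}-{i + 1:04d}" for i in range(n)]
    grp = group if group is not None else hybrid_class
    g = GenotypeMatrix(inds, loci, calls, {i: grp for i in inds})
    return g, [maternal_species] * n


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------


@dataclass
class SiteMix:
    """One sampling site: region label plus per-class individual counts."""

    name: str
    region: str
    counts: dict[str, int]  # keys from {"A", "B", "F1", "F2", "BCxA", "BCxB"}

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if cls not in SPECIES + HYBRID_CLASSES:
                raise ValueError(f"unknown class {cls!r} at site {self.name}")
            if n < 0:
                raise ValueError("counts must be >= 0")


@dataclass
class StudyConfig:
    """Everything needed to generate one synthetic study."""

    sites: list[SiteMix]
    profile: SpeciesProfile
    hybrid_maternal: str = "B"
    fst_within: float = 0.045  # Balding-Nichols site perturbation, per species
    mtdna_length: int = 515
    mtdna_fixed_differences: int = 38
    # intraspecific haplotype weights (first entry = root haplotype)
    mtdna_haplotype_counts: dict[str, list[int]] = field(
        default_factory=lambda: {"A": [237, 5, 6, 9, 4, 1], "B": [68, 1, 21, 15]}
    )
    misid_base: float = 0.74  # P(genetic-B labelled A), length-independent part
    misid_slope: float = 0.0  # logistic slope per mm of fork length
    misid_ref_length: float = 160.0
    fl_mean: dict[str, float] = field(
        default_factory=lambda: {"A": 140.0, "B": 180.0}
    )
    fl_sd: dict[str, float] = field(default_factory=lambda: {"A": 25.0, "B": 35.0})
    region_fl_offset: dict[str, float] = field(default_factory=dict)
    k_mean: dict[str, float] = field(
        default_factory=lambda: {"A": 0.90, "B": 0.75}
    )
    k_sd: dict[str, float] = field(default_factory=lambda: {"A": 0.10, "B": 0.10})
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.misid_base <= 1.0:
            raise ValueError("misid_base outside [0, 1]")
        if not 0.0 <= self.fst_within < 1.0:
            raise ValueError("fst_within outside [0, 1)")
        if self.hybrid_maternal not in SPECIES:
            raise ValueError("hybrid_maternal must be 'A' or 'B'")
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError("duplicate site names")
        regions_of: dict[str, str] = {}
        for s in self.sites:
            if s.name in regions_of and regions_of[s.name] != s.region:
                raise ValueError("inconsistent site/region definitions")
            regions_of[s.name] = s.region
        if self.mtdna_fixed_differences < 0:
            raise ValueError("fixed-difference count must be >= 0")
        total_mut = self.mtdna_fixed_differences + sum(
            len(v) - 1 for v in self.mtdna_haplotype_counts.values()
        )
        if total_mut > self.mtdna_length:
            raise ValueError("more mutated columns than alignment length")


@dataclass
class StudyResult:
    genotypes: GenotypeMatrix  # group label = site name
    alignment: SequenceAlignment
    metadata: dict[str, SampleMetadata]
    truth: pd.DataFrame
    site_region: dict[str, str]

    @property
    def species_of(self) -> dict[str, str]:
        """Genetic species per individual ('hybrid' for hybrid classes)."""
        return dict(zip(self.truth["individual"], self.truth["genetic_species"]))


def _perturb_site_freqs(
    rng: np.random.Generator,
    base: Mapping[str, Mapping[int, float]],
    fst: float,
) -> dict[str, dict[int, float]]:
    """Balding-Nichols draw of site frequencies around the species base."""
    if fst <= 0:
        return {l: dict(f) for l, f in base.items()}
    c = (1.0 - fst) / fst
    out: dict[str, dict[int, float]] = {}
    for locus, f in base.items():
        alleles = sorted(f)
        p = np.array([f[a] for a in alleles])
        if len(alleles) == 1:
            out[locus] = {alleles[0]: 1.0}
            continue
        q = rng.dirichlet(np.maximum(p * c, 1e-6))
        q = np.maximum(q, 1e-12)
        q = q / q.sum()
        out[locus] = {a: float(x) for a, x in zip(alleles, q)}
    return out


def _build_mtdna_haplotypes(
    rng: np.random.Generator, cfg: StudyConfig
) -> dict[str, list[tuple[str, float]]]:
    """Per species: list of (sequence, sampling weight).

    One ancestral sequence; species B's root differs from A's at exactly
    the configured fixed-difference columns; each additional intraspecific
    haplotype adds one private mutation at a fresh column, so the fixed
    differences between species are exactly the configured count.
    """
    L = cfg.mtdna_length
    anc = _BASES[rng.integers(0, 4, size=L)].copy()
    n_intra = sum(len(v) - 1 for v in cfg.mtdna_haplotype_counts.values())
    cols = rng.choice(L, size=cfg.mtdna_fixed_differences + n_intra, replace=False)
    fixed_cols = cols[: cfg.mtdna_fixed_differences]
    intra_cols = list(cols[cfg.mtdna_fixed_differences :])

    def mutate(seq: np.ndarray, col: int) -> np.ndarray:
        out = seq.copy()
        choices = [b for b in "ACGT" if b != out[col]]
        out[col] = choices[int(rng.integers(0, 3))]
        return out

    root = {"A": anc, "B": anc}
    b_root = anc.copy()
    for col in fixed_cols:
        b_root = mutate(b_root, int(col))
    root["B"] = b_root

    out: dict[str, list[tuple[str, float]]] = {}
    ptr = 0
    for sp in SPECIES:
        counts = cfg.mtdna_haplotype_counts.get(sp, [1])
        total = float(sum(counts))
        haps = [("".join(root[sp]), counts[0] / total)]
        for c_i in counts[1:]:
            derived = mutate(root[sp], int(intra_cols[ptr]))
            ptr += 1
            haps.append(("".join(derived), c_i / total))
        out[sp] = haps
    return out


def _misid_probability(cfg: StudyConfig, fl: float) -> float:
    if cfg.misid_slope == 0.0 or cfg.misid_base in (0.0, 1.0):
        return cfg.misid_base
    logit = math.log(cfg.misid_base / (1.0 - cfg.misid_base))
    z = logit + cfg.misid_slope * (fl - cfg.misid_ref_length)
    return 1.0 / (1.0 + math.exp(-z))


def make_study(config: StudyConfig) -> StudyResult:
    """Generate one full synthetic study from a StudyConfig."""
    master = np.random.SeedSequence(config.seed)
    (
        ss_sites,
        ss_mtdna,
        ss_pheno,
        ss_morpho,
    ) = master.spawn(4)
    rng_mtdna = np.random.default_rng(ss_mtdna)
    rng_pheno = np.random.default_rng(ss_pheno)
    rng_morpho = np.random.default_rng(ss_morpho)

    profile = config.profile
    loci = profile.loci
    hap_pool = _build_mtdna_haplotypes(rng_mtdna, config)

    genotype_parts: list[GenotypeMatrix] = []
    records: dict[str, str] = {}
    metadata: dict[str, SampleMetadata] = {}
    truth_rows: list[dict] = []
    site_region: dict[str, str] = {}

    site_streams = ss_sites.spawn(len(config.sites))
    for site, stream in zip(config.sites, site_streams):
        site_region[site.name] = site.region
        rng_site = np.random.default_rng(stream)
        # site-level allele frequencies (regional substructure per species)
        site_freqs = {
            sp: _perturb_site_freqs(rng_site, profile.freqs[sp], config.fst_within)
            for sp in SPECIES
        }
        site_profile = SpeciesProfile(
            freqs=site_freqs,
            diagnostic_loci=[],
            dropout={l: dict(d) for l, d in profile.dropout.items()},
        )
        for cls, n in site.counts.items():
            if n == 0:
                continue
            sub_seed = int(rng_site.integers(0, 2**31 - 1))
            prefix = f"{site.name}-{cls}"
            if cls in SPECIES:
                g = sample_purebreds(
                    site_profile, cls, n, dropout_on=True,
                    seed=sub_seed, prefix=prefix, group=site.name,
                )
                tags = [cls] * n
                genetic = cls
            else:
                g, tags = sample_hybrids(
                    site_profile, cls, n,
                    maternal_species=config.hybrid_maternal,
                    seed=sub_seed, dropout_on=True,
                    prefix=prefix, group=site.name,
                )
                genetic = "hybrid"
            genotype_parts.append(g)
            for ind, maternal in zip(g.individuals, tags):
                # mtDNA haplotype from the maternal lineage
                haps = hap_pool[maternal]
                weights = np.array([w for _, w in haps])
                pick = rng_mtdna.choice(len(haps), p=weights / weights.sum())
                records[ind] = haps[pick][0]
                # morphometrics
                sp_for_size = maternal if genetic == "hybrid" else genetic
                fl_mu = config.fl_mean[sp_for_size] + config.region_fl_offset.get(
                    site.region, 0.0
                )
                fl = max(
                    30.0,
                    float(rng_morpho.normal(fl_mu, config.fl_sd[sp_for_size])),
                )
                kf = max(
                    0.2,
                    float(
                        rng_morpho.normal(
                            config.k_mean[sp_for_size], config.k_sd[sp_for_size]
                        )
                    ),
                )
                wt = kf * fl**3 / 10_000.0
                tl = (fl + 3.076) / 0.945
                # asymmetric misidentification: genetic A always labelled A
                if genetic == "A":
                    label = "A"
                else:
                    p_mis = _misid_probability(config, fl)
                    label = "A" if rng_pheno.random() < p_mis else "B"
                metadata[ind] = SampleMetadata(
                    individual=ind,
                    phenotype_label=label,
                    site=site.name,
                    region=site.region,
                    T_L=round(tl, 1),
                    F_L=round(fl, 1),
                    W_t=round(wt, 1),
                    mtdna_id=ind,
                )
                truth_rows.append(
                    {
                        "individual": ind,
                        "site": site.name,
                        "region": site.region,
                        "genetic_species": genetic,
                        "hybrid_class": cls if genetic == "hybrid" else "",
                        "maternal": maternal if genetic == "hybrid" else genetic,
                        "phenotype_label": label,
                    }
                )

    genotypes = genotype_parts[0]
    for part in genotype_parts[1:]:
        genotypes = genotypes.concat(part)
    alignment = SequenceAlignment(records)
    truth = pd.DataFrame(truth_rows)
    return StudyResult(
        genotypes=genotypes,
        alignment=alignment,
        metadata=metadata,
        truth=truth,
        site_region=site_region,
    )


def default_study_config(seed: int = 0, profile_seed: int | None = None) -> StudyConfig:
    """The default study: 456 individuals across four regions, 3 F1 hybrids.

    Mirrors the survey layout the pipeline targets: species A dominant on
    the Chilean mainland, species B on Chiloe and East Falkland, roughly
    even numbers in West Falkland; two diagnostic loci; two loci with
    severe amplification failure in species B (typing rates 33% and 6%);
    74% of genetic-B fish field-labelled as A; all hybrids maternal-B.
    """
    profile = make_species_profiles(
        n_loci=13,
        alleles_per_locus=10,
        private_fraction=0.70,
        n_diagnostic=2,
        seed=profile_seed if profile_seed is not None else seed + 101,
        dropout={"ms12": {"B": 0.67}, "ms13": {"B": 0.94}},
    )
    sites = [
        SiteMix("M1", "Mainland", {"A": 92}),
        SiteMix("M2", "Mainland", {"A": 92, "B": 1}),
        SiteMix("C1", "Chiloe", {"A": 66, "B": 29, "F1": 1}),
        SiteMix("C2", "Chiloe", {"A": 65, "B": 29, "F1": 1}),
        SiteMix("EF1", "E. Falkland", {"A": 5, "B": 22, "F1": 1}),
        SiteMix("EF2", "E. Falkland", {"A": 5, "B": 22}),
        SiteMix("WF1", "W. Falkland", {"A": 6, "B": 7}),
        SiteMix("WF2", "W. Falkland", {"A": 6, "B": 6}),
    ]
    return StudyConfig(
        sites=sites,
        profile=profile,
        hybrid_maternal="B",
        region_fl_offset={"E. Falkland": 15.0, "W. Falkland": 15.0},
        seed=seed,
    )
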