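"""End-to-end hybrid identification.

The procedure mirrors the standard admixture-based hybrid scan for a
two-species system:

1. run the admixture model (K = 2) on the full genotype matrix, averaging
   replicate chains;
2. pick reference purebreds for each cluster (membership above a cut,
   default Q > 0.9);
3. estimate parental allele frequencies from the references and simulate
   purebred and hybrid-class genotypes (F1, F2, both backcrosses) under
   HWE/linkage equilibrium;
4. rerun the admixture model on the simulated individuals to calibrate
   decision thresholds: Q_pure, the minimum max-membership among simulated
   purebreds, and Q_hyb_max, the maximum max-membership among simulated
   hybrids;
5. classify every real individual as purebred, hybrid, or -- when its
   membership falls between the hybrid envelope and the purebred floor --
   ambiguous; cross-check hybrids against private alleles and determine
   the maternal species from the mtDNA haplogroup.

PCA on allele counts corroborates the admixture classes: purebreds form
two clouds on PC1 and F1 hybrids sit between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .admixture import AdmixtureResult, align_runs, gibbs_admixture
from .data import MISSING, GenotypeMatrix, allele_frequencies
from .popgen import private_alleles
from .synthetic import HYBRID_CLASSES, SpeciesProfile, sample_hybrids, sample_purebreds

__all__ = [
    "HybridCalibration",
    "ClassificationRecord",
    "filter_informative_loci",
    "select_reference_sets",
    "calibrate_thresholds",
    "classify",
    "pca_genotypes",
    "run_hybrid_scan",
    "HybridScanResult",
]


# ---------------------------------------------------------------------------
# locus filtering and reference selection
# ---------------------------------------------------------------------------


def filter_informative_loci(
    g: GenotypeMatrix,
    grouping: Mapping[str, str] | None = None,
    min_typing_rate: float = 0.5,
) -> GenotypeMatrix:
    """Drop loci whose typing rate falls below the cut in any group.

    Markers that fail to amplify in one species carry almost no admixture
    information and bias missing-data handling, so they are excluded
    before running the admixture model (default cut: 50% per group).
    """
    grouping = dict(grouping) if grouping is not None else dict(g.group_of)
    groups: dict[str, list[str]] = {}
    for ind in g.individuals:
        groups.setdefault(grouping.get(ind, ""), []).append(ind)
    keep = [
        locus
        for locus in g.loci
        if all(
            g.typing_rate(locus, members) >= min_typing_rate
            for members in groups.values()
        )
    ]
    if not keep:
        raise ValueError("no locus passes the typing-rate filter")
    return g.subset(loci=keep)


def select_reference_sets(
    adm: AdmixtureResult, q_cut: float = 0.9, min_size: int = 20
) -> tuple[list[str], list[str]]:
    """Individuals with q1 > cut (refA) or q2 > cut (refB); others withheld."""
    refA = [ind for ind, q in zip(adm.individuals, adm.Q) if q[0] > q_cut]
    refB = [ind for ind, q in zip(adm.individuals, adm.Q) if q[1] > q_cut]
    if len(refA) < min_size or len(refB) < min_size:
        raise ValueError(
            f"reference set too small (A: {len(refA)}, B: {len(refB)}; "
            f"minimum {min_size})"
        )
    return refA, refB


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

_CAL_CLASSES = ("PA", "PB") + HYBRID_CLASSES


@dataclass
class HybridCalibration:
    """Simulated per-class max-membership (Q) distributions and thresholds.

    ``Q_pure`` is the minimum max-membership over the simulated purebreds
    and ``Q_hyb_max`` the maximum over the simulated F1s: the envelope of
    confidently detectable hybrids. F2 and backcross distributions are
    summarised too (``Q_late_max`` is their maximum), but they routinely
    overlap the purebred range -- microsatellite panels of this size
    cannot discriminate late-generation hybrids reliably, so individuals
    between ``Q_hyb_max`` and ``Q_pure`` are reported as ambiguous rather
    than assigned a class.
    """

    summaries: dict[str, dict[str, float]]
    # class -> {"min", "max", "mean", "q05", "q25", "q50", "q75", "q95"}
    Q_pure: float  # min max-membership over simulated purebreds
    Q_hyb_max: float  # max max-membership over simulated F1 hybrids
    Q_late_max: float  # max over F2/backcross classes (unreliable zone)
    n_per_class: int
    reps: int
    no_power: bool = False
    class_values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.Q_hyb_max <= 1.0 and 0.0 <= self.Q_pure <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")


def _summary(values: np.ndarray) -> dict[str, float]:
    qs = np.quantile(values, [0.05, 0.25, 0.5, 0.75, 0.95])
    return {
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "q05": float(qs[0]),
        "q25": float(qs[1]),
        "q50": float(qs[2]),
        "q75": float(qs[3]),
        "q95": float(qs[4]),
    }


def calibrate_thresholds(
    refA: GenotypeMatrix,
    refB: GenotypeMatrix,
    n_per_class: int = 100,
    reps: int = 10,
    burnin: int = 500,
    sweeps: int = 2000,
    seed: int = 0,
) -> HybridCalibration:
    """Simulate parental and hybrid classes from the references and derive Q thresholds.

    Per repetition: ``n_per_class`` genotypes are simulated for each of the
    six classes (two parentals, F1, F2, both backcrosses) from allele
    frequencies estimated on the reference sets, and one admixture chain
    (K = 2, no prior labels) is run on the simulated batch. Max-membership
    values are pooled over repetitions; if the purebred range overlaps the
    hybrid range the calibration is flagged as having no power.
    """
    if refA.loci != refB.loci:
        raise ValueError("reference sets must share loci")
    fa = allele_frequencies(refA, {i: "A" for i in refA.individuals})["A"]
    fb = allele_frequencies(refB, {i: "B" for i in refB.individuals})["B"]
    profile = SpeciesProfile(
        freqs={
            "A": {l: dict(fa.freqs[l]) for l in fa.loci if fa.freqs[l]},
            "B": {l: dict(fb.freqs[l]) for l in fb.loci if fb.freqs[l]},
        }
    )
    shared = [l for l in profile.freqs["A"] if l in profile.freqs["B"]]
    profile = SpeciesProfile(
        freqs={sp: {l: profile.freqs[sp][l] for l in shared} for sp in ("A", "B")}
    )

    rng = np.random.default_rng(seed)
    values: dict[str, list[float]] = {c: [] for c in _CAL_CLASSES}
    for _ in range(reps):
        batch_parts = []
        labels: list[str] = []
        for cls in _CAL_CLASSES:
            s = int(rng.integers(0, 2**31 - 1))
            if cls == "PA":
                part = sample_purebreds(profile, "A", n_per_class, False, s, f"sim{cls}")
            elif cls == "PB":
                part = sample_purebreds(profile, "B", n_per_class, False, s, f"sim{cls}")
            else:
                part, _ = sample_hybrids(profile, cls, n_per_class, "B", s,
                                         prefix=f"sim{cls}")
            batch_parts.append(part)
            labels.extend([cls] * n_per_class)
        batch = batch_parts[0]
        for p in batch_parts[1:]:
            batch = batch.concat(p)
        adm = gibbs_admixture(
            batch, K=2, burnin=burnin, sweeps=sweeps,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        qmax = adm.Q.max(axis=1)
        for cls, v in zip(labels, qmax):
            values[cls].append(float(v))

    arr = {c: np.array(v) for c, v in values.items()}
    pure = np.concatenate([arr["PA"], arr["PB"]])
    late = np.concatenate([arr[c] for c in ("F2", "BCxA", "BCxB")])
    q_pure = float(pure.min())
    q_f1 = float(arr["F1"].max())
    return HybridCalibration(
        summaries={c: _summary(v) for c, v in arr.items()},
        Q_pure=q_pure,
        Q_hyb_max=q_f1,
        Q_late_max=float(late.max()),
        n_per_class=n_per_class,
        reps=reps,
        no_power=q_f1 >= q_pure,
        class_values=arr,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationRecord:
    individual: str
    q: tuple[float, float]  # (q_species_A, q_species_B)
    call: str  # purebred-A | purebred-B | hybrid | ambiguous
    mtdna_species: str | None = None
    maternal_species: str | None = None  # set for hybrids with mtDNA
    private_evidence: list[tuple[str, int, str]] = field(default_factory=list)
    pca: tuple[float, float] | None = None
    phenotype_label: str | None = None
    concordant: bool | None = None


def classify(
    adm: AdmixtureResult,
    cal: HybridCalibration,
    g: GenotypeMatrix,
    mtdna_species: Mapping[str, str] | None = None,
    private_allele_list: Sequence[tuple[str, int, str]] | None = None,
    phenotype: Mapping[str, str] | None = None,
    cluster_species: tuple[str, str] = ("A", "B"),
) -> list[ClassificationRecord]:
    """Assign purebred / hybrid / ambiguous calls from calibrated Q thresholds.

    An individual is a purebred of the majority cluster's species when its
    max membership reaches Q_pure, a hybrid when it stays within the
    simulated hybrid envelope (<= Q_hyb_max), and ambiguous in between --
    the zone where admixture alone cannot separate late-generation hybrids
    from purebreds. Hybrid records get a maternal species from their mtDNA
    haplogroup and a list of carried alleles private to the species
    opposite that lineage (the introgression witnesses).
    """
    if cal.no_power:
        raise ValueError("calibration has no power: purebred and hybrid Q overlap")
    mtdna_species = dict(mtdna_species or {})
    private_allele_list = list(private_allele_list or [])
    phenotype = dict(phenotype or {})
    sp_a, sp_b = cluster_species
    priv_by_owner: dict[str, set[tuple[str, int]]] = {}
    for locus, allele, owner in private_allele_list:
        priv_by_owner.setdefault(owner, set()).add((locus, allele))

    records = []
    for ind, q in zip(adm.individuals, adm.Q):
        qmax = float(q.max())
        if qmax >= cal.Q_pure:
            call = f"purebred-{sp_a}" if q[0] >= q[1] else f"purebred-{sp_b}"
        elif qmax <= cal.Q_hyb_max:
            call = "hybrid"
        else:
            call = "ambiguous"
        mt = mtdna_species.get(ind)
        maternal = mt if (call in ("hybrid", "ambiguous") and mt is not None) else None
        evidence: list[tuple[str, int, str]] = []
        if call in ("hybrid", "ambiguous") and mt is not None:
            opposite = sp_b if mt == sp_a else sp_a
            carried = priv_by_owner.get(opposite, set())
            i = g.individuals.index(ind)
            for j, locus in enumerate(g.loci):
                a, b = g.calls[i, j]
                if a == MISSING:
                    continue
                for allele in {int(a), int(b)}:
                    if (locus, allele) in carried:
                        evidence.append((locus, allele, opposite))
        label = phenotype.get(ind)
        concordant = None
        if label is not None:
            if call.startswith("purebred-"):
                concordant = label == call.split("-", 1)[1]
            elif call == "hybrid":
                concordant = False  # field keys have no hybrid category
        records.append(
            ClassificationRecord(
                individual=ind,
                q=(float(q[0]), float(q[1])),
                call=call,
                mtdna_species=mt,
                maternal_species=maternal,
                private_evidence=sorted(evidence),
                phenotype_label=label,
                concordant=concordant,
            )
        )
    return records


# ---------------------------------------------------------------------------
# PCA corroboration
# ---------------------------------------------------------------------------


def pca_genotypes(g: GenotypeMatrix, n_components: int = 2) -> np.ndarray:
    """PCA on allele-count encodings of the genotypes.

    Each observed (locus, allele) pair becomes a column holding the number
    of copies (0/1/2) the individual carries; missing genotypes take the
    column mean. Columns are centred and the covariance matrix is
    eigen-decomposed. Deterministic sign: the largest-magnitude loading of
    each component is made positive.
    """
    if g.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    cols: list[np.ndarray] = []
    for j in range(g.n_loci):
        pairs = g.calls[:, j, :]
        typed = pairs[:, 0] != MISSING
        alleles = np.unique(pairs[typed])
        for a in alleles:
            counts = (pairs == a).sum(axis=1).astype(float)
            if typed.all():
                col = counts
            else:
                mean = counts[typed].mean() if typed.any() else 0.0
                col = np.where(typed, counts, mean)
            cols.append(col)
    X = np.column_stack(cols)
    X = X - X.mean(axis=0, keepdims=True)
    if not (X != 0).any():
        raise ValueError("zero-variance data: PCA undefined")
    cov = X.T @ X / max(g.n_individuals - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_components]
    V = vecs[:, order]
    for k in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, k])))
        if V[i, k] < 0:
            V[:, k] = -V[:, k]
    return X @ V


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------


@dataclass
class HybridScanResult:
    records: list[ClassificationRecord]
    calibration: HybridCalibration
    admixture: AdmixtureResult
    pca: np.ndarray
    loci_used: list[str]
    cluster_species: tuple[str, str]


def run_hybrid_scan(
    g: GenotypeMatrix,
    mtdna_species: Mapping[str, str] | None = None,
    phenotype: Mapping[str, str] | None = None,
    n_runs: int = 5,
    burnin: int = 500,
    sweeps: int = 2000,
    q_cut: float = 0.9,
    min_ref_size: int = 20,
    n_per_class: int = 100,
    cal_reps: int = 10,
    min_typing_rate: float = 0.5,
    seed: int = 0,
) -> HybridScanResult:
    """Run the complete hybrid scan on one genotype matrix.

    ``mtdna_species`` maps individuals to their mtDNA-derived species
    ("A"/"B"); it orients the admixture clusters (the cluster whose
    high-membership individuals carry species-A mtDNA is called A) and
    supplies hybrid maternal lineages. Without it, the larger cluster is
    called A and directionality fields stay empty.
    """
    rng = np.random.default_rng(seed)
    grouping = dict(mtdna_species) if mtdna_species else dict(g.group_of)
    g_used = filter_informative_loci(g, grouping, min_typing_rate)

    runs = [
        gibbs_admixture(
            g_used, K=2, burnin=burnin, sweeps=sweeps,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for _ in range(n_runs)
    ]
    adm = align_runs(runs)

    # orient clusters: cluster 0 should be species "A"
    swap = False
    if mtdna_species:
        q0_a = [
            q[0]
            for ind, q in zip(adm.individuals, adm.Q)
            if mtdna_species.get(ind) == "A"
        ]
        q0_b = [
            q[0]
            for ind, q in zip(adm.individuals, adm.Q)
            if mtdna_species.get(ind) == "B"
        ]
        if q0_a and q0_b and np.mean(q0_a) < np.mean(q0_b):
            swap = True
    else:
        n0 = int((adm.Q[:, 0] > 0.5).sum())
        swap = n0 < adm.Q.shape[0] - n0
    if swap:
        adm = AdmixtureResult(
            individuals=adm.individuals,
            Q=adm.Q[:, ::-1].copy(),
            K=2,
            cluster_freqs=adm.cluster_freqs,
            n_runs=adm.n_runs,
        )

    refA_ids, refB_ids = select_reference_sets(adm, q_cut, min_ref_size)
    refA, refB = g_used.subset(individuals=refA_ids), g_used.subset(individuals=refB_ids)
    cal = calibrate_thresholds(
        refA, refB, n_per_class=n_per_class, reps=cal_reps,
        burnin=burnin, sweeps=sweeps, seed=int(rng.integers(0, 2**31 - 1)),
    )

    freqs = allele_frequencies(
        g_used,
        {**{i: "A" for i in refA_ids}, **{i: "B" for i in refB_ids}},
    )
    priv = private_alleles(freqs["A"], freqs["B"]) if {"A", "B"} <= set(freqs) else []

    records = classify(
        adm, cal, g_used,
        mtdna_species=mtdna_species,
        private_allele_list=priv,
        phenotype=phenotype,
    )
    coords = pca_genotypes(g_used)
    for rec, xy in zip(records, coords):
        rec.pca = (float(xy[0]), float(xy[1]))
    return HybridScanResult(
        records=records,
        calibration=cal,
        admixture=adm,
        pca=coords,
        loci_used=list(g_used.loci),
        cluster_species=("A", "B"),
    )
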