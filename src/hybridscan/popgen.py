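"""Microsatellite population-genetic statistics.

Summary diversity (Na, Ho, unbiased He, rarefied allelic richness), the
private-allele rule used to pick species-diagnostic markers, Weir &
Cockerham's F_ST estimator (theta), a two-level hierarchical AMOVA with
permutation tests, Nei's (1972) standard genetic distance, UPGMA trees
with locus-bootstrap node support, permutation tests for Hardy-Weinberg
proportions and gametic (linkage) disequilibrium, and the sequential
Bonferroni (Holm) correction.

Conventions follow the classic microsatellite toolchain this replaces:
He is Nei's unbiased estimator 2n/(2n-1) * (1 - sum p^2); allelic richness
is rarefied to the smallest per-locus typed sample across the compared
groups; bootstrap node support resamples loci (not individuals); the AMOVA
inter-individual distance is the count of allele copies not shared between
two genotypes, summed over loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, xlogy
from scipy.stats import chi2

from .data import MISSING, AlleleFrequencyTable, GenotypeMatrix, allele_frequencies

__all__ = [
    "DiversitySummary",
    "VarianceComponents",
    "GeneticDistanceMatrix",
    "Tree",
    "diversity_summary",
    "private_alleles",
    "wc_fst",
    "amova_two_level",
    "nei_standard_distance",
    "nei_distance_matrix",
    "upgma",
    "bootstrap_upgma",
    "hwe_test",
    "ld_test",
    "g_statistic",
    "sequential_bonferroni",
]


# ---------------------------------------------------------------------------
# diversity summary
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    """Per-group, per-locus diversity table plus per-group means.

    ``table[group][locus]`` is a dict with keys ``N`` (typed individuals),
    ``size_range`` ((min, max) allele size or None), ``Na``, ``He``
    (unbiased expected heterozygosity), ``Ho`` (observed), and ``Ar``
    (allelic richness rarefied to the smallest per-locus typed count
    across groups; None where the locus is untyped in some group).
    ``mean_ho`` and ``mean_ar`` average the defined per-locus values.
    """

    table: dict[str, dict[str, dict]]
    mean_ho: dict[str, float]
    mean_ar: dict[str, float]


def _unbiased_he(freqs: Mapping[int, float], n: int) -> float:
    if n < 1:
        return float("nan")
    h = 1.0 - sum(p * p for p in freqs.values())
    return 2.0 * n / (2.0 * n - 1.0) * h if n > 0 else float("nan")


def _rarefied_richness(counts: Mapping[int, int], m: int) -> float:
    """Expected allele number in a subsample of m copies (hypergeometric)."""
    total = sum(counts.values())
    if m > total:
        raise ValueError("rarefaction size exceeds sample")
    ar = 0.0
    for c in counts.values():
        # P(allele absent from subsample) = C(total-c, m)/C(total, m)
        if total - c < m:
            p_absent = 0.0
        else:
            p_absent = math.exp(
                gammaln(total - c + 1)
                - gammaln(total - c - m + 1)
                + gammaln(total - m + 1)
                - gammaln(total + 1)
            )
        ar += 1.0 - p_absent
    return ar


def diversity_summary(
    g: GenotypeMatrix, grouping: Mapping[str, str] | None = None
) -> DiversitySummary:
    grouping = dict(grouping) if grouping is not None else dict(g.group_of)
    members: dict[str, list[int]] = {}
    for i, ind in enumerate(g.individuals):
        members.setdefault(grouping.get(ind, ""), []).append(i)
    if any(not v for v in members.values()):
        raise ValueError("empty group")

    # allele copy counts per group per locus
    counts: dict[str, dict[str, dict[int, int]]] = {}
    typed_n: dict[str, dict[str, int]] = {}
    for label, idx in members.items():
        counts[label] = {}
        typed_n[label] = {}
        for j, locus in enumerate(g.loci):
            pairs = g.calls[idx, j, :]
            typed = pairs[pairs[:, 0] != MISSING]
            typed_n[label][locus] = len(typed)
            a, c = np.unique(typed.ravel(), return_counts=True)
            counts[label][locus] = {int(x): int(k) for x, k in zip(a, c)}

    # rarefaction size per locus: smallest typed copy count across groups (>0)
    rarefy: dict[str, int | None] = {}
    for locus in g.loci:
        sizes = [2 * typed_n[lab][locus] for lab in members]
        rarefy[locus] = min(sizes) if all(s > 0 for s in sizes) else None

    table: dict[str, dict[str, dict]] = {}
    mean_ho: dict[str, float] = {}
    mean_ar: dict[str, float] = {}
    for label, idx in members.items():
        table[label] = {}
        hos, ars = [], []
        for j, locus in enumerate(g.loci):
            n = typed_n[label][locus]
            if n == 0:
                table[label][locus] = {
                    "N": 0, "size_range": None, "Na": None,
                    "He": None, "Ho": None, "Ar": None,
                }
                continue
            cnt = counts[label][locus]
            total = sum(cnt.values())
            freqs = {a: k / total for a, k in cnt.items()}
            pairs = g.calls[idx, j, :]
            typed = pairs[pairs[:, 0] != MISSING]
            ho = float((typed[:, 0] != typed[:, 1]).mean())
            he = _unbiased_he(freqs, n)
            ar = (
                _rarefied_richness(cnt, rarefy[locus])
                if rarefy[locus] is not None
                else None
            )
            table[label][locus] = {
                "N": n,
                "size_range": (min(cnt), max(cnt)),
                "Na": len(cnt),
                "He": he,
                "Ho": ho,
                "Ar": ar,
            }
            hos.append(ho)
            if ar is not None:
                ars.append(ar)
        mean_ho[label] = float(np.mean(hos)) if hos else float("nan")
        mean_ar[label] = float(np.mean(ars)) if ars else float("nan")
    return DiversitySummary(table=table, mean_ho=mean_ho, mean_ar=mean_ar)


# ---------------------------------------------------------------------------
# private alleles
# ---------------------------------------------------------------------------


def private_alleles(
    fA: AlleleFrequencyTable,
    fB: AlleleFrequencyTable,
    threshold: float = 0.01,
) -> list[tuple[str, int, str]]:
    """Alleles private to one species under the <1% rule.

    An allele is private to X when it is absent from the other species or
    present there below ``threshold`` (strict), while reaching at least
    ``threshold`` in X. Returns (locus, allele, owner-group) tuples.
    """
    if set(fA.loci) != set(fB.loci):
        raise ValueError("frequency tables cover different loci")
    out: list[tuple[str, int, str]] = []
    for locus in fA.loci:
        alleles = set(fA.freqs[locus]) | set(fB.freqs[locus])
        for a in sorted(alleles):
            pa, pb = fA.p(locus, a), fB.p(locus, a)
            if pa >= threshold and pb < threshold:
                out.append((locus, a, fA.group))
            elif pb >= threshold and pa < threshold:
                out.append((locus, a, fB.group))
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components_locus(
    pops: Sequence[np.ndarray],
) -> list[tuple[float, float, float]]:
    """Per-allele (a, b, c) variance components at one locus.

    Each element of ``pops`` is an (n_i, 2) array of typed allele pairs.
    """
    r = len(pops)
    n = np.array([len(p) for p in pops], dtype=float)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted(set(int(x) for p in pops for x in p.ravel()))
    out = []
    for al in alleles:
        p_i = np.array([(p == al).mean() for p in pops])
        h_i = np.array(
            [((p[:, 0] == al) ^ (p[:, 1] == al)).mean() for p in pops]
        )
        pbar = (n * p_i).sum() / (r * nbar)
        s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        out.append((a, b, c))
    return out


def wc_fst(
    g: GenotypeMatrix,
    grouping: Mapping[str, str] | None = None,
) -> float:
    """Multi-locus Weir & Cockerham theta (ratio of summed components).

    Populations are the labels of ``grouping`` (default: the matrix's own
    group labels). Loci monomorphic across all pops, or with fewer than 2
    typed individuals in any pop, are skipped.
    """
    grouping = dict(grouping) if grouping is not None else dict(g.group_of)
    members: dict[str, list[int]] = {}
    for i, ind in enumerate(g.individuals):
        lab = grouping.get(ind)
        if lab is not None:
            members.setdefault(lab, []).append(i)
    if len(members) < 2:
        raise ValueError("need >= 2 populations")
    num = den = 0.0
    used = 0
    for j in range(g.n_loci):
        pops = []
        ok = True
        for idx in members.values():
            pairs = g.calls[idx, j, :]
            typed = pairs[pairs[:, 0] != MISSING]
            if len(typed) < 2:
                ok = False
                break
            pops.append(typed)
        if not ok:
            continue
        alleles = set(int(x) for p in pops for x in p.ravel())
        if len(alleles) < 2:
            continue
        for a, b, c in _wc_components_locus(pops):
            num += a
            den += a + b + c
        used += 1
    if used == 0:
        raise ValueError("no usable polymorphic loci")
    return num / den


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Two-level AMOVA output (groups / populations-within-groups / within)."""

    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    pct_among_groups: float
    pct_among_pops: float
    pct_within: float
    F_CT: float
    F_SC: float
    F_ST: float
    p_F_CT: float | None = None
    p_F_SC: float | None = None
    p_F_ST: float | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        s = self.pct_among_groups + self.pct_among_pops + self.pct_within
        if abs(s - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {s}, not 100")


def _pairwise_sq_distance(g: GenotypeMatrix) -> np.ndarray:
    """Squared distance between allele copies (gametes): identity mismatch per locus.

    Individuals are split into their two allele copies (the convention for
    genotypic data without gametic phase): copy u of individual i at locus
    j either matches copy v of individual k or it does not, and mismatches
    are summed over the loci typed in both individuals. Row/column order
    is (ind0 copy0, ind0 copy1, ind1 copy0, ...).
    """
    n = g.n_individuals
    d2 = np.zeros((2 * n, 2 * n))
    for j in range(g.n_loci):
        A = g.calls[:, j, :]
        typed = np.repeat(A[:, 0] != MISSING, 2)
        copies = A.reshape(-1)  # (2n,)
        neq = copies[:, None] != copies[None, :]
        mask = typed[:, None] & typed[None, :]
        d2 += np.where(mask, neq, 0.0)
    np.fill_diagonal(d2, 0.0)
    return d2


def _amova_f(
    d2: np.ndarray,
    group_ids: np.ndarray,
    pop_ids: np.ndarray,
) -> tuple[float, float, float, tuple[float, float, float], bool]:
    """Compute variance components and F-statistics from a squared-distance matrix."""
    N = len(group_ids)
    groups = np.unique(group_ids)
    pops = np.unique(pop_ids)
    G, P = len(groups), len(pops)

    def ss(idx: np.ndarray) -> float:
        if len(idx) == 0:
            return 0.0
        sub = d2[np.ix_(idx, idx)]
        return sub.sum() / (2.0 * len(idx))

    ss_total = ss(np.arange(N))
    ss_wp = sum(ss(np.where(pop_ids == p)[0]) for p in pops)
    ss_wg = sum(ss(np.where(group_ids == gl)[0]) for gl in groups)
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    if df_ap <= 0 or df_wp <= 0 or df_ag <= 0:
        raise ValueError("AMOVA needs >=2 groups, more pops than groups, and replication")
    ms_ag, ms_ap, ms_wp = ss_ag / df_ag, ss_ap / df_ap, ss_wp / df_wp

    # coefficients (Excoffier-style moment estimators)
    n_p = np.array([np.sum(pop_ids == p) for p in pops], dtype=float)
    grp_of_pop = np.array(
        [group_ids[np.where(pop_ids == p)[0][0]] for p in pops]
    )
    sum_by_group = {
        gl: n_p[grp_of_pop == gl] for gl in groups
    }
    if any(v.size == 0 for v in sum_by_group.values()):
        raise ValueError("a group contains no population")
    t1 = sum((v**2).sum() / v.sum() for v in sum_by_group.values())
    n_coef = (N - t1) / (P - G)
    n_coef_p = (t1 - (n_p**2).sum() / N) / (G - 1)
    n_coef_pp = (N - sum(v.sum() ** 2 for v in sum_by_group.values()) / N) / (G - 1)

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_coef
    sigma_a = (ms_ag - sigma_c - n_coef_p * sigma_b) / n_coef_pp
    clamped = False
    if sigma_b < 0:
        sigma_b, clamped = 0.0, True
    if sigma_a < 0:
        sigma_a, clamped = 0.0, True
    total = sigma_a + sigma_b + sigma_c
    if total <= 0:
        return 0.0, 0.0, 0.0, (0.0, 0.0, 0.0), clamped
    f_ct = sigma_a / total
    f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0
    f_st = (sigma_a + sigma_b) / total
    return sigma_a, sigma_b, sigma_c, (f_ct, f_sc, f_st), clamped


def amova_two_level(
    g: GenotypeMatrix,
    species_of: Mapping[str, str],
    pop_of: Mapping[str, str],
    n_perm: int = 199,
    seed: int = 0,
) -> VarianceComponents:
    """Hierarchical AMOVA: species groups / populations within species / individuals.

    Sums of squares come from the pairwise allele-mismatch distance;
    p-values from permuting (for F_SC) individuals among populations within
    their species, (for F_CT) whole populations among species, and (for
    F_ST) individuals among populations without restriction. Negative
    variance components are clamped to zero and flagged.
    """
    inds = g.individuals
    group_ids = np.repeat(np.array([species_of[i] for i in inds]), 2)
    pop_ids = np.repeat(np.array([pop_of[i] for i in inds]), 2)
    d2 = _pairwise_sq_distance(g)
    sa, sb, sc, (f_ct, f_sc, f_st), clamped = _amova_f(d2, group_ids, pop_ids)
    total = sa + sb + sc
    pct = (
        (100 * sa / total, 100 * sb / total, 100 * sc / total)
        if total > 0
        else (0.0, 0.0, 100.0)
    )

    p_ct = p_sc = p_st = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        ge_ct = ge_sc = ge_st = 0
        ind_group = np.array([species_of[i] for i in inds])
        ind_pop = np.array([pop_of[i] for i in inds])
        pops = np.unique(ind_pop)
        grp_of_pop = {
            p: ind_group[np.where(ind_pop == p)[0][0]] for p in pops
        }
        for _ in range(n_perm):
            # F_SC: shuffle individuals among pops within each species
            perm_pop = ind_pop.copy()
            for gl in np.unique(ind_group):
                idx = np.where(ind_group == gl)[0]
                perm_pop[idx] = perm_pop[rng.permutation(idx)]
            _, _, _, (pc, psc, pst), _ = _amova_f(
                d2, group_ids, np.repeat(perm_pop, 2)
            )
            if psc >= f_sc - 1e-12:
                ge_sc += 1
            # F_CT: shuffle whole pops among species
            perm_grp_of_pop = rng.permutation([grp_of_pop[p] for p in pops])
            mapping = dict(zip(pops, perm_grp_of_pop))
            perm_group = np.array([mapping[p] for p in ind_pop])
            try:
                _, _, _, (pct_f, _, _), _ = _amova_f(
                    d2, np.repeat(perm_group, 2), pop_ids
                )
            except ValueError:
                pct_f = f_ct  # degenerate permutation (all pops in one group)
            if pct_f >= f_ct - 1e-12:
                ge_ct += 1
            # F_ST: shuffle individuals among pops freely
            perm_pop2 = ind_pop[rng.permutation(len(ind_pop))]
            try:
                _, _, _, (_, _, pst2), _ = _amova_f(
                    d2, group_ids, np.repeat(perm_pop2, 2)
                )
            except ValueError:
                pst2 = f_st  # degenerate permutation
            if pst2 >= f_st - 1e-12:
                ge_st += 1
        p_ct = (ge_ct + 1) / (n_perm + 1)
        p_sc = (ge_sc + 1) / (n_perm + 1)
        p_st = (ge_st + 1) / (n_perm + 1)

    return VarianceComponents(
        sigma_among_groups=sa,
        sigma_among_pops=sb,
        sigma_within=sc,
        pct_among_groups=pct[0],
        pct_among_pops=pct[1],
        pct_within=pct[2],
        F_CT=f_ct,
        F_SC=f_sc,
        F_ST=f_st,
        p_F_CT=p_ct,
        p_F_SC=p_sc,
        p_F_ST=p_st,
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# Nei's standard distance and UPGMA
# ---------------------------------------------------------------------------


def nei_standard_distance(
    fA: AlleleFrequencyTable, fB: AlleleFrequencyTable
) -> float:
    """Nei's (1972) standard genetic distance D = -ln(J_AB / sqrt(J_A J_B)).

    The gene identities J are summed over shared loci before the ratio.
    Returns ``math.inf`` when the groups share no alleles at any locus.
    """
    shared = [
        l for l in fA.loci
        if l in set(fB.loci) and fA.freqs[l] and fB.freqs[l]
    ]
    if not shared:
        raise ValueError("no shared typed loci")
    jab = ja = jb = 0.0
    for locus in shared:
        pa, pb = fA.freqs[locus], fB.freqs[locus]
        ja += sum(p * p for p in pa.values())
        jb += sum(p * p for p in pb.values())
        jab += sum(pa[a] * pb.get(a, 0.0) for a in pa)
    if jab == 0.0:
        return math.inf
    return -math.log(jab / math.sqrt(ja * jb))


@dataclass
class GeneticDistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    metric: str = "Nei-1972"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(m)
        if not np.allclose(m[finite & finite.T], m.T[finite & finite.T]):
            raise ValueError("matrix must be symmetric")
        if (m[np.isfinite(m)] < 0).any():
            raise ValueError("distances must be non-negative")

    def to_phylip(self) -> str:
        lines = [str(len(self.labels))]
        for i, lab in enumerate(self.labels):
            row = " ".join(f"{x:.6f}" for x in self.matrix[i])
            lines.append(f"{lab:<10s} {row}")
        return "\n".join(lines) + "\n"


def nei_distance_matrix(
    tables: Mapping[str, AlleleFrequencyTable], cap: float | None = None
) -> GeneticDistanceMatrix:
    labels = list(tables)
    m = len(labels)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = nei_standard_distance(tables[labels[i]], tables[labels[j]])
            if math.isinf(d):
                if cap is None:
                    D[i, j] = D[j, i] = math.inf
                    continue
                d = cap
            D[i, j] = D[j, i] = d
    return GeneticDistanceMatrix(labels, D)


@dataclass
class Tree:
    """Rooted ultrametric tree node (leaf when ``children`` is empty)."""

    label: str | None = None
    height: float = 0.0
    children: list["Tree"] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset([self.label])  # type: ignore[list-item]
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.leaves()
        return out

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        out = []
        if self.children:
            out.append(self.leaves())
            for c in self.children:
                out.extend(c.clades())
        return out

    def internal_nodes(self) -> list["Tree"]:
        out = []
        if self.children:
            out.append(self)
            for c in self.children:
                out.extend(c.internal_nodes())
        return out

    def newick(self, parent_height: float | None = None) -> str:
        bl = (
            ""
            if parent_height is None
            else f":{parent_height - self.height:.6f}"
        )
        if not self.children:
            return f"{self.label}{bl}"
        inner = ",".join(c.newick(self.height) for c in self.children)
        sup = "" if self.support is None else f"{self.support:.3f}"
        if parent_height is None:
            return f"({inner}){sup};"
        return f"({inner}){sup}{bl}"


def upgma(d: GeneticDistanceMatrix) -> Tree:
    """Average-linkage (UPGMA) clustering into an ultrametric rooted tree.

    Node heights are half the inter-cluster distance. Ties at the minimum
    are broken by the lexicographically smallest pair of cluster
    representative labels (the smallest leaf label of each cluster).
    """
    if len(d.labels) < 2:
        raise ValueError("need >= 2 labels")
    if not np.isfinite(d.matrix).all():
        raise ValueError(
            "distance matrix contains infinite entries; cap them first "
            "(e.g. nei_distance_matrix(..., cap=...))"
        )
    nodes: dict[int, Tree] = {
        i: Tree(label=lab) for i, lab in enumerate(d.labels)
    }
    sizes = {i: 1 for i in nodes}
    reps = {i: lab for i, lab in enumerate(d.labels)}
    dist: dict[tuple[int, int], float] = {}
    m = len(d.labels)
    for i in range(m):
        for j in range(i + 1, m):
            dist[(i, j)] = float(d.matrix[i, j])
    next_id = m
    active = set(nodes)
    while len(active) > 1:
        best = None
        for (i, j), v in dist.items():
            key = (v, tuple(sorted((reps[i], reps[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best  # type: ignore[misc]
        dij = dist[(i, j)]
        new = Tree(height=dij / 2.0, children=[nodes[i], nodes[j]])
        nid = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(nid, k), max(nid, k))] = dnew
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        active -= {i, j}
        active.add(nid)
        nodes[nid] = new
        sizes[nid] = sizes[i] + sizes[j]
        reps[nid] = min(reps[i], reps[j])
    return nodes[next_id - 1]


def bootstrap_upgma(
    g: GenotypeMatrix,
    grouping: Mapping[str, str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> Tree:
    """UPGMA on Nei distances between groups, with locus-bootstrap node support.

    Loci are resampled with replacement ``n_boot`` times; each node's
    support is the fraction of replicate trees containing the same leaf
    set. Infinite replicate distances (no shared alleles in the resampled
    loci) are capped at twice the largest finite distance so the replicate
    still yields a topology.
    """
    if g.n_loci < 2:
        raise ValueError("bootstrap over loci needs >= 2 loci")
    freqs = allele_frequencies(g, grouping)
    full = nei_distance_matrix(freqs)
    if not np.isfinite(full.matrix).all():
        finite_max = np.nanmax(full.matrix[np.isfinite(full.matrix)])
        full = nei_distance_matrix(freqs, cap=2.0 * max(finite_max, 1.0))
    tree = upgma(full)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {c: 0 for c in tree.clades()}
    for _ in range(n_boot):
        loci = [g.loci[k] for k in rng.integers(0, g.n_loci, size=g.n_loci)]
        # resample loci with replacement; duplicated loci need unique names
        sub_calls = np.stack(
            [g.calls[:, g.loci.index(l), :] for l in loci], axis=1
        )
        names = [f"{l}#{k}" for k, l in enumerate(loci)]
        gb = GenotypeMatrix(g.individuals, names, sub_calls, dict(g.group_of))
        fb = allele_frequencies(gb, grouping)
        db = nei_distance_matrix(fb, cap=None)
        if not np.isfinite(db.matrix).all():
            finite = db.matrix[np.isfinite(db.matrix)]
            cap = 2.0 * max(finite.max() if finite.size else 1.0, 1.0)
            db = nei_distance_matrix(fb, cap=cap)
        bt = upgma(db)
        bclades = set(bt.clades())
        for c in counts:
            if c in bclades:
                counts[c] += 1
    for node in tree.internal_nodes():
        node.support = counts[node.leaves()] / n_boot
    return tree


# ---------------------------------------------------------------------------
# permutation tests and multiple-testing correction
# ---------------------------------------------------------------------------


def hwe_test(
    g: GenotypeMatrix,
    group: str,
    locus: str,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation test of Hardy-Weinberg proportions at one locus.

    Statistic: |Ho - He| (unbiased He; constant across permutations since
    allele counts are conserved, so in effect the permutation distribution
    of Ho is compared with its observed value, two-sided around He).
    Allele copies are shuffled into new genotypes ``n_perm`` times. Because
    Ho is discrete, ties between permuted and observed statistics are
    frequent; they are broken by a seeded uniform draw (the randomized
    permutation p-value), which makes the null distribution of p exactly
    uniform. Monomorphic data return p = 1.
    """
    idx = [i for i, ind in enumerate(g.individuals) if g.group_of.get(ind) == group]
    j = g.loci.index(locus)
    pairs = g.calls[idx, j, :]
    typed = pairs[pairs[:, 0] != MISSING]
    n = len(typed)
    if n < 5:
        raise ValueError("need >= 5 typed individuals")
    copies = typed.ravel().astype(np.int64)
    if len(np.unique(copies)) < 2:
        return 1.0

    def stat(arr: np.ndarray) -> float:
        pairs2 = arr.reshape(-1, 2)
        ho = float((pairs2[:, 0] != pairs2[:, 1]).mean())
        _, cnts = np.unique(arr, return_counts=True)
        p = cnts / cnts.sum()
        he = 2.0 * n / (2.0 * n - 1.0) * (1.0 - float((p**2).sum()))
        return abs(ho - he)

    obs = stat(copies)
    rng = np.random.default_rng(seed)
    greater = ties = 0
    work = copies.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        s = stat(work)
        if s > obs + 1e-12:
            greater += 1
        elif s >= obs - 1e-12:
            ties += 1
    u = rng.random()
    p = (greater + u * (ties + 1)) / (n_perm + 1)
    return min(p, 1.0)


def g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio statistic on a contingency table (zero cells drop out)."""
    O = np.asarray(table, dtype=float)
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
    return float(2.0 * xlogy(O, O / np.where(E > 0, E, 1.0)).sum())


def ld_test(
    g: GenotypeMatrix,
    group: str,
    locusA: str,
    locusB: str,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation test of gametic disequilibrium between two loci.

    Statistic: G on the genotype-by-genotype contingency table over
    individuals typed at both loci; locus B genotypes are permuted across
    individuals. Returns the add-one-corrected p-value.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    idx = [i for i, ind in enumerate(g.individuals) if g.group_of.get(ind) == group]
    ja, jb = g.loci.index(locusA), g.loci.index(locusB)
    A = g.calls[idx, ja, :]
    B = g.calls[idx, jb, :]
    keep = (A[:, 0] != MISSING) & (B[:, 0] != MISSING)
    A, B = A[keep], B[keep]
    if len(A) < 5:
        raise ValueError("insufficient jointly typed individuals")

    def codes(X: np.ndarray) -> np.ndarray:
        _, inv = np.unique(X, axis=0, return_inverse=True)
        return inv

    ca, cb = codes(A), codes(B)
    ka, kb = ca.max() + 1, cb.max() + 1
    if ka < 2 or kb < 2:
        raise ValueError("both loci must be polymorphic in the group")

    def stat(cb_perm: np.ndarray) -> float:
        tab = np.zeros((ka, kb))
        np.add.at(tab, (ca, cb_perm), 1)
        return g_statistic(tab)

    obs = stat(cb)
    rng = np.random.default_rng(seed)
    ge = 0
    work = cb.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if stat(work) >= obs - 1e-12:
            ge += 1
    return (ge + 1) / (n_perm + 1)


def sequential_bonferroni(
    pvals: Sequence[float], alpha: float = 0.05
) -> list[bool]:
    """Holm's sequentially rejective Bonferroni procedure.

    Sort p-values ascending and reject while p_(i) <= alpha / (m - i + 1)
    (1-based i); the first failure stops all further rejections. Returns
    rejection flags in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject.tolist()
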