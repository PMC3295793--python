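"""mtDNA barcoding statistics: haplotypes, K2P divergence, nucleotide diversity.

Species delimitation by DNA barcoding rests on the "barcoding gap": the
divergence between candidate species groups is one to two orders of
magnitude larger than the divergence among individuals within a group.
This module provides the pieces needed to measure that gap on an aligned
mitochondrial fragment (here COI or cyt b):

* collapsing identical sequences into haplotypes with multiplicities,
* Kimura two-parameter (K2P) distances, which correct transitions and
  transversions separately,
* count-weighted mean intra- and inter-group divergence,
* nucleotide diversity (pi),
* fixed differences between groups, and
* haplogroup delimitation by single-linkage clustering at a distance
  threshold (default 0.02, the classic barcoding-gap heuristic).

Sites containing N or a gap in either sequence of a pair are excluded
pairwise (not alignment-wide), matching the default of the MEGA-style
toolchain this mirrors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data import SequenceAlignment

__all__ = [
    "HaplotypeTable",
    "K2PResult",
    "SaturationError",
    "collapse_haplotypes",
    "k2p_distance",
    "group_divergence",
    "nucleotide_diversity",
    "fixed_differences",
    "assign_haplogroups",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: too many differences for the correction."""


@dataclass
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: float  # K2P distance
    sites_compared: int


@dataclass
class HaplotypeTable:
    """Distinct sequences with the number of individuals carrying each."""

    haplotypes: dict[str, str]
    count: dict[str, int]
    group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.count.values()):
            raise ValueError("haplotype counts must be >= 1")
        seqs = list(self.haplotypes.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("haplotype sequences must be distinct")

    @property
    def n_individuals(self) -> int:
        return sum(self.count.values())

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def collapse_haplotypes(
    aln: SequenceAlignment, grouping: Mapping[str, str] | None = None
) -> HaplotypeTable:
    """Merge identical aligned sequences into haplotypes.

    Haplotype IDs are ``H1, H2, ...`` in order of first occurrence. When a
    ``grouping`` (sequence ID -> label) is given, each haplotype inherits
    the group of its carriers; carriers from several groups raise an error
    because a barcoding haplotype shared between groups has no single
    group label.
    """
    seen: dict[str, str] = {}
    haplotypes: dict[str, str] = {}
    count: dict[str, int] = {}
    group: dict[str, str] = {}
    for rid, seq in aln.records.items():
        if seq not in seen:
            hid = f"H{len(seen) + 1}"
            seen[seq] = hid
            haplotypes[hid] = seq
            count[hid] = 0
        hid = seen[seq]
        count[hid] += 1
        if grouping is not None:
            g = grouping[rid]
            if hid in group and group[hid] != g:
                raise ValueError(f"haplotype {hid} carried by multiple groups")
            group[hid] = g
    return HaplotypeTable(haplotypes, count, group)


def k2p_distance(s1: str, s2: str) -> K2PResult:
    """Kimura two-parameter distance between two aligned sequences.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q), with P and Q the proportions
    of sites showing a transition and a transversion respectively, over the
    sites where both sequences carry an unambiguous base.
    """
    if len(s1) != len(s2):
        raise ValueError("sequences must be aligned to equal length")
    s1, s2 = s1.upper(), s2.upper()
    n = ts = tv = 0
    for a, b in zip(s1, s2):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P correction undefined (P={P:.4f}, Q={Q:.4f}): sequences saturated"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, d=d, sites_compared=n)


def _pairwise_d(tab: HaplotypeTable) -> tuple[list[str], np.ndarray]:
    ids = list(tab.haplotypes)
    m = len(ids)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = k2p_distance(
                tab.haplotypes[ids[i]], tab.haplotypes[ids[j]]
            ).d
    return ids, D


def group_divergence(
    tab: HaplotypeTable,
    grouping: Mapping[str, str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, tuple[float, float]], tuple[float, float]]:
    """Count-weighted mean K2P divergence within and between groups.

    The mean is over individual pairs: haplotype pairs are weighted by the
    product of their carrier counts, and within-group self pairs use
    count*(count-1)/2. Standard errors come from a seeded nonparametric
    bootstrap over alignment columns.

    Returns ``(intra, inter)`` where ``intra`` maps group label to
    ``(mean, se)`` and ``inter`` is the between-group ``(mean, se)``.
    """
    grouping = dict(grouping) if grouping is not None else dict(tab.group)
    ids = list(tab.haplotypes)
    if not all(h in grouping for h in ids):
        raise ValueError("every haplotype needs a group label")
    L = len(next(iter(tab.haplotypes.values())))
    rng = np.random.default_rng(seed)

    def _means(cols: np.ndarray | None) -> tuple[dict[str, float], float]:
        def dist(h1: str, h2: str) -> float:
            a, b = tab.haplotypes[h1], tab.haplotypes[h2]
            if cols is not None:
                a = "".join(a[c] for c in cols)
                b = "".join(b[c] for c in cols)
            return k2p_distance(a, b).d

        intra_num: dict[str, float] = {}
        intra_den: dict[str, float] = {}
        inter_num = inter_den = 0.0
        for i, h1 in enumerate(ids):
            c1, g1 = tab.count[h1], grouping[h1]
            w_self = c1 * (c1 - 1) / 2.0
            if w_self > 0:
                intra_den[g1] = intra_den.get(g1, 0.0) + w_self
                intra_num.setdefault(g1, 0.0)
            for h2 in ids[i + 1 :]:
                c2, g2 = tab.count[h2], grouping[h2]
                w = c1 * c2
                d = dist(h1, h2)
                if g1 == g2:
                    intra_num[g1] = intra_num.get(g1, 0.0) + w * d
                    intra_den[g1] = intra_den.get(g1, 0.0) + w
                else:
                    inter_num += w * d
                    inter_den += w
        intra = {
            g: (intra_num.get(g, 0.0) / den if den > 0 else 0.0)
            for g, den in intra_den.items()
        }
        inter = inter_num / inter_den if inter_den > 0 else float("nan")
        return intra, inter

    intra_mean, inter_mean = _means(None)
    boot_intra: dict[str, list[float]] = {g: [] for g in intra_mean}
    boot_inter: list[float] = []
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        bi, be = _means(cols)
        for g in boot_intra:
            boot_intra[g].append(bi.get(g, 0.0))
        boot_inter.append(be)
    intra = {
        g: (m, float(np.std(boot_intra[g], ddof=1)) if n_boot > 1 else 0.0)
        for g, m in intra_mean.items()
    }
    inter_se = float(np.std(boot_inter, ddof=1)) if n_boot > 1 else 0.0
    return intra, (inter_mean, inter_se)


def nucleotide_diversity(tab: HaplotypeTable) -> float:
    """Nei's nucleotide diversity pi with the small-sample (n/(n-1)) factor.

    pi = n/(n-1) * sum_{i != j} x_i x_j pi_ij, where x are haplotype
    relative frequencies and pi_ij the per-site difference proportion
    (sites with N or a gap in either haplotype excluded pairwise).
    """
    n = tab.n_individuals
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 individuals")
    ids = list(tab.haplotypes)
    x = np.array([tab.count[h] / n for h in ids])
    total = 0.0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = tab.haplotypes[ids[i]], tab.haplotypes[ids[j]]
            comp = diff = 0
            for ca, cb in zip(a, b):
                if ca in _VALID and cb in _VALID:
                    comp += 1
                    if ca != cb:
                        diff += 1
            pij = diff / comp if comp else 0.0
            total += 2.0 * x[i] * x[j] * pij
    return n / (n - 1) * total


def fixed_differences(
    aln: SequenceAlignment, groupA: list[str], groupB: list[str]
) -> int:
    """Number of alignment columns where the two groups share no base.

    N and gap characters are ignored; a column where one group carries
    only ambiguous states is not counted.
    """
    if not groupA or not groupB:
        raise ValueError("both groups must be non-empty")
    seqsA = [aln.records[r] for r in groupA]
    seqsB = [aln.records[r] for r in groupB]
    count = 0
    for col in range(aln.length):
        a = {s[col] for s in seqsA} & _VALID
        b = {s[col] for s in seqsB} & _VALID
        if a and b and not (a & b):
            count += 1
    return count


def assign_haplogroups(tab: HaplotypeTable, threshold: float = 0.02) -> dict[str, str]:
    """Cluster haplotypes into haplogroups by single linkage cut at a K2P threshold.

    Clusters are labelled ``G1, G2, ...`` in order of descending total
    carrier count (ties broken by first occurrence).
    """
    ids, D = _pairwise_d(tab)
    m = len(ids)
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            if D[i, j] <= threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(m):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(
        clusters.values(),
        key=lambda mem: (-sum(tab.count[ids[i]] for i in mem), mem[0]),
    )
    labels: dict[str, str] = {}
    for rank, mem in enumerate(ordered, start=1):
        for i in mem:
            labels[ids[i]] = f"G{rank}"
    return labels
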