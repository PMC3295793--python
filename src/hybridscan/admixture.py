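"""Bayesian admixture inference on multilocus genotypes (Gibbs sampler).

The model is the classic admixture model for unlinked codominant markers:
each allele copy in individual i originates from cluster k with
probability q_ik, and an allele copy from cluster k at locus j is allele a
with probability p_kja. Priors are independent Dirichlet: q_i ~ Dir(alpha)
(alpha = 1 by default, fixed, not inferred) and p_kj ~ Dir(lambda = 1).
Cluster allele frequencies are independent across clusters (the
uncorrelated-frequencies model); for strongly diverged clusters -- the
use case here is two species with F_ST around 0.25-0.3 -- assignment is
insensitive to the correlated/uncorrelated choice.

Gibbs sweeps alternate: (1) the latent cluster origin Z of every allele
copy given (q, p); (2) cluster allele frequencies p given Z; (3) admixture
proportions q given Z. The reported Q is the posterior mean of q over
post-burn-in sweeps. Missing genotypes contribute nothing to the
likelihood and are never imputed.

With L fully diagnostic loci the origins of all 2L copies of a purebred
are forced, so its posterior mean q is analytically (2L + alpha) /
(2L + K * alpha) -- a useful exactness check on the sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import MISSING, GenotypeMatrix

__all__ = ["AdmixtureResult", "gibbs_admixture", "align_runs"]


@dataclass
class AdmixtureResult:
    """Posterior-mean membership proportions from one or more chains."""

    individuals: list[str]
    Q: np.ndarray  # (n_individuals, K) posterior means, rows sum to 1
    K: int
    cluster_freqs: list[dict] = field(default_factory=list)
    # per locus: {"locus": name, "alleles": [labels], "P": (K, n_alleles) mean freqs}
    loglik_trace: np.ndarray | None = None
    n_runs: int = 1
    replicate_Q: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (len(self.individuals), self.K):
            raise ValueError("Q shape mismatch")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        if ((self.Q < -1e-12) | (self.Q > 1 + 1e-12)).any():
            raise ValueError("Q entries must lie in [0, 1]")

    def q_of(self, individual: str) -> np.ndarray:
        return self.Q[self.individuals.index(individual)]

    def to_frame(self):
        import pandas as pd

        cols = {f"q{k + 1}": self.Q[:, k] for k in range(self.K)}
        return pd.DataFrame({"individual": self.individuals, **cols,
                             "n_runs": self.n_runs})


def _encode(g: GenotypeMatrix) -> tuple[list[np.ndarray], list[list[int]]]:
    """Per locus: allele-index array (n, 2) with -1 for missing, and labels."""
    aidx: list[np.ndarray] = []
    labels: list[list[int]] = []
    for j in range(g.n_loci):
        col = g.calls[:, j, :]
        present = np.unique(col[col != MISSING])
        lab = [int(a) for a in present]
        lookup = {a: i for i, a in enumerate(lab)}
        idx = np.full(col.shape, -1, dtype=np.int64)
        for a, i in lookup.items():
            idx[col == a] = i
        aidx.append(idx)
        labels.append(lab)
    return aidx, labels


def gibbs_admixture(
    g: GenotypeMatrix,
    K: int = 2,
    burnin: int = 2000,
    sweeps: int = 8000,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
    record_loglik: bool = False,
) -> AdmixtureResult:
    """Run one Gibbs chain of the admixture model and return posterior-mean Q.

    Parameters mirror the standard tool's knobs: ``burnin`` discarded
    sweeps, ``sweeps`` retained sweeps, Dirichlet hyper-parameters
    ``alpha`` (individual admixture) and ``lam`` (cluster allele
    frequencies). Individuals with no typed locus are excluded with a
    warning. Same seed, same data => bit-identical output.
    """
    if g.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    typed_any = ~g.missing_mask().all(axis=1)
    if not typed_any.all():
        dropped = [ind for ind, t in zip(g.individuals, typed_any) if not t]
        warnings.warn(f"excluding all-missing individuals: {dropped}")
        g = g.subset(
            individuals=[i for i, t in zip(g.individuals, typed_any) if t]
        )
    aidx, labels = _encode(g)
    if all(len(l) < 2 for l in labels):
        raise ValueError("need at least one polymorphic locus")
    n, L = g.n_individuals, g.n_loci
    rng = np.random.default_rng(seed)

    masks = [ix >= 0 for ix in aidx]  # (n, 2) typed mask per locus
    Z = [rng.integers(0, K, size=(n, 2)) for _ in range(L)]
    q = rng.dirichlet(np.full(K, alpha), size=n)
    P = [
        rng.dirichlet(np.full(max(len(lab), 1), lam), size=K)
        for lab in labels
    ]

    q_sum = np.zeros((n, K))
    p_sum = [np.zeros_like(Pj) for Pj in P]
    loglik: list[float] = []

    for sweep in range(burnin + sweeps):
        # (1) latent origins Z
        counts_q = np.zeros((n, K))
        for j in range(L):
            ix, mask = aidx[j], masks[j]
            safe = np.where(ix >= 0, ix, 0)
            W = q[:, None, :] * P[j].T[safe, :]  # (n, 2, K)
            W = np.where(mask[:, :, None], W, 1.0 / K)
            cum = np.cumsum(W, axis=2)
            u = rng.random((n, 2, 1)) * cum[:, :, -1:]
            Zj = (u > cum).sum(axis=2)
            Z[j] = Zj
            for k in range(K):
                counts_q[:, k] += ((Zj == k) & mask).sum(axis=1)
        # (2) cluster allele frequencies
        for j in range(L):
            m = len(labels[j])
            if m == 0:
                continue
            cnt = np.zeros((K, m))
            ix, mask = aidx[j], masks[j]
            for k in range(K):
                sel = (Z[j] == k) & mask
                if sel.any():
                    cnt[k] = np.bincount(ix[sel], minlength=m)
            Gm = rng.gamma(lam + cnt)
            P[j] = Gm / Gm.sum(axis=1, keepdims=True)
        # (3) admixture proportions
        Gq = rng.gamma(alpha + counts_q)
        q = Gq / Gq.sum(axis=1, keepdims=True)

        if sweep >= burnin:
            q_sum += q
            for j in range(L):
                p_sum[j] += P[j]
        if record_loglik:
            ll = 0.0
            for j in range(L):
                ix, mask = aidx[j], masks[j]
                safe = np.where(ix >= 0, ix, 0)
                lik = (q[:, None, :] * P[j].T[safe, :]).sum(axis=2)
                ll += float(np.log(lik[mask]).sum())
            loglik.append(ll)

    Q = q_sum / sweeps
    Q = Q / Q.sum(axis=1, keepdims=True)
    cluster_freqs = [
        {"locus": g.loci[j], "alleles": labels[j], "P": p_sum[j] / sweeps}
        for j in range(L)
    ]
    return AdmixtureResult(
        individuals=list(g.individuals),
        Q=Q,
        K=K,
        cluster_freqs=cluster_freqs,
        loglik_trace=np.array(loglik) if record_loglik else None,
        n_runs=1,
        replicate_Q=[Q.copy()],
    )


def align_runs(results: Sequence[AdmixtureResult]) -> AdmixtureResult:
    """Align replicate chains' cluster labels against run 1 and average Q.

    For K = 2 the alignment is exact: per run, pick the label permutation
    (identity or swap) maximising sum_i q_i . q_ref,i. For K > 2 a greedy
    column matching is used. This is the label-averaging step usually done
    with CLUMPP.
    """
    if not results:
        raise ValueError("no runs to align")
    ref = results[0]
    for r in results[1:]:
        if r.individuals != ref.individuals or r.K != ref.K:
            raise ValueError("runs must share individuals and K")
    K = ref.K
    aligned = [ref.Q]
    for r in results[1:]:
        if K == 2:
            agree_id = float((r.Q * ref.Q).sum())
            agree_sw = float((r.Q[:, ::-1] * ref.Q).sum())
            aligned.append(r.Q if agree_id >= agree_sw else r.Q[:, ::-1])
        else:
            perm: list[int] = []
            remaining = list(range(K))
            for k in range(K):
                scores = [float(r.Q[:, c] @ ref.Q[:, k]) for c in remaining]
                pick = remaining[int(np.argmax(scores))]
                perm.append(pick)
                remaining.remove(pick)
            aligned.append(r.Q[:, perm])
    Q = np.mean(aligned, axis=0)
    Q = Q / Q.sum(axis=1, keepdims=True)
    return AdmixtureResult(
        individuals=list(ref.individuals),
        Q=Q,
        K=K,
        cluster_freqs=ref.cluster_freqs,
        n_runs=len(results),
        replicate_Q=[np.asarray(a) for a in aligned],
    )
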