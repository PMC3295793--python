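"""Phenotype-vs-genotype concordance and distributional statistics.

Field identification of the two species relies on morphology, which is
unreliable; molecular classification provides the reference. This module
quantifies the disagreement: McNemar's symmetry test on the discordant
counts (is misidentification symmetric between species?), a G-test of
independence on species-by-region abundance tables, Fisher's exact test
for 2x2 composition comparisons, and agreement tables with per-class
percentage agreement. It also carries the morphometric formulas used to
standardise body size: the total-length to fork-length conversion and
Fulton's condition factor K = W / F_L^3 * 10^4.

Convention notes: McNemar is computed without continuity correction and
the G-test without Williams correction, matching how these statistics are
conventionally reported in this literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "ContingencyTable",
    "MorphoDerived",
    "mcnemar",
    "g_test",
    "fisher_exact_2x2",
    "agreement_table",
    "tl_to_fl",
    "fit_length_conversion",
    "fulton_k",
    "TL_TO_FL_INTERCEPT",
    "TL_TO_FL_SLOPE",
]

# empirical total-length -> fork-length conversion (fitted on matched pairs)
TL_TO_FL_INTERCEPT = -3.076
TL_TO_FL_SLOPE = 0.945


@dataclass
class ContingencyTable:
    rows: list[str]
    cols: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.rows), len(self.cols)):
            raise ValueError("counts shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class MorphoDerived:
    intercept: float
    slope: float
    r_squared: float


def mcnemar(b: int, c: int) -> tuple[float, int, float]:
    """McNemar symmetry test on the two discordant counts (no continuity correction).

    chi^2 = (b - c)^2 / (b + c) with 1 degree of freedom.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        raise ValueError("test undefined: no discordant pairs")
    stat = (b - c) ** 2 / (b + c)
    p = float(chi2.sf(stat, 1))
    return float(stat), 1, p


def g_test(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """G-test of independence: G = 2 sum O ln(O/E), df = (r-1)(c-1).

    Zero observed cells contribute nothing; a zero marginal makes the
    expected counts degenerate and raises. No Williams correction.
    """
    O = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, float)
    O = O.astype(float)
    rs, cs = O.sum(axis=1), O.sum(axis=0)
    if (rs == 0).any() or (cs == 0).any():
        raise ValueError("zero marginal: G-test undefined")
    E = np.outer(rs, cs) / O.sum()
    G = float(2.0 * xlogy(O, O / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return G, df, float(chi2.sf(G, df))


def fisher_exact_2x2(table: ContingencyTable | np.ndarray) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table (two-sided, probability-mass method).

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose point probability does not exceed the observed
    table's. Returns (odds ratio, p). Degenerate margins give p = 1.
    """
    O = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    O = np.asarray(O, dtype=np.int64)
    if O.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (O.sum(axis=0) == 0).any() or (O.sum(axis=1) == 0).any():
        a, b, c, d = O.ravel()
        orr = (a * d / (b * c)) if b * c > 0 else float("inf")
        return float(orr), 1.0
    orr, p = _scipy_fisher(O, alternative="two-sided")
    return float(orr), float(p)


def agreement_table(
    pairs: Sequence[tuple[str, str]] | Mapping[str, tuple[str, str]],
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> tuple[ContingencyTable, dict[str, float], dict[str, float]]:
    """Cross-tabulate molecular (rows) vs phenotype (columns) labels.

    ``pairs`` holds (molecular label, phenotype label) per individual.
    Returns the table plus per-row and per-column percentage agreement,
    defined as the diagonal share of each margin where the label exists on
    both axes.
    """
    if isinstance(pairs, Mapping):
        pairs = list(pairs.values())
    rows = list(row_order) if row_order else sorted({m for m, _ in pairs})
    cols = list(col_order) if col_order else sorted({p for _, p in pairs})
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for m, p in pairs:
        counts[rows.index(m), cols.index(p)] += 1
    tab = ContingencyTable(rows, cols, counts)
    row_pct: dict[str, float] = {}
    for i, r in enumerate(rows):
        tot = counts[i].sum()
        if r in cols and tot > 0:
            row_pct[r] = 100.0 * counts[i, cols.index(r)] / tot
    col_pct: dict[str, float] = {}
    for j, c in enumerate(cols):
        tot = counts[:, j].sum()
        if c in rows and tot > 0:
            col_pct[c] = 100.0 * counts[rows.index(c), j] / tot
    return tab, row_pct, col_pct


def tl_to_fl(T_L: float) -> float:
    """Convert total length (mm) to fork length (mm) by the standard line."""
    if not T_L > 0:
        raise ValueError("total length must be positive")
    return TL_TO_FL_INTERCEPT + TL_TO_FL_SLOPE * T_L


def fit_length_conversion(
    pairs: Sequence[tuple[float, float]]
) -> MorphoDerived:
    """Ordinary least squares fit of fork length on total length."""
    if len(pairs) < 3:
        raise ValueError("need >= 3 (T_L, F_L) pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("lengths must be positive")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MorphoDerived(intercept=float(intercept), slope=float(slope), r_squared=r2)


def fulton_k(W_t: float, F_L: float) -> float:
    """Fulton's condition factor K = W_t / F_L^3 * 10,000 (weight g, length mm)."""
    if not (W_t > 0 and F_L > 0):
        raise ValueError("weight and length must be positive")
    return W_t / F_L**3 * 10_000.0
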