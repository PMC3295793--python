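"""Published field-survey counts for the two-species system.

These are the molecularly classified counts from the published survey of
the two *Aplochiton* species (A. zebra and A. taeniatus) across Chilean
Patagonia and the Falkland Islands. They are inputs to the distributional
and concordance analyses: a species-by-region abundance table (hybrids
excluded), and the phenotype-vs-molecular classification table of all 456
matched samples.
"""

from __future__ import annotations

import numpy as np

from .concordance import ContingencyTable

__all__ = [
    "REGIONS",
    "regional_abundance_table",
    "phenotype_concordance_table",
    "MISIDENTIFIED_B",
    "TOTAL_GENETIC_B",
]

REGIONS = ["Mainland", "Chiloe", "E. Falkland", "W. Falkland"]

# molecularly classified individuals per species per region (hybrids excluded)
_ABUNDANCE = np.array(
    [
        [184, 131, 10, 12],  # A. zebra
        [1, 58, 44, 13],  # A. taeniatus
    ]
)

# phenotype (columns) vs molecular (rows) classification of matched samples
_CONCORDANCE = np.array(
    [
        [338, 0],  # molecular A. zebra:     phenotype zebra / taeniatus
        [85, 30],  # molecular A. taeniatus
        [2, 1],  # hybrids
    ]
)

MISIDENTIFIED_B = 85  # genetic A. taeniatus field-labelled as A. zebra
TOTAL_GENETIC_B = 115


def regional_abundance_table() -> ContingencyTable:
    """2x4 species-by-region table of molecularly classified individuals."""
    return ContingencyTable(
        rows=["A. zebra", "A. taeniatus"],
        cols=list(REGIONS),
        counts=_ABUNDANCE.copy(),
    )


def phenotype_concordance_table(include_hybrids: bool = True) -> ContingencyTable:
    """Molecular classification (rows) vs field phenotype (columns)."""
    counts = _CONCORDANCE.copy() if include_hybrids else _CONCORDANCE[:2].copy()
    rows = ["A. zebra", "A. taeniatus"] + (["hybrid"] if include_hybrids else [])
    return ContingencyTable(rows=rows, cols=["A. zebra", "A. taeniatus"], counts=counts)
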