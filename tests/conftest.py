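"""Shared fixtures: synthetic studies and profiles reused across test modules.

Expensive artefacts (the default 456-individual study and one full hybrid
scan) are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import hybridscan as hs


@pytest.fixture(scope="session")
def diagnostic_profile() -> hs.SpeciesProfile:
    """11 fully diagnostic loci: A fixed for 100, B fixed for 120 everywhere."""
    freqs: dict = {"A": {}, "B": {}}
    for j in range(11):
        locus = f"ms{j + 1:02d}"
        freqs["A"][locus] = {100: 1.0}
        freqs["B"][locus] = {120: 1.0}
    return hs.SpeciesProfile(freqs=freqs)


@pytest.fixture(scope="session")
def default_study() -> hs.StudyResult:
    return hs.make_study(hs.default_study_config(seed=3))


@pytest.fixture(scope="session")
def default_scan(default_study) -> hs.HybridScanResult:
    """One full hybrid scan of the default study at desk-scale MCMC settings."""
    tr = default_study.truth
    mtdna = dict(zip(tr["individual"], tr["maternal"]))
    phenotype = dict(zip(tr["individual"], tr["phenotype_label"]))
    return hs.run_hybrid_scan(
        default_study.genotypes,
        mtdna_species=mtdna,
        phenotype=phenotype,
        n_runs=3,
        burnin=300,
        sweeps=1200,
        cal_reps=5,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
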