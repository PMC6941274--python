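"""Shared synthetic cohorts (generated once per session) and helpers."""

import numpy as np
import pytest

import snpedigree as sp
from snpedigree.genotype_io import GenotypeMatrix, SNPPanel


def make_matrix(calls, ploidy=None, ids=None, chromosomes=None):
    """Tiny matrix from a nested list of dosages (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, s = calls.shape
    ids = ids or [f"I{k}" for k in range(n)]
    panel = SNPPanel(np.array([f"S{j}" for j in range(s)], dtype=object),
                     np.asarray(chromosomes if chromosomes is not None
                                else np.full(s, 19)),
                     np.arange(s, dtype=np.int64))
    return GenotypeMatrix(ids, panel, calls, ploidy)


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free 3-generation cohort: every true relationship must show
    exactly 0 ME."""
    cfg = sp.SimulationConfig(n_founders=40, n_generations=3,
                              offspring_per_generation=35, n_snps=3000,
                              error_rate=0.0, missing_rate=0.0,
                              n_triploids=2, seed=101)
    return sp.simulate(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """The reference study conditions: 201 individuals, 5000 SNPs, four
    generations, per-call error 0.002, missingness 0.005."""
    cfg = sp.SimulationConfig(n_founders=60, n_generations=4,
                              offspring_per_generation=47, n_snps=5000,
                              error_rate=0.002, missing_rate=0.005, seed=7)
    return sp.simulate(cfg)


@pytest.fixture(scope="session")
def noisy_run(noisy_cohort):
    matrix, meta, truth = noisy_cohort
    thr = sp.ThresholdConfig.for_error_rate(0.002)
    return sp.run_all(matrix, meta, sp.PipelineConfig(thresholds=thr, seed=7))


@pytest.fixture(scope="session")
def masked_parent_setup():
    """A cohort where one genotyped mid-pedigree parent is removed from
    the matrix: its children's duos become orphans and the grandparent
    search should recover the removed parent's parent couple."""
    cfg = sp.SimulationConfig(n_founders=40, n_generations=3,
                              offspring_per_generation=40, n_snps=5000,
                              error_rate=0.002, missing_rate=0.005, seed=11)
    matrix, meta, truth = sp.simulate(cfg)
    target = None
    for child, parents in truth.pedigree.items():
        for p in parents:
            if p in truth.pedigree and truth.generation[p] == 2:
                target = p
                break
        if target:
            break
    masked = sp.mask_individuals(matrix, [target])
    meta = {k: v for k, v in meta.items() if k != target}
    return masked, meta, truth, target
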