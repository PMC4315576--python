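"""Shared fixtures.

Heavy end-to-end studies are session-scoped so the pipeline runs once and
both the module tests and the acceptance checks read from it.
"""
import numpy as np
import pytest

from pseudocall.experiment import (ValidationConfig, run_breakpoint_experiment,
                                   run_cnv_experiment,
                                   run_validation_experiment)
from pseudocall.locus import (LocusParams, derive_pseudogenes,
                              generate_master_locus, plant_variants)


@pytest.fixture(scope="session")
def small_locus():
    """A small master/pseudogene locus for unit-level checks."""
    params = LocusParams(exon_count=12, duplicated_exon_range=(1, 12),
                         n_pseudogenes=3, seed=11)
    locus = generate_master_locus(params)
    derive_pseudogenes(locus, params)
    return params, locus


@pytest.fixture(scope="session")
def small_truth(small_locus):
    _params, locus = small_locus
    return plant_variants(locus, seed=13)


@pytest.fixture(scope="session")
def full_experiment():
    """The deep-coverage validation study at the reference conditions:
    33 duplicated exons, six pseudogene copies at 97.7% identity, 2x150 bp
    pairs with 200 bp outer distance, base error 0.001, 1000x coverage,
    at least one planted alteration per 100 bp of coding sequence."""
    return run_validation_experiment(ValidationConfig(seed=1))


@pytest.fixture(scope="session")
def single_exon_cnv_study():
    return run_cnv_experiment(deleted_exons=[22], seed=3)


@pytest.fixture(scope="session")
def multi_exon_cnv_study():
    return run_cnv_experiment(deleted_exons=list(range(15, 22)), seed=4)


@pytest.fixture(scope="session")
def breakpoint_study():
    return run_breakpoint_experiment(n_deletions=50, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
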