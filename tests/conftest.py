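"""Shared fixtures: reduced synthetic study conditions for fast tests.

The ``small_config`` scales every dimension down (fewer TFs, genes,
lines, patients) while keeping the default effect sizes, so stage-level
behavior is preserved at a fraction of the runtime. Acceptance tests
that quantify recovery rates use the full default configuration instead.
"""

import numpy as np
import pytest

from tfnet.synthetic import SyntheticConfig, generate_all

SMALL = dict(n_tfs=60, n_genes=400, n_cell_lines=50, n_driver_tfs=20,
             n_active_null_tfs=8, n_module_drivers=5, n_hubs=2,
             n_background_proteins=120, n_patients=200, n_cohorts=2,
             cohort_size=150, n_cancer_specific=8, n_decoy_genes=4,
             n_survival_genes=5, module_program_size=30, module_program_targets=10)


def small_config(seed: int = 3, **overrides) -> SyntheticConfig:
    kwargs = {**SMALL, **overrides}
    return SyntheticConfig(rng_seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_bundle():
    """One fully generated reduced study, shared across tests."""
    return generate_all(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
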