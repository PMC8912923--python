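import numpy as np
import pytest

import socmeth as sm


def standard_covariates(cohort, n_pcs: int = 6):
    """Covariate design used throughout: sex/age/batch/intervention plus
    the first PCs of the M-value matrix."""
    pcs = sm.compute_pcs(sm.beta_to_m(cohort.methylation.betas.to_numpy()), n_pcs)
    return sm.build_covariates(cohort.metadata.frame, pcs=pcs)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused by read-only tests."""
    cfg = sm.SimConfig(n_samples=160, n_cpgs=400, n_hit_cpgs=20, seed=7)
    return sm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_ewas(small_cohort):
    cov = standard_covariates(small_cohort)
    return sm.run_ewas(small_cohort.methylation, small_cohort.metadata, cov)
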