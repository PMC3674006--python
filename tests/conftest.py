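import warnings

import numpy as np
import pytest

from sparsecmtf import generate_cohort, prepare
from sparsecmtf.cmtf import CMTFModel, align_components, cmtf_fit


def pytest_configure(config):
    warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """20-subject coupled cohort with mild noise and known truth."""
    ds, truth = generate_cohort(
        subjects=20, biomarkers=10, timepoints=4, baseline_vars=5, snps=8,
        noise_sd=(0.05, 0.05, 0.05), missing_rate=0.1, seed=7,
        discretize_genes=False,
    )
    return ds, truth


@pytest.fixture(scope="session")
def prepared_small(small_cohort):
    ds, truth = small_cohort
    return prepare(ds), truth


@pytest.fixture(scope="session")
def small_fit(prepared_small):
    ds, truth = prepared_small
    model = cmtf_fit(ds, rank=2, lam=1e-4, n_starts=5, seed=1)
    return align_components(model, ds), ds, truth


def truth_model(tr, raw=None):
    """Ground truth as a CMTFModel; if ``raw`` is given, matrix-block
    loadings are expressed in the standardized analysis space (rows divided
    by the empirical raw column sd)."""
    D, E = tr.baseline_loadings, tr.gene_loadings
    if raw is not None:
        D = D / raw.baseline.std(axis=0, ddof=1)[:, None]
        E = E / raw.gene.std(axis=0, ddof=1)[:, None]
    return CMTFModel(
        A=tr.subject_scores, B=tr.biomarker_loadings, C=tr.time_loadings,
        D=D, E=E,
    )


def assert_monotone_trace(model, rtol=1e-9):
    t = np.asarray(model.loss_trace)
    assert len(t) >= 1
    drops = np.diff(t)
    # floor at machine noise relative to the initial loss (a fit that hits
    # an exactly-zero residual dithers at ~1e-29 in float64)
    tol = rtol * t[:-1] + 1e-14 * t[0] + 1e-20
    assert np.all(drops <= tol), (
        f"penalized loss increased: max rise {drops.max():.3e}"
    )
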