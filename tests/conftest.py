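import logging

import numpy as np
import pandas as pd
import pytest

import apmcluster as apm

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def sc_cohort():
    """Default synthetic single-cell cohort with planted N_x in [0.5, 8]."""
    genes = apm.genesets.MHC_I_CORRECTION_GENES
    ratios = dict(zip(genes,
                      np.random.default_rng(7).uniform(0.5, 8, len(genes))))
    cells, truth = apm.generate_sc_cohort(apm_ratio=ratios, seed=7)
    return cells, truth


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default synthetic bulk cohort (planted clusters, survival, BOR)."""
    return apm.generate_bulk_cohort(seed=11)


@pytest.fixture(scope="session")
def corrected_results(bulk_cohort):
    """Purity-corrected expression clustered by the fitted model."""
    expr, clinical, purity, truth = bulk_cohort
    corrected = apm.correct_bulk_expression(expr, purity, truth.norm_factors)
    results = apm.APMClusterModel(corrected, clinical=clinical).fit()
    return corrected, results, truth


@pytest.fixture()
def small_expr():
    frame = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]],
                         index=["G1", "G2"], columns=["S1", "S2"])
    return apm.ExpressionMatrix(frame)
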