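import numpy as np
import pandas as pd
import pytest

from pgl_metabotyper.quantification import quantify_cohort
from pgl_metabotyper.synthetic_cohort import CohortSpec, GridSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default 28-sample cohort (fixed seed): spectra, truths, standard."""
    spec = CohortSpec.default(seed=7)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def default_quant(default_cohort):
    spectra, truths, standard = default_cohort
    return quantify_cohort(spectra, standard)


@pytest.fixture(scope="session")
def truth_frame(default_cohort):
    _, truths, _ = default_cohort
    metabolites = sorted({m for t in truths for m in t.concentrations})
    return pd.DataFrame(
        [
            {
                "sample_id": t.sample_id,
                "group": t.group,
                "weight_mg": t.weight_mg,
                **{m: t.concentrations.get(m, 0.0) for m in metabolites},
            }
            for t in truths
        ]
    )


@pytest.fixture()
def narrow_grid():
    """Small grid around the aliphatic region for fast rendering tests."""
    return GridSpec(ppm_min=1.0, ppm_max=3.5, step=0.0005)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
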