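import numpy as np
import pytest
from hypothesis import settings

import ewingsign as es
from ewingsign.classifier import EwingSignConfig, EwingSignModel
from ewingsign.mixtures import MixtureSetSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> es.SimulationConfig:
    """A reduced cohort for fast unit tests (structure identical to defaults)."""
    return es.SimulationConfig(
        seed=11,
        n_windows=600,
        n_dmr_per_pair=40,
        n_calibration_windows=20,
        depth=10_000,
        fragments_per_sample=5_000,
        cohort_layout=es.CohortLayout(
            n_ews_arrays=12,
            n_cic_arrays=6,
            n_ncc_cohort1=24,
            n_ncc_cohort2=8,
            n_ews_patients=3,
            n_cic_patients=1,
            relapse_fraction=1.0,
        ),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> es.MethylationCohort:
    return es.simulate_methylation_cohort(small_config)


@pytest.fixture(scope="session")
def small_model(small_cohort) -> EwingSignModel:
    """A 2-ensemble x 3-sub-classifier model trained on the small cohort."""
    cfg = EwingSignConfig(n_splits=2, n_sub=3, top_k_features=60, depth=10_000)
    spec = MixtureSetSpec(n_ews_mixtures=80, n_cic_mixtures=40, n_ncc_mixtures=120)
    return EwingSignModel.from_cohort(small_cohort, cfg, spec, seed=17)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
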