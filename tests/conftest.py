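import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adcresponse.synthgen import (
    CohortConfig,
    LesionGroundTruth,
    generate_cohort,
    render_lesion_volume,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_ground_truth(
    diameter_mm=40.0,
    viable_fraction=0.5,
    pre_adc=1070.0,
    post_adc=1450.0,
    lrtr="viable",
    **kwargs,
):
    return LesionGroundTruth(
        lesion_id=kwargs.pop("lesion_id", "LTEST"),
        patient_id="PTEST",
        diameter_mm=diameter_mm,
        viable_fraction_post=viable_fraction,
        is_mpr=viable_fraction <= 0.10,
        is_pcr=viable_fraction == 0.0,
        true_delta_adc_pct=(post_adc - pre_adc) / pre_adc * 100.0,
        lrtr_category=lrtr,
        sld_pre_mm=0.9 * diameter_mm,
        sld_post_mm=0.5 * diameter_mm,
        pre_adc_roi=pre_adc,
        post_adc_roi=post_adc,
        **kwargs,
    )


@pytest.fixture(scope="session")
def lesion_4cm():
    gt = make_ground_truth(diameter_mm=40.0)
    vol, mask = render_lesion_volume(gt, "pre", noise_sd=50.0, seed=11)
    return gt, vol, mask


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_patients=10, n_lesions=12, seed=5)
    return cfg, *generate_cohort(cfg)
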