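"""Shared fixtures: calibrated model and cached compensated simulations."""

import warnings

import pytest
from hypothesis import HealthCheck, settings

from triseg.calibration import calibrate
from triseg.config import Config
from triseg.experiments import (DysfunctionSpec, dysfunction_model,
                                find_compensated_tbv)

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

CASE_SPECS = {
    "LVSD-M": DysfunctionSpec("LV", "systolic", "moderate"),
    "LVSD-S": DysfunctionSpec("LV", "systolic", "severe"),
    "LVDD-M": DysfunctionSpec("LV", "diastolic", "moderate"),
    "LVDD-S": DysfunctionSpec("LV", "diastolic", "severe"),
    "RVSD-S": DysfunctionSpec("RV", "systolic", "severe"),
    "RVDD-S": DysfunctionSpec("RV", "diastolic", "severe"),
}


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def calibrated(config):
    """(model, calibration report) for the normative healthy subject."""
    return calibrate(config)


@pytest.fixture(scope="session")
def healthy_model(calibrated):
    return calibrated[0]


@pytest.fixture(scope="session")
def compensated(config, healthy_model):
    """Lazy cache of fully compensated runs, keyed by case label."""
    cache = {}

    def get(label: str):
        if label not in cache:
            model = healthy_model
            if label != "Healthy":
                model = dysfunction_model(model, CASE_SPECS[label], config)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cache[label] = find_compensated_tbv(model)
        return cache[label]

    return get
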