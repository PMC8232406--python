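"""Shared fixtures: presets and small synthetic traces, generated at test time."""

from __future__ import annotations

import dataclasses

import pytest

from metaflex.metabolic_metrics import derive_metabolic_series
from metaflex.synthetic_data import (
    builtin_presets,
    generate_activity_trace,
    generate_calorimetry_trace,
)


@pytest.fixture(scope="session")
def presets():
    return builtin_presets()


@pytest.fixture(scope="session")
def baseline_preset(presets):
    return presets["baseline"]


@pytest.fixture(scope="session")
def noiseless_baseline(baseline_preset):
    """Baseline condition with the stochastic terms switched off."""
    return dataclasses.replace(baseline_preset, ee_noise_sd=0.0, rer_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_trace(noiseless_baseline):
    return generate_calorimetry_trace(noiseless_baseline, seed=0)


@pytest.fixture(scope="session")
def noiseless_series(noiseless_trace):
    return derive_metabolic_series(noiseless_trace)


@pytest.fixture(scope="session")
def noisy_trace(baseline_preset):
    return generate_calorimetry_trace(baseline_preset, seed=7)


@pytest.fixture(scope="session")
def noisy_series(noisy_trace):
    return derive_metabolic_series(noisy_trace)


@pytest.fixture(scope="session")
def activity_trace(baseline_preset):
    return generate_activity_trace(baseline_preset, seed=7)
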