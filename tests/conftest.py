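import dataclasses

import numpy as np
import pytest

from adcfmri import (
    AcquisitionScheme,
    StimulationParadigm,
    compute_adc,
    make_label_phantom,
    preset,
    simulate_series,
    split_interleaved,
)


@pytest.fixture(scope="session")
def paradigm() -> StimulationParadigm:
    return StimulationParadigm()


@pytest.fixture(scope="session")
def dw_scheme() -> AcquisitionScheme:
    return AcquisitionScheme(contrast="dw_interleaved")


@pytest.fixture(scope="session")
def bold_scheme() -> AcquisitionScheme:
    return AcquisitionScheme(contrast="bold")


@pytest.fixture(scope="session")
def label_map():
    return make_label_phantom((32, 32, 4), "default", seed=1)


@pytest.fixture(scope="session")
def small_label_map():
    spec = {"A": ((6.0, 6.0, 1.0), 2.5), "B": ((13.0, 13.0, 1.0), 2.5)}
    return make_label_phantom((20, 20, 2), spec, seed=0)


def noisefree(tissue_by_region):
    """Strip noise and drift from a preset for deterministic checks."""
    return {
        name: dataclasses.replace(t, noise_sigma=0.0, drift_amp_pct=0.0)
        for name, t in tissue_by_region.items()
    }


@pytest.fixture(scope="session")
def msc_noisefree_adc(label_map, paradigm, dw_scheme):
    """Noise-free ADC series for the excitatory-mSC preset, with truth."""
    tissue = noisefree(preset("mSC_1Hz"))
    dw, truth = simulate_series(label_map, tissue, paradigm, dw_scheme, seed=3)
    low, high = split_interleaved(dw, dw_scheme)
    adc = compute_adc(low, high, (dw_scheme.b_low, dw_scheme.b_high))
    return adc, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
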