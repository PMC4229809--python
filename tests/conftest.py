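import numpy as np
import pytest

import wmnquant as w


def wm_only_config(**overrides) -> w.SlideConfig:
    """A small white-matter-dominated slide (thin token cortex band, no
    cortical cells) used wherever only the white-matter compartment matters."""
    base = dict(
        width_um=1600.0,
        height_um=1700.0,
        cortex_band_frac=0.05,
        layer6_density=0.0,
        cortex_density=0.0,
        background_margin_um=40.0,
    )
    base.update(overrides)
    return w.SlideConfig(**base)


def cortex_config(**overrides) -> w.SlideConfig:
    """A two-compartment slide with dense layer VI and an undulating
    grey/white interface, exercising the automated workflow."""
    base = dict(
        width_um=2000.0,
        height_um=3000.0,
        boundary_wave_amplitude_um=150.0,
        boundary_wavelength_um=1000.0,
    )
    base.update(overrides)
    return w.SlideConfig(**base)


@pytest.fixture(scope="session")
def cortex_slide():
    """One rendered cortex+WM slide with its truth, shared across tests."""
    config = cortex_config(seed=424242)
    slide, truth = w.generate_slide(config, case_id="fixture")
    return config, slide, truth


@pytest.fixture(scope="session")
def wm_slide():
    """One rendered WM-only slide with its truth."""
    config = wm_only_config(seed=31337)
    slide, truth = w.generate_slide(config, case_id="wm_fixture")
    return config, slide, truth


@pytest.fixture(scope="session")
def noiseless_wm_slide():
    config = wm_only_config(seed=2024, stain_noise_sd=0.0)
    slide, truth = w.generate_slide(config, case_id="noiseless")
    return config, slide, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
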