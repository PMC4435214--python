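import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_config():
    from acoustrap import load_preset

    return load_preset()


@pytest.fixture(scope="session")
def fitted_beam_like():
    """Analytic stand-in for the pipeline's fitted focal beam.

    Synthetic BeamModel with the waist/intensity the four-focus synthesis
    pipeline measures (32.6 um half-power width, 150 W/cm^2 peak), placed at
    the local-frame origin; lets force/dynamics unit tests run without the
    minute-scale field synthesis.
    """
    from acoustrap.beam_analysis import BeamModel

    return BeamModel(
        focus=[0.0, 0.0, 0.0],
        waist=32.6e-6,
        wavelength=30e-6,
        peak_intensity=150e4,
    )


@pytest.fixture(scope="session")
def four_focus():
    """Full four-focus synthesis pipeline (shared; takes ~1.5 min)."""
    from acoustrap.scenarios import synthesize_multi_focus

    return synthesize_multi_focus()


@pytest.fixture(scope="session")
def trapping_rows(four_focus):
    from acoustrap.scenarios import trapping_table

    return trapping_table(
        four_focus.beam,
        four_focus.config.medium,
        four_focus.config.particle,
    )
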