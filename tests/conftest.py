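"""Shared fixtures: small simulated sessions and calibrated models."""

import dataclasses

import numpy as np
import pytest

from spellersim import p3, paradigms, synthetic


@pytest.fixture(scope="session")
def rc_config():
    """Row/column matrix speller at the common 250 ms SOI."""
    return paradigms.P3SpellerConfig(
        style="row_column", stimulus_duration_ms=125, isi_ms=125, repetitions=10
    )


@pytest.fixture(scope="session")
def high_snr_erp():
    """Generator settings with a clearly detectable P3."""
    return synthetic.ERPGenConfig(p3_amplitude=8.0, noise_sigma=6.0, seed=101)


@pytest.fixture(scope="session")
def calibrated_model(rc_config, high_snr_erp):
    """Model trained on one simulated 8-symbol calibration run."""
    rng = np.random.default_rng(7)
    text = "".join(rc_config.matrix[i] for i in rng.integers(0, 36, size=8))
    rec, events, _ = synthetic.generate_p3_speller_session(
        dataclasses.replace(high_snr_erp, seed=77), rc_config, text
    )
    return p3.calibrate_from_session(rec, events, rc_config, seed=3)
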