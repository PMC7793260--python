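import numpy as np
import pytest
from hypothesis import settings

import fretpg as f

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_cfg():
    """Noiseless, scatter-free generator config for exact closed-loop checks."""
    return f.SyntheticPanelConfig.default(
        noise_sigma=0.0, replicate_cv=0.0, n_replicates=1, seed=7
    )


@pytest.fixture(scope="session")
def clean_basis(clean_cfg):
    """Reference basis built from noiseless synthetic reference scans."""
    return basis_from_spectra(f.simulate_panel([("tandem", {})], clean_cfg).spectra)


def basis_from_spectra(spectra):
    channels = sorted({s.excitation_nm for s in spectra})

    def one(role, ch):
        return next(s for s in spectra if s.role == role and s.excitation_nm == ch)

    return f.build_reference_basis(
        buffer_by_channel={ch: one("buffer", ch) for ch in channels},
        empty_by_channel={ch: one("empty_cell", ch) for ch in channels},
        donor_ref=one("donor_ref", channels[0]),
        acceptor_ref_by_channel={ch: one("acceptor_ref", ch) for ch in channels},
    )


def mix_spectrum(basis, channel, amplitudes, sample_id="mix"):
    """Construct an exact linear combination of one channel's basis columns."""
    ch = basis.channel(channel)
    y = ch.matrix @ np.asarray(amplitudes, dtype=float)
    return f.EmissionSpectrum(
        sample_id=sample_id,
        excitation_nm=channel,
        wavelengths=ch.grid,
        intensities=y,
        role="fret_sample",
    )
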