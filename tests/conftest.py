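import numpy as np
import pytest

from qhcr.config import (AmplifierParams, BackgroundParams, ChannelSpec,
                         OpticsParams, SimulationConfig)


@pytest.fixture
def antibody_channel():
    return ChannelSpec(target_id="TH", probe_kind="antibody_full_initiator",
                       binding_efficiency=1.0,
                       amplifier=AmplifierParams(mean_polymer_length=180,
                                                 length_law="deterministic"))


@pytest.fixture
def quiet_optics():
    """Deterministic forward model: no PSF, no noise, no offset."""
    return OpticsParams(psf_sigma=0.0, photon_scale=1.0, read_noise_sd=0.0,
                        dark_offset=0.0, shot_noise=False)


def small_config(seed=0, n_cells=3, shape=(64, 64), channels=(),
                 law=None, optics=None, cell_axes_um=(0.6, 1.6), **kw):
    """A 64x64 field (~10 µm) with cells small enough to fit it."""
    return SimulationConfig(
        image_shape=shape, pixel_size=0.16, n_cells=n_cells,
        abundance_law=law or {"name": "deterministic", "density": 5},
        channels=channels, seed=seed, cell_axes_um=cell_axes_um,
        optics=optics or OpticsParams(psf_sigma=0.0, shot_noise=False,
                                      read_noise_sd=0.0, dark_offset=0.0),
        **kw)


@pytest.fixture
def make_config():
    return small_config
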