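import numpy as np
import pytest

from phasequant import synthetic as syn


@pytest.fixture(scope="session")
def clean_droplet_field():
    """Noise-free field of 3 identical droplets with ground truth."""
    return syn.make_droplet_field(
        n_droplets=3, radius_range=(0.53, 0.53), pixel_size=0.106,
        snr=np.inf, field_size=128, seed=2,
    )

@pytest.fixture(scope="session")
def noisy_droplet_field():
    """Field of 8 droplets at SNR 10."""
    return syn.make_droplet_field(
        n_droplets=8, radius_range=(0.6, 1.2), pixel_size=0.106,
        snr=10.0, field_size=256, seed=7,
    )


@pytest.fixture(scope="session")
def fusion_movie_21s():
    return syn.make_fusion_movie(t_fusion=21.0, dt=1.0, seed=3)


@pytest.fixture(scope="session")
def nucleus_stack_mixed():
    """Two nuclei with truth foci counts {7, 14}, half colocalized."""
    return syn.make_nucleus_stack(
        n_nuclei=2, foci_per_nucleus=[7, 14], n_telomeres=12,
        coloc_fraction=0.5, seed=11,
    )
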