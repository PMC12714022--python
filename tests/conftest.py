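import numpy as np
import pytest

from plastmap import synthetic


@pytest.fixture(scope="session")
def half_annulus_geom():
    """Half-annular ventricular wall: r 300-600 µm, 20 µm bead pitch."""
    return synthetic.TissueGeometry(
        shape_kind="annulus",
        r_inner=300.0,
        r_outer=600.0,
        theta_min=0.0,
        theta_max=np.pi,
        spot_spacing=20.0,
    )


@pytest.fixture(scope="session")
def half_annulus(half_annulus_geom):
    spots, truth = synthetic.gen_spots(half_annulus_geom, smear_fraction=0.1, seed=11)
    return spots, truth


@pytest.fixture(scope="session")
def wedge_geom():
    """Valve-leaflet wedge: 400 µm base, 600 µm tall, tip at the origin."""
    return synthetic.TissueGeometry(
        shape_kind="wedge", base_width=400.0, height=600.0, spot_spacing=20.0
    )


@pytest.fixture(scope="session")
def three_stage_chain():
    return synthetic.gen_transition_chain(
        n_per_type=[40, 40, 40],
        chain=["immature", "transitional", "mature"],
        forward_p=0.8,
        noise_p=0.0,
        seed=5,
    )
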