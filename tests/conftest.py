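import numpy as np
import pytest

from hcscreen.image_analysis import DetectionParams
from hcscreen.plate_model import PlateLayout, WellSpec
from hcscreen.synthetic import SyntheticSpec, generate_field


@pytest.fixture
def params():
    return DetectionParams()


@pytest.fixture
def small_spec():
    """Small, fast field: 256x256, ~8 cells, full noise model."""
    return SyntheticSpec(seed=7, field_shape=(256, 256), cells_per_field=8.0)


@pytest.fixture
def clean_spec():
    """Noise-free small field for exact checks."""
    return SyntheticSpec(
        seed=7, field_shape=(256, 256), cells_per_field=6.0,
        shot_noise=False, read_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def default_field():
    """One full-size field under default (study baseline) conditions."""
    spec = SyntheticSpec(seed=11)
    return generate_field(spec, "A01", 0)


def make_layout(n_dmso=4, compounds=(), genotype="mutant", plate_id="test"):
    """Small plate layout: DMSO controls first, then duplicate compound wells."""
    wells = []
    addresses = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]
    it = iter(addresses)
    for _ in range(n_dmso):
        wells.append(WellSpec(next(it), "dmso_control", genotype=genotype))
    for comp in compounds:
        for rep in (1, 2):
            wells.append(
                WellSpec(next(it), "compound", compound_id=comp, dose_um=10.0,
                         genotype=genotype, replicate=rep)
            )
    return PlateLayout(plate_id=plate_id, wells=wells)


@pytest.fixture
def small_layout():
    return make_layout(n_dmso=4, compounds=("cmpd-a", "cmpd-b"))
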