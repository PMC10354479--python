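import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from pterowing import preset_library
from pterowing.specimens import Specimen, SpecimenTable


@pytest.fixture(scope="session")
def presets():
    return preset_library()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(taxon, rows):
    """rows: list of (id, dict of measurements)."""
    return SpecimenTable(
        taxon=taxon,
        specimens=tuple(Specimen(sid, meas) for sid, meas in rows),
    )


@pytest.fixture
def tiny_table():
    full = dict(
        skull=110.0, neck=60.0, tail=280.0, humerus=38.0, ulna_radius=67.0,
        mcIV=26.0, wp1=119.0, wp2=100.0, wp3=76.0, wp4=50.0, femur=55.0,
        tibia=75.0, wingspan=1000.0,
    )
    rows = [("sp1", dict(full))]
    partial = dict(full)
    del partial["humerus"]
    rows.append(("sp2", partial))
    rows.append(("sp3", {k: v * 0.5 for k, v in full.items()}))
    return make_table("Testoterus", rows)
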