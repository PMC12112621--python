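import numpy as np
import pytest

from hemamorph.io_formats import Calibration
from hemamorph.synthetic_smear import CellSpec, render_smear


@pytest.fixture(scope="session")
def cal():
    """Reference calibration: 0.1 µm per pixel."""
    return Calibration(0.1)


@pytest.fixture(scope="session")
def circle_sample(cal):
    """One ideal circular RBC, a = b = 3.5 µm, no pallor, noise-free."""
    spec = CellSpec(
        class_name="rbc",
        archetype="Normal",
        center=(60.0, 60.0),
        a_um=3.5,
        b_um=3.5,
        pallor_kind="none",
    )
    return render_smear([spec], (120, 120), cal, seed=0, noise_sigma=0.0)


@pytest.fixture(scope="session")
def pallor_cell_sample(cal):
    """A normal discocyte with round central pallor (noise-free)."""
    spec = CellSpec(
        class_name="rbc",
        archetype="Normal",
        center=(60.0, 60.0),
        a_um=3.5,
        b_um=3.5,
        pallor_ratio=0.45,
    )
    return render_smear([spec], (120, 120), cal, seed=0, noise_sigma=0.0)
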