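"""Shared fixtures: one small orthorhombic ground truth and a standard
wedge dataset, reused wherever a test only needs 'a realistic dataset'."""

import numpy as np
import pytest

from edbatch.formats import UnitCell
from edbatch.symmetry import laue_operators
from edbatch.synthetic import WedgeSpec, make_dataset, make_ground_truth

ORTHO_CELL = UnitCell(6.0, 7.027, 21.718, 90.0, 90.0, 90.0)


@pytest.fixture(scope="session")
def ortho_cell():
    return ORTHO_CELL


@pytest.fixture(scope="session")
def laue_mmm():
    return laue_operators("mmm")


@pytest.fixture(scope="session")
def laue_p1():
    return laue_operators("-1")


@pytest.fixture(scope="session")
def mmm_truth(ortho_cell):
    return make_ground_truth(ortho_cell, "mmm", d_min=0.8, seed=42)


@pytest.fixture(scope="session")
def std_dataset(mmm_truth):
    """One well-behaved 130-degree wedge (large-tilt single-crystal style)."""
    wedge = WedgeSpec(phi_start=0.0, phi_end=130.0, orientation=(15, 40, 70))
    return make_dataset(mmm_truth, wedge, seed=7, dataset_id="std")
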