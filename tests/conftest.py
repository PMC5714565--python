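import numpy as np
import pytest

import sirtdose as sd


@pytest.fixture(scope="session")
def kernel6():
    """Synthetic 6 mm S-value kernel, 7^3, exact energy closure."""
    return sd.generate_test_kernel(pitch=(6.0, 6.0, 6.0), extent=3)


@pytest.fixture(scope="session")
def tumor_params():
    return sd.RadiobioParams.tumor()


@pytest.fixture(scope="session")
def liver_params():
    return sd.RadiobioParams.liver()


@pytest.fixture(scope="session")
def small_patient():
    """Compact virtual patient (72^3 at 4 mm) shared across test modules."""
    return sd.make_virtual_patient(
        n_tumors=1, tumor_volumes_cm3=(80.0,), liver_volume_cm3=1400.0,
        tumor_to_liver_ratio=4.0, admin_activity_gbq=1.1, seed=11,
        shape=(72, 72, 72), spacing_mm=(4.0, 4.0, 4.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def make_dose_grid(values, spacing=(2.0, 2.0, 2.0), **kw):
    return sd.ImageGrid(np.asarray(values, dtype=float), spacing,
                        quantity=sd.Quantity.DOSE, **kw)


def make_mask(bool_array, grid, name="roi"):
    return sd.StructureMask(name, sd.ImageGrid(
        np.asarray(bool_array, dtype=float), grid.spacing, grid.origin,
        sd.Quantity.MASK))
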