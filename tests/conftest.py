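import numpy as np
import pytest

from diadesign import (
    PrecursorRecord,
    ScanArea,
    SpectralLibrary,
    generate_within_trapezoid,
)


def lib_from_arrays(mz, im, charge, **kwargs) -> SpectralLibrary:
    records = [
        PrecursorRecord(mz=float(a), im=float(b), charge=int(c))
        for a, b, c in zip(mz, im, charge)
    ]
    return SpectralLibrary.from_records(records, deduplicate=False, **kwargs)


@pytest.fixture
def uniform_library():
    """1000 uniform points over the full proteome coordinate ranges."""
    rng = np.random.default_rng(11)
    n = 1000
    return lib_from_arrays(
        rng.uniform(300, 1200, n),
        rng.uniform(0.6, 1.5, n),
        rng.choice([2, 3, 4], n),
    )


#: steep, thin diagonal band: the shape a charge-stratified precursor cloud
#: actually has, and the geometry a two-strip dia-PASEF scheme can tile
RECOVERY_AREA = ScanArea(0.70, 1.10, 0.85, 1.30)
RECOVERY_MZ_RANGE = (400.0, 1200.0)


@pytest.fixture
def trapezoid_fixture():
    """2000-precursor cloud drawn strictly inside RECOVERY_AREA."""
    return generate_within_trapezoid(RECOVERY_AREA, RECOVERY_MZ_RANGE, 2000, seed=3)
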