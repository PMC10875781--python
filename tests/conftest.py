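import numpy as np
import pytest

from egidrive import DriveParams, delta_x, vial40_design, simulate_assay


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noiseless_records():
    """Assay records lying exactly on the model curve for F=1.2, c=0.9."""
    from egidrive import AssayRecord

    params = DriveParams(F=1.2, c=0.9)
    records = []
    total = 10_000  # large counts so integer rounding is negligible
    for x0 in np.arange(0.05, 0.96, 0.05):
        x1 = x0 + delta_x(float(x0), params)
        records.append(
            AssayRecord(
                start_egi=round(x0 * total),
                start_wt=total - round(x0 * total),
                offspring_egi=round(x1 * 10**7),
                offspring_wt=10**7 - round(x1 * 10**7),
            )
        )
    return records


@pytest.fixture
def synthetic_assay():
    """One seeded 40-fly-design assay under a mildly non-neutral drive."""
    return simulate_assay(vial40_design(), DriveParams(F=1.2, c=0.9), seed=11)
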