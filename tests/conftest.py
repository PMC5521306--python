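import numpy as np
import pytest

from dotppi.hemodynamics import build_canonical_hrf
from dotppi.synth import GroundTruthCouplings, RegionLayout, generate_design


@pytest.fixture(scope="session")
def hrf10():
    return build_canonical_hrf(10.0, 32.0)


@pytest.fixture(scope="session")
def hrf1():
    return build_canonical_hrf(1.0, 32.0)


@pytest.fixture(scope="session")
def coarse_layout():
    """Desk-scale version of the canonical 10-region layout (9-mm voxels)."""
    return RegionLayout.default(9.0)


@pytest.fixture(scope="session")
def default_designs():
    return generate_design(4, seed=7)


@pytest.fixture(scope="session")
def battery():
    """Shared synthetic-recovery battery: ten seeded group replicates with
    the single complex-condition modulation, plus twenty zero-coupling
    three-subject replicates for false-positive control.

    Session-scoped because each replicate simulates a full multi-subject
    session; the recovery, deconvolution-advantage and scrambled-signal
    checks all read from this one battery.
    """
    from dotppi.experiments import run_null_replicate, run_recovery_replicate

    replicates = [run_recovery_replicate(seed=100 + i) for i in range(10)]
    null_p = [run_null_replicate(seed=500 + i) for i in range(20)]
    return {"replicates": replicates, "null_p": null_p}
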