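import numpy as np
import pytest

from aquaflux import units
from aquaflux.vesicle import VesicleSpec, VolumeTrace, deflate_analytic


@pytest.fixture
def ref_spec() -> VesicleSpec:
    """Reference stopped-flow scenario: 100 nm LUV, 290 -> 300 mM, P_f = 0.01 cm/s."""
    return VesicleSpec(
        r0=units.nm_to_cm(100.0),
        c_in0=units.mM_to_mol_cm3(290.0),
        c_out=units.mM_to_mol_cm3(300.0),
        P_f=0.01,
    )


@pytest.fixture
def ref_trace(ref_spec) -> VolumeTrace:
    """Noiseless closed-form deflation trace over ~6 relaxation times."""
    t = np.linspace(0.0, 6.0 * ref_spec.tau_linear, 500)
    return VolumeTrace(t=t, V=np.asarray(deflate_analytic(ref_spec, t)))


def random_spec(rng: np.random.Generator) -> VesicleSpec:
    """Random but physical vesicle spec for property sweeps (shrink + mild swell)."""
    r0 = units.nm_to_cm(rng.uniform(30.0, 200.0))
    c_in0 = units.mM_to_mol_cm3(rng.uniform(100.0, 400.0))
    # ratio in (0.5, 2): covers swelling and shrinking, away from W-branch trouble
    c_out = c_in0 * rng.uniform(0.5, 2.0)
    P_f = 10.0 ** rng.uniform(-3.0, -1.0)
    return VesicleSpec(r0=r0, c_in0=c_in0, c_out=c_out, P_f=P_f)
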