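import numpy as np
import pytest

from paleomonsoon import synthetic, wax
from paleomonsoon.records import ProxyRecord


@pytest.fixture(scope="session")
def ages_3kyr():
    """Orbital-resolution age grid over a five-glacial-cycle window."""
    return np.arange(0.0, 511.0, 3.0)


@pytest.fixture(scope="session")
def wax_config(ages_3kyr):
    """A complete isotope-chain configuration with a synthetic stack."""
    stack = synthetic.gen_benthic_stack(ages_3kyr)
    return wax.WaxChainConfig(
        endmembers=wax.MixingEndMembers(),
        fractionation=wax.FractionationParams(eps_C3=-115.0, eps_C4=-132.0),
        seawater=wax.SeawaterCorrection(ages_3kyr, stack.values),
    )


@pytest.fixture()
def column_factory():
    """Synthetic sediment columns with a glacial-cycle-scale dust signal."""

    def make(focusing=1.5, seed=3, n=37, r_terr=1.0e-8, **kw):
        ages = np.linspace(0.0, 510.0, n)
        dust = 0.35 + 0.25 * np.sin(2 * np.pi * ages / 23.0)
        return synthetic.SyntheticColumn(
            ages=ages, true_dust_flux=dust, f_caco3=0.6,
            focusing_factor=focusing, r_terr_true=r_terr, seed=seed, **kw)

    return make


@pytest.fixture()
def sine_record():
    def make(period, n=171, dt=3.0, phase=0.0, amp=1.0):
        t = np.arange(n) * dt
        return ProxyRecord(t, amp * np.sin(2 * np.pi * (t - phase) / period))

    return make
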