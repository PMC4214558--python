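import numpy as np
import pytest

from phosink import invivo_system, table1_system
from phosink.model_core import KineticParameters, SystemTotals


@pytest.fixture(scope="session")
def table1():
    return table1_system()


@pytest.fixture(scope="session")
def invivo():
    return invivo_system()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140)


def draw_random_system(rng, no_sink=False, atp_range=(1.0, 1000.0)):
    """Broad log-uniform draw of basic-model rates and totals."""
    lu = lambda lo, hi: float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
    params = KineticParameters(
        k1=lu(0.1, 10), k2=lu(10, 1000), ka=1.0,
        kS=lu(1e-3, 1e2), krS=lu(1e-3, 1e2),
        kM=lu(1e-3, 1e2), krM=lu(1e-3, 1e2),
        khS=lu(1e-3, 1e1), khM=lu(1e-3, 1e1),
    )
    totals = SystemTotals(
        HK_tot=lu(0.5, 50),
        RR1_tot=0.0 if no_sink else lu(0.1, 50),
        RR2_tot=lu(0.1, 50),
        ATP=lu(*atp_range),
    )
    return params, totals
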