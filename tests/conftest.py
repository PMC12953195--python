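import numpy as np
import pytest
from scipy.optimize import brentq

from nlsbind.itc_binding import ItcProtocol
from nlsbind.presets import peptide_records


@pytest.fixture(scope="session")
def records():
    return peptide_records()


@pytest.fixture(scope="session")
def protocol():
    """The study's titration protocol: 19 x 2 uL, 10 uM cell, 100 uM syringe."""
    return ItcProtocol()


def equilibrium_complex_um(pt_um, lt_um, ka_m, n=1.0):
    """Independent mass-balance oracle for [PL] (uM): solve
    Ka (nPT - PL)(LT - PL) = PL by bracketed root finding."""
    npt = n * pt_um * 1e-6
    lt = lt_um * 1e-6
    upper = min(npt, lt)
    if upper <= 0:
        return 0.0
    f = lambda pl: ka_m * (npt - pl) * (lt - pl) - pl
    return brentq(f, 0.0, upper, xtol=1e-18, rtol=1e-15) * 1e6


def stepwise_itc_heats(protocol, ka_m, dh, n=1.0, qd=0.0):
    """Brute-force overflow-cell simulator: update totals injection by
    injection and re-equilibrate with the bracketed mass-balance solver."""
    v0 = protocol.cell_volume_ul
    lt, pt = 0.0, protocol.cell_protein_um
    pl_prev = 0.0
    heats = []
    for v in protocol.injection_volumes_ul:
        f = 1.0 - v / v0
        lt = lt * f + protocol.syringe_ligand_um * (v / v0)
        pt = pt * f
        pl = equilibrium_complex_um(pt, lt, ka_m, n)
        heats.append(v0 * dh * (pl - pl_prev * f)
                     / (v * protocol.syringe_ligand_um) + qd)
        pl_prev = pl
    return np.array(heats)
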