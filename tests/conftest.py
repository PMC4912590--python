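import numpy as np
import pytest

from ureaconf import sim, wham


@pytest.fixture(scope="session")
def vacuum_potential():
    return sim.get_preset("paper_vacuum")


@pytest.fixture(scope="session")
def vacuum_windows(vacuum_potential):
    """Full 121-window protocol on the vacuum preset at reduced sampling."""
    windows = sim.make_umbrella_protocol()
    cfg = sim.SimConfig(n_snapshots=1000, seed=1)
    return sim.run_umbrella_protocol(vacuum_potential, windows, cfg)


@pytest.fixture(scope="session")
def vacuum_profile(vacuum_windows):
    inp = wham.build_wham_input(vacuum_windows, bin_width=3.0)
    return wham.wham_solve(inp)


def analytic_reference(pot, angles):
    u = pot.energy(np.asarray(angles))
    return u - u.min()
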