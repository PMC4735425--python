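import math

import numpy as np
import pytest

from bgqsp.circuit import build_network, circuit_params, integrate_single_cell


@pytest.fixture(scope="session")
def graph():
    """One wired network shared across tests (seed 1)."""
    return build_network(1)


@pytest.fixture(scope="session")
def short_sim(graph):
    """A short healthy-state run shared by readout/engine tests."""
    from bgqsp.circuit import run_simulation

    return run_simulation(graph, 1000.0, seed=7)


def stn_rk4_reference(duration, dt, i_app, V0):
    """Independent tiny-step RK4 integrator for the isolated STN cell.

    Implements the published current-balance equations directly from the
    parameter file; shares no code with the simulation kernel.
    """
    p = circuit_params()["cells"]["stn"]

    def sig(v, g):
        return 1.0 / (1.0 + math.exp(-(v - g["theta"]) / g["sigma"]))

    def tau(v, g):
        return g["tau0"] + g["tau1"] / (
            1.0 + math.exp(-(v - g["theta_t"]) / g["sigma_t"]))

    b_off = 1.0 / (1.0 + math.exp(4.0))

    def deriv(y):
        v, h, n, r, ca = y
        minf = sig(v, p["m"])
        ainf = sig(v, p["a"])
        sinf = sig(v, p["s"])
        binf = 1.0 / (1.0 + math.exp((r - p["b_r"]["theta"]) / 0.1)) - b_off
        I_na = p["gNa"] * minf ** 3 * h * (v - p["ENa"])
        I_k = p["gK"] * n ** 4 * (v - p["EK"])
        I_l = p["gL"] * (v - p["EL"])
        I_t = p["gT"] * ainf ** 3 * binf ** 2 * (v - p["ECa"])
        I_ca = p["gCa"] * sinf ** 2 * (v - p["ECa"])
        I_ahp = p["gAHP"] * (v - p["EK"]) * ca / (ca + p["k1"])
        dv = (-(I_na + I_k + I_l + I_t + I_ca + I_ahp) + i_app) / p["C"]
        dh = p["h"]["phi"] * (sig(v, p["h"]) - h) / tau(v, p["h"])
        dn = p["n"]["phi"] * (sig(v, p["n"]) - n) / tau(v, p["n"])
        dr = p["r"]["phi"] * (sig(v, p["r"]) - r) / tau(v, p["r"])
        dca = p["ca_eps"] * (-I_ca - I_t - p["ca_k"] * ca)
        return np.array([dv, dh, dn, dr, dca])

    y = np.array([V0, sig(V0, p["h"]), sig(V0, p["n"]), sig(V0, p["r"]), 0.05])
    n_steps = int(round(duration / dt))
    spikes = []
    armed = True
    for i in range(n_steps):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * dt * k1)
        k3 = deriv(y + 0.5 * dt * k2)
        k4 = deriv(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if armed and y[0] >= -20.0:
            spikes.append((i + 1) * dt)
            armed = False
        elif not armed and y[0] < -30.0:
            armed = True
    return np.array(spikes)


@pytest.fixture(scope="session")
def stn_oracle():
    """Spike times of the isolated STN cell: kernel vs tiny-step RK4 reference
    over 500 ms of tonic firing.  Computed once per session."""
    duration, i_app, V0 = 500.0, 10.0, -62.0
    ref = stn_rk4_reference(duration, dt=0.002, i_app=i_app, V0=V0)
    _, _, eng = integrate_single_cell("STN", duration, i_app=i_app, V0=V0)
    return ref, eng
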