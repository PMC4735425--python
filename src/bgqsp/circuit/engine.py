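"""Network integration engine.

Every compartment obeys the Hodgkin-Huxley current-balance equation
C dV/dt = -sum_a g_a (V - E_a) + I_ex.  Gating variables advance by
exponential Euler, membrane potentials by a forward update, at dt = 0.025 ms
by default (the accuracy contract requires dt <= 0.05 ms).  Synaptic
conductances are difference-of-exponentials driven by delayed presynaptic
spikes (upward threshold crossings at -20 mV); background bombardment is an
Ornstein-Uhlenbeck conductance pair per cell.  The hot loop is compiled with
numba; the model equations live here, the constants in the vendored
parameter file.

The per-step summed synaptic current onto pyramidal cells — the field
potential proxy consumed by the spectral readout — is recorded alongside the
spike raster.  All randomness (noise path, initial jitter) derives from the
caller's seed; identical (configuration, seed) runs are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import NetworkGraph, POPULATION_ORDER, build_network

__all__ = ["SimResult", "run_simulation", "integrate_single_cell", "FAMILY_CODES"]

FAMILY_CODES = {"stn": 0, "gp": 1, "tc": 2, "re": 3, "msn": 4, "pyr": 5, "bc": 6}

#: channel-target name -> per-cell conductance array attribute
CHANNEL_TARGET_ATTR = {
    "K_ir": ("gKir",),
    "K_A": ("gKA",),
    "K_dr": ("gK",),
    "K_Ca": ("gKCa",),
    "HVA": ("gHVA",),
    "Na_p": ("gNaP",),
    "Ih": ("gH",),
    "K_leak": ("gKL",),
    "leak": ("gL", "gLd"),
}

_REST_V = {"stn": -62.0, "gp": -65.0, "tc": -66.0, "re": -70.0,
           "msn": -82.0, "pyr": -70.0, "bc": -65.0}


@dataclass
class SimResult:
    """Spike raster, LFP proxy and bookkeeping of one network run."""

    dt: float
    duration: float
    spike_times: np.ndarray      # ms
    spike_cells: np.ndarray      # global cell indices
    pyr_synaptic_current: np.ndarray
    populations: dict
    seed: int
    voltages: np.ndarray | None = None
    voltage_cells: tuple = ()

    def spikes_of(self, pop: str) -> np.ndarray:
        start, count = self.populations[pop]
        m = (self.spike_cells >= start) & (self.spike_cells < start + count)
        return self.spike_times[m]

    def rate_of(self, pop: str, skip_ms: float = 200.0) -> float:
        """Mean firing rate (Hz per cell) after a settling interval."""
        start, count = self.populations[pop]
        t = self.spikes_of(pop)
        window_s = (self.duration - skip_ms) / 1000.0
        return float(np.sum(t >= skip_ms)) / count / window_s

    def rates(self, skip_ms: float = 200.0) -> dict:
        return {p: self.rate_of(p, skip_ms) for p in self.populations}


@njit(cache=True, fastmath=True)
def _sig(v, theta, sigma):
    return 1.0 / (1.0 + math.exp(-(v - theta) / sigma))


@njit(cache=True, fastmath=True)
def _tau(v, t0, t1, tt, ts):
    return t0 + t1 / (1.0 + math.exp(-(v - tt) / ts))


@njit(cache=True, fastmath=True)
def _deriv(fam_i, v, vd, h, n, r, ca, q, b,
           Gs_i, GEs_i, Gd_i, GEd_i, iapp_i,
           C, gNa, gK, gL, gLd, gC, gT, gCa, gAHP, k1, ca_eps, ca_k,
           gKir, gKA, gNaP, gKCa, gHVA, kca_half, ca_alpha, ca_tau, gH, gKL,
           ENa, EK, EL, ELd, ECa, EH,
           m_th, m_sg,
           h_th, h_sg, h_t0, h_t1, h_tt, h_ts, h_phi,
           n_th, n_sg, n_t0, n_t1, n_tt, n_ts, n_phi,
           r_th, r_sg, r_t0, r_t1, r_tt, r_ts, r_phi,
           a_th, a_sg, aux1_th, aux1_sg, aux2_th, aux2_sg,
           aux3_th, aux3_sg, aux3_tau, b_off):
    """Time derivatives of one cell's state given frozen synaptic/noise
    conductance aggregates (G, G*E) per compartment."""
    dv = dvd = dh = dn = dr = dca = dq = db = 0.0
    minf = _sig(v, m_th, m_sg)
    hinf = _sig(v, h_th, h_sg)
    ninf = _sig(v, n_th, n_sg)
    gna = gNa * minf * minf * minf * h
    gk = gK * n ** 4
    G = gna + gk + gL + Gs_i
    GE = gna * ENa + gk * EK + gL * EL + GEs_i

    if fam_i == 0 or fam_i == 1:
        ainf = _sig(v, a_th, a_sg)
        sinf = _sig(v, aux1_th, aux1_sg)
        if fam_i == 0:
            binf = _sig(r, aux2_th, aux2_sg) - b_off
            gt = gT * ainf ** 3 * binf * binf
        else:
            gt = gT * ainf ** 3 * r
        gca = gCa * sinf * sinf
        gahp = gAHP * ca / (ca + k1)
        G += gt + gca + gahp
        GE += (gt + gca) * ECa + gahp * EK
        dca = ca_eps * (-(gca + gt) * (v - ECa) - ca_k * ca)
        tr = _tau(v, r_t0, r_t1, r_tt, r_ts)
        dr = r_phi * (_sig(v, r_th, r_sg) - r) / tr
    elif fam_i == 2 or fam_i == 3:
        pinf = _sig(v, a_th, a_sg)
        gt = gT * pinf * pinf * r
        G += gKL + gt
        GE += gKL * EK + gt * ECa
        tr = 0.4 * (28.0 + math.exp(-(v + 25.0) / 10.5))
        dr = (_sig(v, r_th, r_sg) - r) / tr
        if fam_i == 2:
            gh_ = gH * q
            aA = _sig(v, aux2_th, aux2_sg)
            ga = gKA * aA * b
            G += gh_ + ga
            GE += gh_ * EH + ga * EK
            tq = 20.0 + 1000.0 / (math.exp((v + 71.5) / 14.2)
                                  + math.exp(-(v + 89.0) / 11.6))
            dq = (_sig(v, aux1_th, aux1_sg) - q) / tq
            db = (_sig(v, aux3_th, aux3_sg) - b) / aux3_tau
    elif fam_i == 4:
        # two compartments: spiking soma + K_ir/K_A dendrite
        G += gC
        GE += gC * vd
        kinf = _sig(vd, aux1_th, aux1_sg)
        gkir = gKir * kinf
        aA = _sig(vd, aux2_th, aux2_sg)
        ga = gKA * aA * b
        Gd = gkir + ga + gLd + gC + Gd_i
        GEd = ((gkir + ga) * EK + gLd * ELd + gC * v + GEd_i)
        dvd = (GEd - Gd * vd) / C
        db = (_sig(vd, aux3_th, aux3_sg) - b) / aux3_tau
    elif fam_i == 5:
        pinf = _sig(v, aux1_th, aux1_sg)
        gnap = gNaP * pinf
        uinf = _sig(v, aux2_th, aux2_sg)
        ghva = gHVA * uinf * uinf
        gkca = gKCa * ca / (ca + kca_half)
        G += gnap + ghva + gkca + gC
        GE += gnap * ENa + ghva * ECa + gkca * EK + gC * vd
        dca = -ca_alpha * ghva * (v - ECa) - ca / ca_tau
        Gd = gLd + gC + Gd_i
        GEd = gLd * ELd + gC * v + GEd_i
        dvd = (GEd - Gd * vd) / C

    dv = (GE - G * v + iapp_i) / C
    th = _tau(v, h_t0, h_t1, h_tt, h_ts)
    dh = h_phi * (hinf - h) / th
    tn = _tau(v, n_t0, n_t1, n_tt, n_ts)
    dn = n_phi * (ninf - n) / tn
    return dv, dvd, dh, dn, dr, dca, dq, db


@njit(cache=True, fastmath=True)
def _kernel(n_steps, dt, fam,
            V, Vd, gh, gn, gr, ca, gq, gb,
            C, gNa, gK, gL, gLd, gC, gT, gCa, gAHP, k1, ca_eps, ca_k,
            gKir, gKA, gNaP, gKCa, gHVA, kca_half, ca_alpha, ca_tau,
            gH, gKL, iapp,
            ENa, EK, EL, ELd, ECa, EH,
            m_th, m_sg,
            h_th, h_sg, h_t0, h_t1, h_tt, h_ts, h_phi,
            n_th, n_sg, n_t0, n_t1, n_tt, n_ts, n_phi,
            r_th, r_sg, r_t0, r_t1, r_tt, r_ts, r_phi,
            a_th, a_sg, aux1_th, aux1_sg, aux2_th, aux2_sg,
            aux3_th, aux3_sg, aux3_tau,
            s_pre, s_post, s_comp, s_nmda, s_w, s_E, s_fr, s_fd, s_dstep, s_lfp,
            sA, sB,
            ext_steps, ext_syn,
            mu_e, sd_ke, mu_i, sd_ki, k_e, k_i, E_e, E_i, ou_e, ou_i, noise_dend,
            thresh, rearm, seed,
            lfp, spike_t, spike_id, vrec_idx, vrec):
    np.random.seed(seed)
    N = V.shape[0]
    n_syn = s_pre.shape[0]
    L = 0
    for i in range(n_syn):
        if s_dstep[i] + 2 > L:
            L = s_dstep[i] + 2
    if L < 2:
        L = 2
    rb = np.zeros((N, L), dtype=np.uint8)
    armed = np.ones(N, dtype=np.uint8)
    Gs = np.zeros(N)
    GEs = np.zeros(N)
    Gd = np.zeros(N)
    GEd = np.zeros(N)
    n_spk = 0
    max_spk = spike_t.shape[0]
    ev_ptr = 0
    n_ev = ext_steps.shape[0]
    b_off = 1.0 / (1.0 + math.exp(4.0))
    half = 0.5 * dt

    for t in range(n_steps):
        for i in range(N):
            Gs[i] = 0.0
            GEs[i] = 0.0
            Gd[i] = 0.0
            GEd[i] = 0.0
        lfp_t = 0.0

        # --- synaptic conductances (decay + delayed spike increments); the
        # NMDA Mg-block factor is evaluated at the step's starting voltage
        for s in range(n_syn):
            sA[s] *= s_fr[s]
            sB[s] *= s_fd[s]
            p = s_pre[s]
            if p >= 0:
                if rb[p, (t - s_dstep[s]) % L] == 1:
                    sA[s] += 1.0
                    sB[s] += 1.0
            g = s_w[s] * (sB[s] - sA[s])
            if g != 0.0:
                j = s_post[s]
                vloc = Vd[j] if s_comp[s] == 1 else V[j]
                if s_nmda[s] == 1:
                    g *= 1.0 / (1.0 + 0.2801 * math.exp(-0.062 * vloc))
                if s_comp[s] == 1:
                    Gd[j] += g
                    GEd[j] += g * s_E[s]
                else:
                    Gs[j] += g
                    GEs[j] += g * s_E[s]
                if s_lfp[s] == 1:
                    lfp_t += g * (vloc - s_E[s])

        # external sensory events fan out to the TC synapses
        while ev_ptr < n_ev and ext_steps[ev_ptr] == t:
            for e in range(ext_syn.shape[0]):
                sA[ext_syn[e]] += 1.0
                sB[ext_syn[e]] += 1.0
            ev_ptr += 1

        lfp[t] = lfp_t

        # --- background OU conductances ------------------------------------
        for i in range(N):
            ou_e[i] = mu_e[i] + (ou_e[i] - mu_e[i]) * k_e \
                + sd_ke[i] * np.random.standard_normal()
            ou_i[i] = mu_i[i] + (ou_i[i] - mu_i[i]) * k_i \
                + sd_ki[i] * np.random.standard_normal()
            ge = ou_e[i] if ou_e[i] > 0.0 else 0.0
            gi = ou_i[i] if ou_i[i] > 0.0 else 0.0
            if noise_dend[i] == 1:
                Gd[i] += ge + gi
                GEd[i] += ge * E_e + gi * E_i
            else:
                Gs[i] += ge + gi
                GEs[i] += ge * E_e + gi * E_i

        # --- membrane update: two-stage (Heun) second-order step -----------
        for i in range(N):
            f = fam[i]
            d0 = _deriv(f, V[i], Vd[i], gh[i], gn[i], gr[i], ca[i],
                        gq[i], gb[i], Gs[i], GEs[i], Gd[i], GEd[i], iapp[i],
                        C[i], gNa[i], gK[i], gL[i], gLd[i], gC[i], gT[i],
                        gCa[i], gAHP[i], k1[i], ca_eps[i], ca_k[i], gKir[i],
                        gKA[i], gNaP[i], gKCa[i], gHVA[i], kca_half[i],
                        ca_alpha[i], ca_tau[i], gH[i], gKL[i], ENa[i], EK[i],
                        EL[i], ELd[i], ECa[i], EH[i],
                        m_th[i], m_sg[i], h_th[i], h_sg[i], h_t0[i], h_t1[i],
                        h_tt[i], h_ts[i], h_phi[i],
                        n_th[i], n_sg[i], n_t0[i], n_t1[i], n_tt[i], n_ts[i],
                        n_phi[i],
                        r_th[i], r_sg[i], r_t0[i], r_t1[i], r_tt[i], r_ts[i],
                        r_phi[i],
                        a_th[i], a_sg[i], aux1_th[i], aux1_sg[i], aux2_th[i],
                        aux2_sg[i], aux3_th[i], aux3_sg[i], aux3_tau[i], b_off)
            v1 = V[i] + dt * d0[0]
            vd1 = Vd[i] + dt * d0[1]
            h1 = gh[i] + dt * d0[2]
            n1 = gn[i] + dt * d0[3]
            r1 = gr[i] + dt * d0[4]
            ca1 = ca[i] + dt * d0[5]
            q1 = gq[i] + dt * d0[6]
            b1 = gb[i] + dt * d0[7]
            d1 = _deriv(f, v1, vd1, h1, n1, r1, ca1, q1, b1,
                        Gs[i], GEs[i], Gd[i], GEd[i], iapp[i],
                        C[i], gNa[i], gK[i], gL[i], gLd[i], gC[i], gT[i],
                        gCa[i], gAHP[i], k1[i], ca_eps[i], ca_k[i], gKir[i],
                        gKA[i], gNaP[i], gKCa[i], gHVA[i], kca_half[i],
                        ca_alpha[i], ca_tau[i], gH[i], gKL[i], ENa[i], EK[i],
                        EL[i], ELd[i], ECa[i], EH[i],
                        m_th[i], m_sg[i], h_th[i], h_sg[i], h_t0[i], h_t1[i],
                        h_tt[i], h_ts[i], h_phi[i],
                        n_th[i], n_sg[i], n_t0[i], n_t1[i], n_tt[i], n_ts[i],
                        n_phi[i],
                        r_th[i], r_sg[i], r_t0[i], r_t1[i], r_tt[i], r_ts[i],
                        r_phi[i],
                        a_th[i], a_sg[i], aux1_th[i], aux1_sg[i], aux2_th[i],
                        aux2_sg[i], aux3_th[i], aux3_sg[i], aux3_tau[i], b_off)
            V[i] += half * (d0[0] + d1[0])
            Vd[i] += half * (d0[1] + d1[1])
            gh[i] += half * (d0[2] + d1[2])
            gn[i] += half * (d0[3] + d1[3])
            gr[i] += half * (d0[4] + d1[4])
            ca[i] += half * (d0[5] + d1[5])
            gq[i] += half * (d0[6] + d1[6])
            gb[i] += half * (d0[7] + d1[7])

        # --- spikes ---------------------------------------------------------
        col = t % L
        for i in range(N):
            rb[i, col] = 0
            if armed[i] == 1:
                if V[i] >= thresh:
                    rb[i, col] = 1
                    armed[i] = 0
                    if n_spk < max_spk:
                        spike_t[n_spk] = t * dt
                        spike_id[n_spk] = i
                        n_spk += 1
            else:
                if V[i] < rearm:
                    armed[i] = 1

        for e in range(vrec_idx.shape[0]):
            vrec[t, e] = V[vrec_idx[e]]

        if (t & 1023) == 0:
            for i in range(N):
                if not math.isfinite(V[i]):
                    return n_spk, i, t
    for i in range(N):
        if not math.isfinite(V[i]):
            return n_spk, i, n_steps - 1
    return n_spk, -1, -1


def _gate(cfg, name, keys=("theta", "sigma")):
    g = cfg.get(name, None)
    out = []
    for k in keys:
        out.append(float(g[k]) if g is not None and k in g else 0.0)
    return out


class _Flat:
    """Per-cell parameter/state arrays compiled from a NetworkGraph."""

    def __init__(self, graph: NetworkGraph, multipliers=None, kind_folds=None):
        params = graph.params
        cells = params["cells"]
        N = graph.n_cells
        self.N = N
        self.graph = graph

        z = lambda: np.zeros(N)
        self.fam = np.zeros(N, dtype=np.int8)
        names = ("C gNa gK gL gLd gC gT gCa gAHP k1 ca_eps ca_k gKir gKA "
                 "gNaP gKCa gHVA kca_half ca_alpha ca_tau gH gKL iapp "
                 "ENa EK EL ELd ECa EH "
                 "m_th m_sg h_th h_sg h_t0 h_t1 h_tt h_ts h_phi "
                 "n_th n_sg n_t0 n_t1 n_tt n_ts n_phi "
                 "r_th r_sg r_t0 r_t1 r_tt r_ts r_phi "
                 "a_th a_sg aux1_th aux1_sg aux2_th aux2_sg "
                 "aux3_th aux3_sg aux3_tau").split()
        for nm in names:
            setattr(self, nm, z())
        self.aux3_tau += 1.0
        self.r_ts -= 1.0  # avoid division by zero where unused
        self.h_ts -= 1.0
        self.n_ts -= 1.0

        for pop, (start, count) in graph.populations.items():
            famname = graph.family[pop]
            cfg = cells[famname]
            sl = slice(start, start + count)
            self.fam[sl] = FAMILY_CODES[famname]
            simple = dict(C="C", gNa="gNa", gK="gK", gL="gL", gLd="gLd",
                          gC="gC", gT="gT", gCa="gCa", gAHP="gAHP", k1="k1",
                          ca_eps="ca_eps", ca_k="ca_k", gKir="gKir", gKA="gKA",
                          gNaP="gNaP", gKCa="gKCa", gHVA="gHVA",
                          kca_half="kca_half", ca_alpha="ca_alpha",
                          ca_tau="ca_tau", gH="gH", gKL="gKL",
                          ENa="ENa", EK="EK", EL="EL", ELd="ELd", ECa="ECa",
                          EH="EH")
            for attr, key in simple.items():
                if key in cfg:
                    getattr(self, attr)[sl] = float(cfg[key])
            if famname == "gp":
                self.iapp[sl] = float(cfg["i_app_gpe"] if pop == "GPe"
                                      else cfg["i_app_gpi"])
            else:
                self.iapp[sl] = float(cfg.get("i_app", 0.0))

            self.m_th[sl], self.m_sg[sl] = _gate(cfg, "m")
            for gate, pre in (("h", "h"), ("n", "n")):
                th, sg, t0, t1, tt, ts, phi = _gate(
                    cfg, gate, ("theta", "sigma", "tau0", "tau1", "theta_t",
                                "sigma_t", "phi"))
                for suffix, val in zip(
                        ("_th", "_sg", "_t0", "_t1", "_tt", "_ts", "_phi"),
                        (th, sg, t0, t1, tt, ts, phi)):
                    getattr(self, pre + suffix)[sl] = val
            if "r" in cfg:
                th, sg, t0, t1, tt, ts, phi = _gate(
                    cfg, "r", ("theta", "sigma", "tau0", "tau1", "theta_t",
                               "sigma_t", "phi"))
            elif "rT" in cfg:
                th, sg = _gate(cfg, "rT")
                t0, t1, tt, ts, phi = 1.0, 0.0, 0.0, -1.0, 1.0
            else:
                th = sg = 0.0
                t0, t1, tt, ts, phi = 1.0, 0.0, 0.0, -1.0, 1.0
            for suffix, val in zip(("_th", "_sg", "_t0", "_t1", "_tt",
                                    "_ts", "_phi"), (th, sg, t0, t1, tt, ts, phi)):
                getattr(self, "r" + suffix)[sl] = val

            if famname in ("stn", "gp"):
                self.a_th[sl], self.a_sg[sl] = _gate(cfg, "a")
                self.aux1_th[sl], self.aux1_sg[sl] = _gate(cfg, "s")
                if famname == "stn":
                    self.aux2_th[sl], self.aux2_sg[sl] = _gate(cfg, "b_r")
            elif famname in ("tc", "re"):
                self.a_th[sl], self.a_sg[sl] = _gate(cfg, "p")
                if famname == "tc":
                    self.aux1_th[sl], self.aux1_sg[sl] = _gate(cfg, "q")
                    self.aux2_th[sl], self.aux2_sg[sl] = _gate(cfg, "aA")
                    self.aux3_th[sl], self.aux3_sg[sl] = _gate(cfg, "bA")
                    self.aux3_tau[sl] = float(cfg["bA"]["tau"])
            elif famname == "msn":
                self.aux1_th[sl], self.aux1_sg[sl] = _gate(cfg, "kir")
                self.aux2_th[sl], self.aux2_sg[sl] = _gate(cfg, "aA")
                self.aux3_th[sl], self.aux3_sg[sl] = _gate(cfg, "bA")
                self.aux3_tau[sl] = float(cfg["bA"]["tau"])
            elif famname == "pyr":
                self.aux1_th[sl], self.aux1_sg[sl] = _gate(cfg, "pNaP")
                self.aux2_th[sl], self.aux2_sg[sl] = _gate(cfg, "uHVA")

        # conductance modulation (channel targets)
        multipliers = multipliers or {}
        for (pop, target), mult in multipliers.items():
            if pop not in graph.populations:
                continue
            attrs = CHANNEL_TARGET_ATTR.get(target)
            if attrs is None:
                continue  # synaptic target, handled below
            sl = graph.slice(pop)
            for attr in attrs:
                getattr(self, attr)[sl] *= mult

        # --- synapses -------------------------------------------------------
        kind_folds = kind_folds or {}
        dt = params["integration"]["dt_ms"]
        pre_l, post_l, comp_l, nmda_l, w_l, E_l, fr_l, fd_l, dstep_l, lfp_l = \
            ([] for _ in range(10))
        pyr_s, pyr_c = graph.populations["Pyr"]
        for name in sorted(graph.projections):
            proj = graph.projections[name]
            spec = proj.spec
            mult = multipliers.get((proj.post_pop, proj.target), 1.0) \
                if proj.target else 1.0
            kf = kind_folds.get(
                {"AMPA": "AMPA", "NMDA": "NMDA", "GABA": "GABA_A",
                 "mGluR": "mGluR"}[spec.kind], 1.0)
            if spec.kind == "NMDA" and proj.post_pop in ("Pyr", "BC"):
                # NR2B-carrying NMDA receptors are restricted to cortex
                kf *= kind_folds.get("NMDA_cortical", 1.0)
            w = spec.gmax * spec.norm * mult * kf
            n_e = len(proj)
            pre_l.append(proj.pre.astype(np.int64))
            post_l.append(proj.post.astype(np.int64))
            comp_l.append(np.full(n_e, 1 if proj.comp == "dend" else 0,
                                  dtype=np.int8))
            nmda_l.append(np.full(n_e, 1 if spec.mg_block else 0,
                                  dtype=np.int8))
            w_l.append(np.full(n_e, w))
            E_l.append(np.full(n_e, spec.reversal))
            fr_l.append(np.full(n_e, math.exp(-dt / spec.t_rise)))
            fd_l.append(np.full(n_e, math.exp(-dt / spec.t_decay)))
            dstep_l.append(np.maximum(
                1, np.round(proj.delay_ms / dt)).astype(np.int64))
            lfp_l.append(((proj.post >= pyr_s)
                          & (proj.post < pyr_s + pyr_c)).astype(np.int8))
        self.s_pre = np.concatenate(pre_l)
        self.s_post = np.concatenate(post_l)
        self.s_comp = np.concatenate(comp_l)
        self.s_nmda = np.concatenate(nmda_l)
        self.s_w = np.concatenate(w_l)
        self.s_E = np.concatenate(E_l)
        self.s_fr = np.concatenate(fr_l)
        self.s_fd = np.concatenate(fd_l)
        self.s_dstep = np.concatenate(dstep_l)
        self.s_lfp = np.concatenate(lfp_l)
        self.ext_syn = np.nonzero(self.s_pre < 0)[0].astype(np.int64)
        self.dt = dt

        # --- noise ----------------------------------------------------------
        noise = params["noise"]
        self.mu_e, self.sd_e, self.mu_i, self.sd_i = z(), z(), z(), z()
        self.noise_dend = np.zeros(N, dtype=np.int8)
        for pop, (start, count) in graph.populations.items():
            cfgn = noise["by_population"][pop]
            sl = slice(start, start + count)
            self.mu_e[sl] = cfgn["mu_e"]
            self.sd_e[sl] = cfgn["sd_e"]
            self.mu_i[sl] = cfgn["mu_i"]
            self.sd_i[sl] = cfgn["sd_i"]
            if graph.family[pop] in ("msn", "pyr"):
                self.noise_dend[sl] = 1
        self.tau_e = noise["tau_e_ms"]
        self.tau_i = noise["tau_i_ms"]
        self.E_e = noise["E_e"]
        self.E_i = noise["E_i"]


def run_simulation(
    graph: NetworkGraph,
    duration: float,
    seed: int,
    multipliers=None,
    kind_folds=None,
    evoked=None,
    noise_scale: float = 1.0,
    dt: float | None = None,
    record_voltages: tuple = (),
    max_rate_hz: float = 400.0,
) -> SimResult:
    """Integrate the network for ``duration`` ms.

    ``multipliers`` maps (population, target) -> conductance multiplier (from
    :func:`bgqsp.coupling.apply_modulation` plus disease structural factors);
    ``kind_folds`` applies global folds per synapse kind (e.g. an NMDA
    conductance reducer); ``evoked`` is an array of external event times (ms)
    fanned out to the TC cells.  Reproducible bit-for-bit per (config, seed).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    flat = _Flat(graph, multipliers, kind_folds)
    if dt is not None and not np.isclose(dt, flat.dt):
        if dt > 0.05 + 1e-12:
            raise ValueError("accuracy contract requires dt <= 0.05 ms")
        scale = flat.dt / dt
        flat.dt = dt
        # recompute per-dt decay factors
        flat.s_fr = flat.s_fr ** (1.0 / scale)
        flat.s_fd = flat.s_fd ** (1.0 / scale)
        flat.s_dstep = np.maximum(1, np.round(flat.s_dstep * scale).astype(np.int64))
    dt = flat.dt
    n_steps = int(round(duration / dt))

    rng = np.random.default_rng(seed)
    N = flat.N
    V = np.empty(N)
    for pop, (start, count) in graph.populations.items():
        V[start:start + count] = (_REST_V[graph.family[pop]]
                                  + rng.uniform(-3.0, 3.0, count))
    Vd = V.copy()
    gh = np.array([_sig_py(V[i], flat.h_th[i], flat.h_sg[i]) for i in range(N)])
    gn = np.array([_sig_py(V[i], flat.n_th[i], flat.n_sg[i]) for i in range(N)])
    gr = np.array([_sig_py(V[i], flat.r_th[i], flat.r_sg[i]) for i in range(N)])
    ca = np.full(N, 0.05)
    gq = np.zeros(N)
    gb = np.array([_sig_py(V[i], flat.aux3_th[i], flat.aux3_sg[i])
                   if flat.aux3_sg[i] != 0 else 0.0 for i in range(N)])

    sA = np.zeros(len(flat.s_pre))
    sB = np.zeros(len(flat.s_pre))
    ou_e = flat.mu_e.copy()
    ou_i = flat.mu_i.copy()
    mu_e = flat.mu_e * noise_scale
    mu_i = flat.mu_i * noise_scale
    k_e = math.exp(-dt / flat.tau_e)
    k_i = math.exp(-dt / flat.tau_i)
    sd_ke = flat.sd_e * noise_scale * math.sqrt(1.0 - k_e * k_e)
    sd_ki = flat.sd_i * noise_scale * math.sqrt(1.0 - k_i * k_i)

    if evoked is None or len(evoked) == 0:
        ext_steps = np.zeros(0, dtype=np.int64)
    else:
        ext_steps = np.sort(np.round(np.asarray(evoked, dtype=float) / dt)
                            ).astype(np.int64)
        ext_steps = ext_steps[(ext_steps >= 0) & (ext_steps < n_steps)]

    max_spk = int(N * duration / 1000.0 * max_rate_hz) + 64
    spike_t = np.zeros(max_spk)
    spike_id = np.zeros(max_spk, dtype=np.int64)
    lfp = np.zeros(n_steps)
    vrec_idx = np.array(record_voltages, dtype=np.int64)
    vrec = np.zeros((n_steps if len(vrec_idx) else 0, len(vrec_idx)))

    kernel_seed = int(seed) % (2 ** 31 - 1)
    n_spk, err_cell, err_step = _kernel(
        n_steps, dt, flat.fam,
        V, Vd, gh, gn, gr, ca, gq, gb,
        flat.C, flat.gNa, flat.gK, flat.gL, flat.gLd, flat.gC, flat.gT,
        flat.gCa, flat.gAHP, flat.k1, flat.ca_eps, flat.ca_k,
        flat.gKir, flat.gKA, flat.gNaP, flat.gKCa, flat.gHVA, flat.kca_half,
        flat.ca_alpha, flat.ca_tau, flat.gH, flat.gKL, flat.iapp,
        flat.ENa, flat.EK, flat.EL, flat.ELd, flat.ECa, flat.EH,
        flat.m_th, flat.m_sg,
        flat.h_th, flat.h_sg, flat.h_t0, flat.h_t1, flat.h_tt, flat.h_ts,
        flat.h_phi,
        flat.n_th, flat.n_sg, flat.n_t0, flat.n_t1, flat.n_tt, flat.n_ts,
        flat.n_phi,
        flat.r_th, flat.r_sg, flat.r_t0, flat.r_t1, flat.r_tt, flat.r_ts,
        flat.r_phi,
        flat.a_th, flat.a_sg, flat.aux1_th, flat.aux1_sg, flat.aux2_th,
        flat.aux2_sg, flat.aux3_th, flat.aux3_sg, flat.aux3_tau,
        flat.s_pre, flat.s_post, flat.s_comp, flat.s_nmda, flat.s_w, flat.s_E,
        flat.s_fr, flat.s_fd, flat.s_dstep, flat.s_lfp,
        sA, sB, ext_steps, flat.ext_syn,
        mu_e, sd_ke, mu_i, sd_ki, k_e, k_i, flat.E_e, flat.E_i, ou_e, ou_i,
        flat.noise_dend,
        graph.params["integration"]["spike_threshold_mV"],
        graph.params["integration"]["spike_reset_below_mV"],
        kernel_seed,
        lfp, spike_t, spike_id, vrec_idx, vrec,
    )
    if err_cell >= 0:
        pop = graph.population_of(err_cell)
        raise FloatingPointError(
            f"non-finite membrane potential in cell {err_cell} ({pop}) "
            f"at t = {err_step * dt:.3f} ms"
        )
    return SimResult(
        dt=dt, duration=duration,
        spike_times=spike_t[:n_spk].copy(),
        spike_cells=spike_id[:n_spk].copy(),
        pyr_synaptic_current=lfp,
        populations=dict(graph.populations),
        seed=seed,
        voltages=vrec if len(vrec_idx) else None,
        voltage_cells=tuple(record_voltages),
    )


def _sig_py(v, theta, sigma):
    if sigma == 0.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-(v - theta) / sigma))


def integrate_single_cell(
    population: str,
    duration: float,
    i_app: float | None = None,
    dt: float = 0.025,
    seed: int = 0,
    overrides=None,
    V0: float | None = None,
):
    """Integrate one isolated, noise-free cell of a population.

    Returns (time_ms, V_trace, spike_times).  ``overrides`` patches the
    family's channel constants (e.g. zeroing every conductance but the leak);
    used by the integrator accuracy tests and for single-cell exploration.
    """
    graph = build_network(seed)
    # keep only the requested cell: zero all synapses and noise
    idx = graph.populations[population][0]
    if overrides:
        fam = graph.family[population]
        graph.params["cells"][fam].update(overrides)
    for cfgn in graph.params["noise"]["by_population"].values():
        cfgn["mu_e"] = cfgn["sd_e"] = cfgn["mu_i"] = cfgn["sd_i"] = 0.0
    flat = _Flat(graph)
    flat.s_w[:] = 0.0
    if i_app is not None:
        flat.iapp[:] = 0.0
        flat.iapp[idx] = i_app
    if dt != flat.dt:
        flat.dt = dt

    n_steps = int(round(duration / dt))
    N = flat.N
    V = np.full(N, -65.0)
    for pop, (start, count) in graph.populations.items():
        V[start:start + count] = _REST_V[graph.family[pop]]
    if V0 is not None:
        V[idx] = V0
    Vd = V.copy()
    gh = np.array([_sig_py(V[i], flat.h_th[i], flat.h_sg[i]) for i in range(N)])
    gn = np.array([_sig_py(V[i], flat.n_th[i], flat.n_sg[i]) for i in range(N)])
    gr = np.array([_sig_py(V[i], flat.r_th[i], flat.r_sg[i]) for i in range(N)])
    ca = np.full(N, 0.05)
    gq = np.zeros(N)
    gb = np.array([_sig_py(V[i], flat.aux3_th[i], flat.aux3_sg[i])
                   if flat.aux3_sg[i] != 0 else 0.0 for i in range(N)])
    sA = np.zeros(len(flat.s_pre))
    sB = np.zeros(len(flat.s_pre))
    zero = np.zeros(N)
    # other cells may spike spontaneously; size the buffer for all of them
    spike_t = np.zeros(int(N * duration * 0.4) + 64)
    spike_id = np.zeros(len(spike_t), dtype=np.int64)
    lfp = np.zeros(n_steps)
    vrec_idx = np.array([idx], dtype=np.int64)
    vrec = np.zeros((n_steps, 1))
    n_spk, err_cell, err_step = _kernel(
        n_steps, dt, flat.fam,
        V, Vd, gh, gn, gr, ca, gq, gb,
        flat.C, flat.gNa, flat.gK, flat.gL, flat.gLd, flat.gC, flat.gT,
        flat.gCa, flat.gAHP, flat.k1, flat.ca_eps, flat.ca_k,
        flat.gKir, flat.gKA, flat.gNaP, flat.gKCa, flat.gHVA, flat.kca_half,
        flat.ca_alpha, flat.ca_tau, flat.gH, flat.gKL, flat.iapp,
        flat.ENa, flat.EK, flat.EL, flat.ELd, flat.ECa, flat.EH,
        flat.m_th, flat.m_sg,
        flat.h_th, flat.h_sg, flat.h_t0, flat.h_t1, flat.h_tt, flat.h_ts,
        flat.h_phi,
        flat.n_th, flat.n_sg, flat.n_t0, flat.n_t1, flat.n_tt, flat.n_ts,
        flat.n_phi,
        flat.r_th, flat.r_sg, flat.r_t0, flat.r_t1, flat.r_tt, flat.r_ts,
        flat.r_phi,
        flat.a_th, flat.a_sg, flat.aux1_th, flat.aux1_sg, flat.aux2_th,
        flat.aux2_sg, flat.aux3_th, flat.aux3_sg, flat.aux3_tau,
        flat.s_pre, flat.s_post, flat.s_comp, flat.s_nmda, flat.s_w, flat.s_E,
        flat.s_fr, flat.s_fd, flat.s_dstep, flat.s_lfp,
        sA, sB, np.zeros(0, dtype=np.int64), flat.ext_syn,
        zero, zero, zero, zero, 1.0, 1.0, 0.0, -80.0, zero.copy(), zero.copy(),
        flat.noise_dend,
        graph.params["integration"]["spike_threshold_mV"],
        graph.params["integration"]["spike_reset_below_mV"],
        1,
        lfp, spike_t, spike_id, vrec_idx, vrec,
    )
    if err_cell >= 0:
        raise FloatingPointError(
            f"non-finite membrane potential at t = {err_step * dt:.3f} ms"
        )
    t = np.arange(n_steps) * dt
    mine = spike_id[:n_spk] == idx
    return t, vrec[:, 0], spike_t[:n_spk][mine]
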