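"""Delay-coupled whole-brain network of ALN mean-field nodes.

Each node is a two-population (excitatory/inhibitory) mean-field reduction of
a spiking AdEx network.  Population state evolves through precomputed transfer
functions (rate, mean voltage, effective timescale), saturating synaptic
activation variables with mean and variance dynamics, an adiabatic mean
adaptation current on the excitatory population, and Ornstein-Uhlenbeck
background noise.  Nodes are coupled excitatory-to-excitatory through a
structural connectome with per-edge axonal delays.

Integration is Euler forward at ``dt`` (default 0.1 ms); delays are rounded to
integer multiples of ``dt``.  A simulation is a pure function of
(connectome, parameters, seed): identical inputs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .transfer_tables import TransferTables, lookup

__all__ = [
    "PopulationParams",
    "GlobalParams",
    "Connectome",
    "NodeState",
    "SimulationOutput",
    "ou_step",
    "effective_input_rates",
    "node_step",
    "simulate",
]


@dataclass(frozen=True)
class PopulationParams:
    """ALN population parameters (defaults: whole-brain resting-state set)."""

    J_EE: float = 2.4     # maximum synaptic currents (mV/ms)
    J_IE: float = 2.6
    J_EI: float = -3.3
    J_II: float = -1.6
    c_EE: float = 0.3     # single-spike PSC amplitudes (mV/ms)
    c_IE: float = 0.3
    c_EI: float = 0.5
    c_II: float = 0.5
    tau_s_E: float = 2.0  # synaptic time constants (ms)
    tau_s_I: float = 5.0
    K_E: int = 800        # inputs per neuron
    K_I: int = 200
    d_E: float = 4.0      # local synaptic delays (ms), indexed by target pop
    d_I: float = 2.0
    sigma_ext: float = 1.5   # std of external input (mV/sqrt(ms))
    mu_E_ext: float = 1.63   # mean external inputs (mV/ms)
    mu_I_ext: float = 0.05
    alpha: float = 28.26     # subthreshold adaptation conductance (nS)
    beta: float = 24.04      # spike-triggered adaptation increment (pA)
    tau_A: float = 200.0     # adaptation time constant (ms)
    E_A: float = -80.0       # adaptation reversal (mV)

    def __post_init__(self):
        if self.tau_s_E <= 0 or self.tau_s_I <= 0 or self.tau_A <= 0:
            raise ValueError("time constants must be positive")
        if self.K_E <= 0 or self.K_I <= 0:
            raise ValueError("input counts must be positive")
        if not (self.J_EE > 0 and self.J_IE > 0):
            raise ValueError("excitatory synaptic currents must be positive")
        if not (self.J_EI < 0 and self.J_II < 0):
            raise ValueError("inhibitory synaptic currents must be negative")


@dataclass(frozen=True)
class GlobalParams:
    """Network-level simulation parameters."""

    K_gl: float = 250.0     # global coupling strength
    v_gl: float = 20.0      # global signal speed (m/s)
    sigma_ou: float = 0.19  # OU fluctuation amplitude (mV*ms^-3/2)
    tau_ou: float = 5.0     # OU time constant (ms)
    dt: float = 0.1         # integration step (ms)
    duration: float = 70.0  # total simulated time (s)
    transient: float = 5.0  # discarded initial span (s)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.duration > self.transient >= 0:
            raise ValueError("need duration > transient >= 0")
        if self.tau_ou <= 0 or self.sigma_ou < 0:
            raise ValueError("invalid OU parameters")


@dataclass
class Connectome:
    """Network substrate: coupling strengths, delays and region labels."""

    C: np.ndarray         # (n, n) dimensionless, max-normalized
    D: np.ndarray         # (n, n) delays in ms
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if not self.labels:
            self.labels = [f"region_{i:03d}" for i in range(self.C.shape[0])]

    @property
    def n(self) -> int:
        return self.C.shape[0]

    def validate(self) -> None:
        C, D = self.C, self.D
        if C.shape != (self.n, self.n) or D.shape != (self.n, self.n):
            raise ValueError("C and D must be square with matching shape")
        if len(self.labels) != self.n:
            raise ValueError("labels length does not match region count")
        if not np.allclose(C, C.T):
            raise ValueError("C must be symmetric")
        if np.any(C < 0) or np.any(D < 0):
            raise ValueError("C and D must be non-negative")
        if not np.allclose(np.diag(C), 0):
            raise ValueError("C must have a zero diagonal")
        if C.max() > 0 and not np.isclose(C.max(), 1.0):
            raise ValueError("C must be max-normalized (max entry 1)")
        if not np.allclose(D, D.T):
            raise ValueError("D must be symmetric")


@dataclass
class NodeState:
    """Per-node ALN state (arrays of shape (n,))."""

    mu_E: np.ndarray
    mu_I: np.ndarray
    mu_ou_E: np.ndarray
    mu_ou_I: np.ndarray
    s_EE: np.ndarray
    s_EI: np.ndarray
    s_IE: np.ndarray
    s_II: np.ndarray
    v_EE: np.ndarray
    v_EI: np.ndarray
    v_IE: np.ndarray
    v_II: np.ndarray
    I_A: np.ndarray
    V_E: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "NodeState":
        return cls(*[np.zeros(n) for _ in range(16)])


@dataclass
class SimulationOutput:
    """Excitatory rate traces (kHz) after the transient, plus provenance."""

    rate_E: np.ndarray      # (n, T)
    t_ms: np.ndarray        # (T,) time axis relative to simulation start
    output_step_ms: float
    seed: int
    params: dict
    n_clamp_events: int = 0


def ou_step(mu_ou, sigma_ou: float, tau_ou: float, dt: float, rng):
    """One Euler-Maruyama step of the zero-mean OU noise process."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    mu_ou = np.asarray(mu_ou, dtype=float)
    xi = rng.standard_normal(mu_ou.shape if mu_ou.ndim else None)
    return mu_ou + dt * (-mu_ou / tau_ou) + sigma_ou * np.sqrt(dt) * xi


def effective_input_rates(state_history: dict, connectome: Connectome,
                          pop: PopulationParams, K_gl: float,
                          dt: float = 0.1):
    """Mean and variance of the effective input rates at the current time.

    ``state_history`` maps ``"r_E"``/``"r_I"`` to arrays of shape (n, T) whose
    last column is the present step; delayed terms index backwards from it.
    Local delays are target-population specific (``d_E`` for inputs to E,
    ``d_I`` for inputs to I); inter-regional coupling is E-to-E only.

    Returns two dicts keyed ``"EE", "EI", "IE", "II"`` of per-node arrays.
    """
    rE, rI = np.asarray(state_history["r_E"]), np.asarray(state_history["r_I"])
    n, T = rE.shape
    Dsteps = np.rint(connectome.D / dt).astype(np.int64)
    dE = int(round(pop.d_E / dt))
    dI = int(round(pop.d_I / dt))
    need = max(int(Dsteps.max()) if n > 1 else 0, dE, dI) + 1
    if T < need:
        raise ValueError(
            f"history buffer spans {T} steps but {need} are required "
            f"(max delay {need - 1} steps at dt={dt} ms)")

    def delayed(r, d):
        return r[:, T - 1 - d]

    inter = np.zeros(n)
    inter2 = np.zeros(n)
    for i in range(n):
        for j in range(n):
            v = rE[j, T - 1 - Dsteps[i, j]]
            inter[i] += connectome.C[i, j] * v
            inter2[i] += connectome.C[i, j] ** 2 * v
    r_ab, rho_ab = {}, {}
    spec = {
        "EE": (pop.c_EE, pop.J_EE, pop.tau_s_E, pop.K_E, delayed(rE, dE), True),
        "EI": (pop.c_EI, pop.J_EI, pop.tau_s_I, pop.K_I, delayed(rI, dE), False),
        "IE": (pop.c_IE, pop.J_IE, pop.tau_s_E, pop.K_E, delayed(rE, dI), False),
        "II": (pop.c_II, pop.J_II, pop.tau_s_I, pop.K_I, delayed(rI, dI), False),
    }
    for key, (c, J, tau_s, K, r_del, is_EE) in spec.items():
        glob = K_gl * inter if is_EE else 0.0
        glob2 = K_gl * inter2 if is_EE else 0.0
        # one spike contributes a PSC of amplitude c_ab, activating a fraction
        # c_ab/|J_ab| of the remaining inactive synapses
        r_ab[key] = c / abs(J) * tau_s * (K * r_del + glob)
        rho_ab[key] = (c / abs(J) * tau_s) ** 2 * (K * r_del + glob2)
    return r_ab, rho_ab


def node_step(state: NodeState, r_ab: dict, rho_ab: dict,
              tables: TransferTables, pop: PopulationParams, dt: float,
              sigma_ou_input=None):
    """One Euler step of every node's populations given effective input rates.

    Mutates and returns ``state``.  ``sigma_ou_input`` optionally supplies the
    already-updated OU currents (pair of arrays for E and I)."""
    p = pop
    tau_m = tables.neuron.tau_m
    Cap = tables.neuron.C
    clamps = 0
    syn = {"EE": (p.tau_s_E,), "EI": (p.tau_s_I,),
           "IE": (p.tau_s_E,), "II": (p.tau_s_I,)}
    for key, (tau_s,) in syn.items():
        s = getattr(state, f"s_{key}")
        v = getattr(state, f"v_{key}")
        r = np.asarray(r_ab[key], dtype=float)
        rho = np.asarray(rho_ab[key], dtype=float)
        # exponential update of the locally linear synapse ODEs (see kernel)
        s_star = r / (r + 1.0)
        s_new = s_star + (s - s_star) * np.exp(-(r + 1.0) / tau_s * dt)
        B = (2.0 * tau_s * (r + 1.0) - rho) / tau_s ** 2
        A = (1.0 - s_new) ** 2 * rho / tau_s ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            v_star = np.where(B > 0, A / np.where(B > 0, B, 1.0), 0.0)
        v_new = np.where(B > 0, v_star + (v - v_star) * np.exp(-B * dt),
                         v + dt * (A - B * v))
        bad = v_new < 0
        clamps += int(np.count_nonzero(bad))
        v_new = np.maximum(v_new, 0.0)
        setattr(state, f"s_{key}", s_new)
        setattr(state, f"v_{key}", v_new)

    def sigma_sq(Jb, vb, tau_sb, rb):
        return (2.0 * Jb ** 2 * vb * tau_sb * tau_m
                / ((1.0 + rb) * tau_m + tau_sb))

    sig_E = np.sqrt(sigma_sq(p.J_EE, state.v_EE, p.tau_s_E, r_ab["EE"])
                    + sigma_sq(p.J_EI, state.v_EI, p.tau_s_I, r_ab["EI"])
                    + p.sigma_ext ** 2)
    sig_I = np.sqrt(sigma_sq(p.J_IE, state.v_IE, p.tau_s_E, r_ab["IE"])
                    + sigma_sq(p.J_II, state.v_II, p.tau_s_I, r_ab["II"])
                    + p.sigma_ext ** 2)
    if sigma_ou_input is not None:
        state.mu_ou_E, state.mu_ou_I = sigma_ou_input

    mu_syn_E = p.J_EE * state.s_EE + p.J_EI * state.s_EI
    mu_syn_I = p.J_IE * state.s_IE + p.J_II * state.s_II
    _, _, tau_E = lookup(tables, state.mu_E - state.I_A / Cap, sig_E)
    _, _, tau_I = lookup(tables, state.mu_I, sig_I)
    state.mu_E = state.mu_E + dt * (mu_syn_E + p.mu_E_ext + state.mu_ou_E
                                    - state.mu_E) / tau_E
    state.mu_I = state.mu_I + dt * (mu_syn_I + p.mu_I_ext + state.mu_ou_I
                                    - state.mu_I) / tau_I
    r_E, V_E, _ = lookup(tables, state.mu_E - state.I_A / Cap, sig_E)
    r_I, _, _ = lookup(tables, state.mu_I, sig_I)
    state.r_E = np.atleast_1d(r_E)
    state.r_I = np.atleast_1d(r_I)
    state.V_E = np.atleast_1d(V_E)
    state.I_A = state.I_A + dt * ((p.alpha * (state.V_E - p.E_A) - state.I_A)
                                  / p.tau_A + p.beta * state.r_E)
    return state, clamps


@njit(cache=False, fastmath=True, inline="always")
def _bilinear_uniform(table, x0, dx, nx, y0, dy, ny, x, y):
    fx = (x - x0) / dx
    if fx <= 0.0:
        ix = 0
        fx = 0.0
    elif fx >= nx - 1:
        ix = nx - 2
        fx = 1.0
    else:
        ix = int(fx)
        fx -= ix
    fy = (y - y0) / dy
    if fy <= 0.0:
        iy = 0
        fy = 0.0
    elif fy >= ny - 1:
        iy = ny - 2
        fy = 1.0
    else:
        iy = int(fy)
        fy -= iy
    v00 = table[ix, iy]
    v10 = table[ix + 1, iy]
    v01 = table[ix, iy + 1]
    v11 = table[ix + 1, iy + 1]
    return ((1.0 - fx) * (1.0 - fy) * v00 + fx * (1.0 - fy) * v10
            + (1.0 - fx) * fy * v01 + fx * fy * v11)


@njit(cache=False, fastmath=True)
def _network_kernel(n, n_steps, dt, cptr, cidx, cw, cw2, dsteps_flat,
                    dE_steps, dI_steps, L,
                    mu_grid, sig_grid, r_tab, V_tab, tau_tab,
                    JEE, JIE, JEI, JII, aEE, aEI, aIE, aII,
                    tsE, tsI, KE, KI, sig_ext, muEext, muIext,
                    alpha, beta, tauA, EA, Cap, tau_m,
                    Kgl, sig_ou, tau_ou, seed, use_noise, noise,
                    transient_steps, decim, r_init, out_rE):
    np.random.seed(seed)
    mu0 = mu_grid[0]
    dmu = mu_grid[1] - mu_grid[0]
    nmu = mu_grid.shape[0]
    sg0 = sig_grid[0]
    dsg = sig_grid[1] - sig_grid[0]
    nsg = sig_grid.shape[0]
    # history buffers seeded with a moderate rate so that a self-sustained
    # (coupling-maintained) active state can be reached from rest; the
    # transient window absorbs the settling either way
    histE = np.full((L, n), r_init)
    histI = np.full((L, n), r_init)
    muE = np.zeros(n)
    muI = np.zeros(n)
    ouE = np.zeros(n)
    ouI = np.zeros(n)
    sEE = np.zeros(n)
    sEI = np.zeros(n)
    sIE = np.zeros(n)
    sII = np.zeros(n)
    vEE = np.zeros(n)
    vEI = np.zeros(n)
    vIE = np.zeros(n)
    vII = np.zeros(n)
    IA = np.zeros(n)
    sqdt = np.sqrt(dt)
    sig_ext2 = sig_ext * sig_ext
    clamps = 0
    out_col = 0
    for t in range(n_steps):
        slot_next = t + 1 - ((t + 1) // L) * L
        tE = t - dE_steps
        if tE < 0:
            tE += L
        else:
            tE -= (tE // L) * L
        tI = t - dI_steps
        if tI < 0:
            tI += L
        else:
            tI -= (tI // L) * L
        for i in range(n):
            rE_dE = histE[tE, i]
            rI_dE = histI[tE, i]
            rE_dI = histE[tI, i]
            rI_dI = histI[tI, i]
            inter = 0.0
            inter2 = 0.0
            for e in range(cptr[i], cptr[i + 1]):
                td = t - dsteps_flat[e]
                if td < 0:
                    td += L
                else:
                    td -= (td // L) * L
                v = histE[td, cidx[e]]
                inter += cw[e] * v
                inter2 += cw2[e] * v
            rEEd = aEE * tsE * (KE * rE_dE + Kgl * inter)
            rhoEE = (aEE * tsE) ** 2 * (KE * rE_dE + Kgl * inter2)
            rEId = aEI * tsI * (KI * rI_dE)
            rhoEI = (aEI * tsI) ** 2 * (KI * rI_dE)
            rIEd = aIE * tsE * (KE * rE_dI)
            rhoIE = (aIE * tsE) ** 2 * (KE * rE_dI)
            rIId = aII * tsI * (KI * rI_dI)
            rhoII = (aII * tsI) ** 2 * (KI * rI_dI)

            # synaptic mean/variance dynamics: exponential update of the
            # locally linear ODEs (exact for frozen drive, Euler-consistent
            # as dt -> 0, and unconditionally keeps s in [0,1], v >= 0)
            a = (rEEd + 1.0) / tsE
            star = rEEd / (rEEd + 1.0)
            sEE[i] = star + (sEE[i] - star) * np.exp(-a * dt)
            B = (2.0 * tsE * (rEEd + 1.0) - rhoEE) / (tsE * tsE)
            A = (1.0 - sEE[i]) ** 2 * rhoEE / (tsE * tsE)
            if B > 0.0:
                vst = A / B
                vEE[i] = vst + (vEE[i] - vst) * np.exp(-B * dt)
            else:
                vEE[i] += dt * (A - B * vEE[i])
            a = (rEId + 1.0) / tsI
            star = rEId / (rEId + 1.0)
            sEI[i] = star + (sEI[i] - star) * np.exp(-a * dt)
            B = (2.0 * tsI * (rEId + 1.0) - rhoEI) / (tsI * tsI)
            A = (1.0 - sEI[i]) ** 2 * rhoEI / (tsI * tsI)
            if B > 0.0:
                vst = A / B
                vEI[i] = vst + (vEI[i] - vst) * np.exp(-B * dt)
            else:
                vEI[i] += dt * (A - B * vEI[i])
            a = (rIEd + 1.0) / tsE
            star = rIEd / (rIEd + 1.0)
            sIE[i] = star + (sIE[i] - star) * np.exp(-a * dt)
            B = (2.0 * tsE * (rIEd + 1.0) - rhoIE) / (tsE * tsE)
            A = (1.0 - sIE[i]) ** 2 * rhoIE / (tsE * tsE)
            if B > 0.0:
                vst = A / B
                vIE[i] = vst + (vIE[i] - vst) * np.exp(-B * dt)
            else:
                vIE[i] += dt * (A - B * vIE[i])
            a = (rIId + 1.0) / tsI
            star = rIId / (rIId + 1.0)
            sII[i] = star + (sII[i] - star) * np.exp(-a * dt)
            B = (2.0 * tsI * (rIId + 1.0) - rhoII) / (tsI * tsI)
            A = (1.0 - sII[i]) ** 2 * rhoII / (tsI * tsI)
            if B > 0.0:
                vst = A / B
                vII[i] = vst + (vII[i] - vst) * np.exp(-B * dt)
            else:
                vII[i] += dt * (A - B * vII[i])
            if vEE[i] < 0.0:
                vEE[i] = 0.0
                clamps += 1
            if vEI[i] < 0.0:
                vEI[i] = 0.0
                clamps += 1
            if vIE[i] < 0.0:
                vIE[i] = 0.0
                clamps += 1
            if vII[i] < 0.0:
                vII[i] = 0.0
                clamps += 1

            sigE2 = (2.0 * JEE * JEE * vEE[i] * tsE * tau_m
                     / ((1.0 + rEEd) * tau_m + tsE)
                     + 2.0 * JEI * JEI * vEI[i] * tsI * tau_m
                     / ((1.0 + rEId) * tau_m + tsI) + sig_ext2)
            sigI2 = (2.0 * JIE * JIE * vIE[i] * tsE * tau_m
                     / ((1.0 + rIEd) * tau_m + tsE)
                     + 2.0 * JII * JII * vII[i] * tsI * tau_m
                     / ((1.0 + rIId) * tau_m + tsI) + sig_ext2)
            sigE = np.sqrt(sigE2)
            sigI = np.sqrt(sigI2)

            # OU noise, one independent stream per population per region
            if use_noise == 1:
                xiE = noise[t, i]
                xiI = noise[t, n + i]
            else:
                xiE = np.random.normal()
                xiI = np.random.normal()
            ouE[i] += dt * (-ouE[i] / tau_ou) + sig_ou * sqdt * xiE
            ouI[i] += dt * (-ouI[i] / tau_ou) + sig_ou * sqdt * xiI

            mu_syn_E = JEE * sEE[i] + JEI * sEI[i]
            mu_syn_I = JIE * sIE[i] + JII * sII[i]
            muq = muE[i] - IA[i] / Cap
            tauE = _bilinear_uniform(tau_tab, mu0, dmu, nmu, sg0, dsg, nsg,
                                     muq, sigE)
            tauI = _bilinear_uniform(tau_tab, mu0, dmu, nmu, sg0, dsg, nsg,
                                     muI[i], sigI)
            muE[i] += dt * (mu_syn_E + muEext + ouE[i] - muE[i]) / tauE
            muI[i] += dt * (mu_syn_I + muIext + ouI[i] - muI[i]) / tauI
            muq = muE[i] - IA[i] / Cap
            rE_new = _bilinear_uniform(r_tab, mu0, dmu, nmu, sg0, dsg, nsg,
                                       muq, sigE)
            VE_new = _bilinear_uniform(V_tab, mu0, dmu, nmu, sg0, dsg, nsg,
                                       muq, sigE)
            rI_new = _bilinear_uniform(r_tab, mu0, dmu, nmu, sg0, dsg, nsg,
                                       muI[i], sigI)
            IA[i] += dt * ((alpha * (VE_new - EA) - IA[i]) / tauA
                           + beta * rE_new)
            if not (np.isfinite(muE[i]) and np.isfinite(muI[i])
                    and np.isfinite(rE_new)):
                return -(t + 1), i, clamps
            histE[slot_next, i] = rE_new
            histI[slot_next, i] = rI_new
        if (t + 1) > transient_steps and ((t + 1) - transient_steps) % decim == 0:
            for i in range(n):
                out_rE[i, out_col] = histE[slot_next, i]
            out_col += 1
    return n_steps, -1, clamps


def simulate(connectome: Connectome, pop: PopulationParams,
             glob: GlobalParams, seed: int, tables: TransferTables,
             output_step_ms: float = 1.0,
             noise: np.ndarray | None = None,
             r_init: float = 0.05) -> SimulationOutput:
    """Integrate the full delay-coupled network and return rate traces.

    The first ``glob.transient`` seconds are discarded.  ``noise`` optionally
    supplies explicit standard-normal increments of shape (n_steps, 2n)
    (columns: E streams then I streams); otherwise streams are derived
    deterministically from ``seed``.
    """
    connectome.validate()
    for g_name, g_arr in (("mu", tables.mu_grid), ("sigma", tables.sigma_grid)):
        if g_arr.size < 2:
            raise ValueError(f"{g_name} grid needs at least two points")
        d = np.diff(g_arr)
        if np.max(np.abs(d - d[0])) > 1e-9 * max(abs(d[0]), 1.0):
            raise ValueError(f"simulate requires a uniformly spaced {g_name} grid")
    n = connectome.n
    dt = glob.dt
    n_steps = int(round(glob.duration * 1000.0 / dt))
    transient_steps = int(round(glob.transient * 1000.0 / dt))
    decim = max(int(round(output_step_ms / dt)), 1)
    Dsteps = np.rint(connectome.D / dt).astype(np.int64)
    dE_steps = int(round(pop.d_E / dt))
    dI_steps = int(round(pop.d_I / dt))
    L = int(max(Dsteps.max() if n > 1 else 0, dE_steps, dI_steps)) + 2

    # CSR adjacency over nonzero couplings
    mask = connectome.C > 0
    counts = mask.sum(axis=1)
    cptr = np.zeros(n + 1, dtype=np.int64)
    cptr[1:] = np.cumsum(counts)
    cidx = np.nonzero(mask)[1].astype(np.int64)
    cw = connectome.C[mask].astype(float)
    cw2 = cw ** 2
    dsteps_flat = Dsteps[mask]

    T_out = (n_steps - transient_steps) // decim
    out_rE = np.zeros((n, T_out))
    if noise is not None:
        noise = np.ascontiguousarray(noise, dtype=float)
        if noise.shape != (n_steps, 2 * n):
            raise ValueError(f"noise must have shape {(n_steps, 2 * n)}")
        use_noise = 1
    else:
        noise = np.zeros((1, 2 * n))
        use_noise = 0

    status, bad_node, clamps = _network_kernel(
        n, n_steps, dt, cptr, cidx, cw, cw2, dsteps_flat,
        dE_steps, dI_steps, L,
        tables.mu_grid, tables.sigma_grid, tables.r_table, tables.V_table,
        tables.tau_table,
        pop.J_EE, pop.J_IE, pop.J_EI, pop.J_II,
        pop.c_EE / abs(pop.J_EE), pop.c_EI / abs(pop.J_EI),
        pop.c_IE / abs(pop.J_IE), pop.c_II / abs(pop.J_II),
        pop.tau_s_E, pop.tau_s_I, float(pop.K_E), float(pop.K_I),
        pop.sigma_ext, pop.mu_E_ext, pop.mu_I_ext,
        pop.alpha, pop.beta, pop.tau_A, pop.E_A,
        tables.neuron.C, tables.neuron.tau_m,
        glob.K_gl, glob.sigma_ou, glob.tau_ou,
        int(seed) % (2**31 - 1), use_noise, noise,
        transient_steps, decim, r_init, out_rE)
    if status < 0:
        t_fail = -status
        raise FloatingPointError(
            f"non-finite state at t={t_fail * dt:.1f} ms in node {bad_node}")

    t_ms = (transient_steps + decim * (1 + np.arange(T_out))) * dt
    return SimulationOutput(
        rate_E=out_rE, t_ms=t_ms, output_step_ms=decim * dt, seed=int(seed),
        params={"population": asdict(pop), "global": asdict(glob),
                "n_regions": n, "output_decimation": decim},
        n_clamp_events=int(clamps))
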