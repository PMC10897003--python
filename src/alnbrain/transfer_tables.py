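"""Precomputed transfer functions of an exponential integrate-and-fire population.

The mean-field (ALN) description of a population of EIF/AdEx neurons driven by
white noise with mean ``mu`` (mV/ms) and amplitude ``sigma`` (mV/sqrt(ms))
needs three stationary maps:

* ``Phi_r(mu, sigma)``   -- stationary population rate (kHz),
* ``Phi_V(mu, sigma)``   -- mean membrane voltage (mV), refractory mass at reset,
* ``Phi_tau(mu, sigma)`` -- effective timescale (ms) of the linear rate
  response, obtained from a low-frequency exponential-filter fit.

The rate and voltage follow from threshold integration of the stationary
Fokker-Planck equation with an absorbing boundary at the spike voltage,
re-injection at the reset and an explicit refractory period.  The timescale is
fitted to the Fokker-Planck linear rate response evaluated at a handful of low
frequencies.  Surfaces are tabulated on a (mu, sigma) grid and queried by
bilinear interpolation with clamping at the grid edges.

Unit convention: currents are expressed per capacitance (mV/ms), rates in kHz,
time in ms.  Conversion to Hz happens only at reporting boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

__all__ = [
    "NeuronParams",
    "SolverSettings",
    "TransferTables",
    "build_transfer_tables",
    "lookup",
    "save_tables",
    "load_tables",
]


@dataclass(frozen=True)
class NeuronParams:
    """AdEx/EIF single-neuron parameters (capacitance-normalized units)."""

    C: float = 200.0        # membrane capacitance (pF)
    g_L: float = 10.0       # leak conductance (nS)
    E_L: float = -65.0      # leak reversal (mV)
    Delta_T: float = 1.5    # threshold slope factor (mV)
    V_T: float = -50.0      # threshold voltage (mV)
    V_s: float = -40.0      # spike voltage threshold (mV)
    V_reset: float = -70.0  # reset voltage (mV)
    T_ref: float = 1.5      # refractory time (ms)

    def __post_init__(self):
        if self.C <= 0 or self.g_L <= 0:
            raise ValueError("C and g_L must be positive")
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be positive")
        if self.V_s <= self.V_T:
            raise ValueError("spike threshold V_s must exceed V_T")
        if self.T_ref < 0:
            raise ValueError("T_ref must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L (ms)."""
        return self.C / self.g_L


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings of the Fokker-Planck threshold integration."""

    V_lb: float = -200.0          # lower voltage bound (mV)
    dV: float = 0.05              # voltage step (mV)
    fit_freqs_khz: tuple = (0.002, 0.005, 0.01, 0.025, 0.06)
    tau_min: float = 1.0          # clamp for Phi_tau (ms); keeps Euler stable
    tau_max: float = 100.0
    rate_floor: float = 1e-5      # below this rate (kHz) tau falls back to tau_m
    # declared interpolation tolerance for refined-grid cross-checks
    interp_rtol: float = 0.05
    interp_atol_rate: float = 1e-4


@dataclass
class TransferTables:
    """Gridded Phi_r / Phi_V / Phi_tau surfaces over (mu, sigma)."""

    mu_grid: np.ndarray
    sigma_grid: np.ndarray
    r_table: np.ndarray      # (n_mu, n_sigma), kHz
    V_table: np.ndarray      # mV
    tau_table: np.ndarray    # ms
    flags: np.ndarray        # int8, nonzero marks a diagnostically flagged point
    neuron: NeuronParams = field(default_factory=NeuronParams)
    solver: SolverSettings = field(default_factory=SolverSettings)

    def validate(self) -> None:
        if not (np.all(np.diff(self.mu_grid) > 0) and np.all(np.diff(self.sigma_grid) > 0)):
            raise ValueError("grids must be strictly ascending")
        for name, tab in (("r", self.r_table), ("V", self.V_table), ("tau", self.tau_table)):
            if not np.all(np.isfinite(tab)):
                raise ValueError(f"{name}_table contains non-finite values")
        if np.any(self.r_table < 0):
            raise ValueError("negative rates in r_table")
        if np.any(self.tau_table <= 0):
            raise ValueError("non-positive timescales in tau_table")


@njit(cache=False)
def _drift(V, E_L, Delta_T, V_T, tau_m):
    return (E_L - V + Delta_T * np.exp((V - V_T) / Delta_T)) / tau_m


@njit(cache=False)
def _stationary_point(mu, sigma, Vgrid, dV, ir, E_L, Delta_T, V_T, tau_m,
                      T_ref, V_reset, qprof):
    """Threshold integration of the stationary EIF Fokker-Planck equation.

    Marches the unit-flux scaled density q = p/r downward from the spike
    threshold, with flux 1 above the reset and 0 below.  Returns
    (rate, mean_voltage, overflowed) and fills ``qprof`` with the q profile
    (valid only when overflowed == 0).
    """
    D = 0.5 * sigma * sigma
    nV = Vgrid.shape[0]
    q = 0.0
    qprof[nV - 1] = 0.0
    I0 = 0.0
    I1 = 0.0
    ls = 0.0  # accumulated log-scale from renormalization
    for k in range(nV - 1, 0, -1):
        A = _drift(Vgrid[k], E_L, Delta_T, V_T, tau_m) + mu
        jk = 1.0 if (k - 1) >= ir else 0.0
        c = -A * dV / D
        if c > 690.0:
            c = 690.0
        Efac = np.exp(c)
        if np.abs(c) > 1e-12:
            w = -np.expm1(c) / A
        else:
            w = dV / D
        qn = q * Efac + jk * w
        if qn < 0.0:
            qn = 0.0
        I0 += 0.5 * (q + qn) * dV
        I1 += 0.5 * (q * Vgrid[k] + qn * Vgrid[k - 1]) * dV
        q = qn
        if q > 1e100:
            q *= 1e-100
            I0 *= 1e-100
            I1 *= 1e-100
            ls += 100.0 * np.log(10.0)
        qprof[k - 1] = q
    scale = np.exp(-ls)  # underflows to exactly 0 for deep subthreshold points
    denom = I0 + T_ref * scale
    if denom <= 0.0:
        return 0.0, V_reset, 1
    r = scale / denom
    Vbar = (I1 + T_ref * V_reset * scale) / denom
    overflowed = 1 if ls > 0.0 else 0
    return r, Vbar, overflowed


@njit(cache=False)
def _linear_response(mu, sigma, omega, Vgrid, dV, ir, E_L, Delta_T, V_T,
                     tau_m, T_ref, p0):
    """Rate response r1/mu1 at angular frequency omega (1/ms).

    Solves the linearized Fokker-Planck system by marching a forced and a
    homogeneous (unit-rate, delayed re-injection) solution downward and
    imposing zero total flux at the lower boundary.
    """
    D = 0.5 * sigma * sigma
    nV = Vgrid.shape[0]
    pf = 0.0 + 0.0j
    jf = 0.0 + 0.0j
    ph = 0.0 + 0.0j
    jh = 1.0 + 0.0j
    reinj = np.exp(-1j * omega * T_ref)
    for k in range(nV - 1, 0, -1):
        A = _drift(Vgrid[k], E_L, Delta_T, V_T, tau_m) + mu
        c = -A * dV / D
        if c > 690.0:
            c = 690.0
        Efac = np.exp(c)
        if np.abs(c) > 1e-12:
            w = -np.expm1(c) / A
        else:
            w = dV / D
        # dj/dV = -i omega p  =>  j(V - dV) = j(V) + i omega p dV
        jf_n = jf + 1j * omega * pf * dV
        jh_n = jh + 1j * omega * ph * dV
        pf = pf * Efac + (jf - p0[k]) * w
        ph = ph * Efac + jh * w
        jf = jf_n
        jh = jh_n
        if (k - 1) == ir:
            jh = jh - reinj
    if np.abs(jh) == 0.0:
        return 0.0 + 0.0j
    return -jf / jh


@njit(cache=False)
def _build_kernel(mu_grid, sigma_grid, Vgrid, dV, ir, E_L, Delta_T, V_T,
                  tau_m, T_ref, V_reset, freqs, rate_floor, tau_min, tau_max):
    n_mu = mu_grid.shape[0]
    n_sig = sigma_grid.shape[0]
    nf = freqs.shape[0]
    r_tab = np.zeros((n_mu, n_sig))
    V_tab = np.zeros((n_mu, n_sig))
    tau_tab = np.zeros((n_mu, n_sig))
    flags = np.zeros((n_mu, n_sig), dtype=np.int8)
    qprof = np.zeros(Vgrid.shape[0])
    p0 = np.zeros(Vgrid.shape[0])
    Rmag = np.zeros(nf)
    for j in range(n_sig):
        sig = sigma_grid[j]
        for i in range(n_mu):
            mu = mu_grid[i]
            r, Vbar, ovf = _stationary_point(
                mu, sig, Vgrid, dV, ir, E_L, Delta_T, V_T, tau_m,
                T_ref, V_reset, qprof)
            if not (np.isfinite(r) and np.isfinite(Vbar)):
                flags[i, j] = 1
                r, Vbar = 0.0, V_reset
            r_tab[i, j] = r
            V_tab[i, j] = Vbar
            if ovf == 1 or r < rate_floor:
                tau_tab[i, j] = tau_m
                continue
            # zero-frequency response from a small finite difference in mu
            dmu = 1e-3
            r_hi, _, o1 = _stationary_point(mu + dmu, sig, Vgrid, dV, ir, E_L,
                                            Delta_T, V_T, tau_m, T_ref,
                                            V_reset, p0)
            r_lo, _, o2 = _stationary_point(mu - dmu, sig, Vgrid, dV, ir, E_L,
                                            Delta_T, V_T, tau_m, T_ref,
                                            V_reset, p0)
            R0 = (r_hi - r_lo) / (2.0 * dmu)
            if R0 <= 0.0 or o1 == 1 or o2 == 1:
                tau_tab[i, j] = tau_m
                continue
            for k in range(Vgrid.shape[0]):
                p0[k] = r * qprof[k]
            num = 0.0
            den = 0.0
            for f in range(nf):
                om = 2.0 * np.pi * freqs[f]
                R = _linear_response(mu, sig, om, Vgrid, dV, ir, E_L, Delta_T,
                                     V_T, tau_m, T_ref, p0)
                Rmag[f] = np.abs(R)
                if Rmag[f] > 0.0:
                    y = (R0 / Rmag[f]) ** 2 - 1.0
                    if y < 0.0:
                        y = 0.0
                    num += y * om * om
                    den += om ** 4
            tau = np.sqrt(num / den) if den > 0.0 else tau_m
            if tau < tau_min:
                tau = tau_min
            if tau > tau_max:
                tau = tau_max
            tau_tab[i, j] = tau
    return r_tab, V_tab, tau_tab, flags


def build_transfer_tables(neuron: NeuronParams | None = None,
                          mu_grid=None, sigma_grid=None,
                          solver: SolverSettings | None = None) -> TransferTables:
    """Build Phi_r, Phi_V, Phi_tau surfaces on a (mu, sigma) grid.

    Default grid: mu in [-4, 6] mV/ms step 0.05, sigma in [0.1, 5] mV/sqrt(ms)
    step 0.1, bracketing the operating points reachable with the default
    population parameters under all perturbation families (including the
    adaptation-shifted down-state currents).
    """
    neuron = neuron or NeuronParams()
    solver = solver or SolverSettings()
    if mu_grid is None:
        mu_grid = np.arange(-4.0, 6.0 + 1e-9, 0.05)
    if sigma_grid is None:
        sigma_grid = np.arange(0.1, 5.0 + 1e-9, 0.1)
    mu_grid = np.ascontiguousarray(np.asarray(mu_grid, dtype=float))
    sigma_grid = np.ascontiguousarray(np.asarray(sigma_grid, dtype=float))
    if mu_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if not (np.all(np.diff(mu_grid) > 0) and np.all(np.diff(sigma_grid) > 0)):
        raise ValueError("grids must be strictly ascending")
    if np.any(sigma_grid <= 0):
        raise ValueError("sigma values must be positive")

    nV = int(round((neuron.V_s - solver.V_lb) / solver.dV)) + 1
    Vgrid = np.linspace(solver.V_lb, neuron.V_s, nV)
    dV = Vgrid[1] - Vgrid[0]
    ir = int(np.argmin(np.abs(Vgrid - neuron.V_reset)))
    freqs = np.asarray(solver.fit_freqs_khz, dtype=float)

    r_tab, V_tab, tau_tab, flags = _build_kernel(
        mu_grid, sigma_grid, Vgrid, dV, ir, neuron.E_L, neuron.Delta_T,
        neuron.V_T, neuron.tau_m, neuron.T_ref, neuron.V_reset, freqs,
        solver.rate_floor, solver.tau_min, min(solver.tau_max, 5 * neuron.tau_m))

    if np.any(flags):
        bad = np.argwhere(flags != 0)
        raise FloatingPointError(
            "Fokker-Planck integration failed to converge at grid points "
            f"(mu, sigma) = {[(float(mu_grid[i]), float(sigma_grid[j])) for i, j in bad[:5]]}"
            f" ({bad.shape[0]} points total)")

    tables = TransferTables(mu_grid=mu_grid, sigma_grid=sigma_grid,
                            r_table=r_tab, V_table=V_tab, tau_table=tau_tab,
                            flags=flags, neuron=neuron, solver=solver)
    tables.validate()
    return tables


@njit(cache=False)
def _bilinear(grid_x, grid_y, table, x, y):
    """Bilinear interpolation with clamping to the grid boundary."""
    nx = grid_x.shape[0]
    ny = grid_y.shape[0]
    if x <= grid_x[0]:
        ix, fx = 0, 0.0
    elif x >= grid_x[nx - 1]:
        ix, fx = nx - 2, 1.0
    else:
        ix = np.searchsorted(grid_x, x) - 1
        fx = (x - grid_x[ix]) / (grid_x[ix + 1] - grid_x[ix])
    if y <= grid_y[0]:
        iy, fy = 0, 0.0
    elif y >= grid_y[ny - 1]:
        iy, fy = ny - 2, 1.0
    else:
        iy = np.searchsorted(grid_y, y) - 1
        fy = (y - grid_y[iy]) / (grid_y[iy + 1] - grid_y[iy])
    if nx == 1:
        ix, fx = 0, 0.0
    if ny == 1:
        iy, fy = 0, 0.0
    i1 = min(ix + 1, nx - 1)
    j1 = min(iy + 1, ny - 1)
    v00 = table[ix, iy]
    v10 = table[i1, iy]
    v01 = table[ix, j1]
    v11 = table[i1, j1]
    return ((1 - fx) * (1 - fy) * v00 + fx * (1 - fy) * v10
            + (1 - fx) * fy * v01 + fx * fy * v11)


def lookup(tables: TransferTables, mu, sigma):
    """Query (rate, mean_voltage, timescale) at (mu, sigma), scalar or array.

    Values outside the grid clamp to the boundary.  Non-finite queries raise.
    """
    mu_a = np.atleast_1d(np.asarray(mu, dtype=float))
    sg_a = np.atleast_1d(np.asarray(sigma, dtype=float))
    if not np.all(np.isfinite(mu_a)):
        raise ValueError("non-finite query for state variable mu")
    if not np.all(np.isfinite(sg_a)):
        raise ValueError("non-finite query for state variable sigma")
    mu_a, sg_a = np.broadcast_arrays(mu_a, sg_a)
    r = np.empty(mu_a.shape)
    V = np.empty(mu_a.shape)
    tau = np.empty(mu_a.shape)
    it = np.nditer(mu_a, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        r[idx] = _bilinear(tables.mu_grid, tables.sigma_grid, tables.r_table,
                           mu_a[idx], sg_a[idx])
        V[idx] = _bilinear(tables.mu_grid, tables.sigma_grid, tables.V_table,
                           mu_a[idx], sg_a[idx])
        tau[idx] = _bilinear(tables.mu_grid, tables.sigma_grid, tables.tau_table,
                             mu_a[idx], sg_a[idx])
    if np.isscalar(mu) and np.isscalar(sigma):
        return float(r.ravel()[0]), float(V.ravel()[0]), float(tau.ravel()[0])
    return r, V, tau


def save_tables(tables: TransferTables, path) -> None:
    """Serialize a table archive (grids, surfaces, provenance) to one file."""
    prov = json.dumps({"neuron": asdict(tables.neuron),
                       "solver": asdict(tables.solver)}, sort_keys=True)
    np.savez(path, mu_grid=tables.mu_grid, sigma_grid=tables.sigma_grid,
             r_table=tables.r_table, V_table=tables.V_table,
             tau_table=tables.tau_table, flags=tables.flags,
             provenance=np.frombuffer(prov.encode(), dtype=np.uint8))


def load_tables(path) -> TransferTables:
    with np.load(path) as z:
        prov = json.loads(bytes(z["provenance"]).decode())
        solver_kwargs = dict(prov["solver"])
        solver_kwargs["fit_freqs_khz"] = tuple(solver_kwargs["fit_freqs_khz"])
        tables = TransferTables(
            mu_grid=z["mu_grid"], sigma_grid=z["sigma_grid"],
            r_table=z["r_table"], V_table=z["V_table"],
            tau_table=z["tau_table"], flags=z["flags"],
            neuron=NeuronParams(**prov["neuron"]),
            solver=SolverSettings(**solver_kwargs))
    tables.validate()
    return tables
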