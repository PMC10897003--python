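"""Monte-Carlo spiking-network reference simulations.

Two independent ground-truth simulators used to validate the mean-field code:

* :func:`eif_population_rate` -- an uncoupled population of EIF neurons driven
  by white-noise current with mean ``mu`` and amplitude ``sigma``; its
  stationary firing rate is the direct Monte-Carlo counterpart of the
  Fokker-Planck transfer function ``Phi_r``.
* :func:`simulate_adex_network` -- a sparse recurrent network of AdEx neurons
  (excitatory population with somatic adaptation plus inhibitory population,
  current-based exponential synapses with saturating per-spike activation and
  population-specific delays); its excitatory rate is the ground truth for a
  single ALN node.

Both use Euler-Maruyama at the model time step and are deterministic under a
seed.  They share no code with the Fokker-Planck or ALN integrators.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .transfer_tables import NeuronParams
from .network import PopulationParams

__all__ = ["eif_population_rate", "simulate_adex_network"]


@njit(cache=False)
def _eif_mc_kernel(n_neurons, n_steps, dt, mu, sigma, E_L, Delta_T, V_T,
                   tau_m, V_s, V_reset, ref_steps, discard_steps, seed):
    np.random.seed(seed)
    V = np.full(n_neurons, E_L)
    refrac = np.zeros(n_neurons, dtype=np.int64)
    sqdt = np.sqrt(dt)
    spikes = 0
    for t in range(n_steps):
        for i in range(n_neurons):
            if refrac[i] > 0:
                refrac[i] -= 1
                continue
            arg = (V[i] - V_T) / Delta_T
            if arg > 20.0:
                arg = 20.0
            dV = ((E_L - V[i] + Delta_T * np.exp(arg)) / tau_m + mu) * dt \
                + sigma * sqdt * np.random.normal()
            V[i] += dV
            if V[i] >= V_s:
                V[i] = V_reset
                refrac[i] = ref_steps
                if t >= discard_steps:
                    spikes += 1
    window_ms = (n_steps - discard_steps) * dt
    return spikes / (n_neurons * window_ms)  # kHz


def eif_population_rate(mu: float, sigma: float, neuron: NeuronParams,
                        n_neurons: int = 2000, duration_ms: float = 10000.0,
                        discard_ms: float = 1000.0, dt: float = 0.05,
                        seed: int = 0) -> float:
    """Stationary rate (kHz) of uncoupled white-noise-driven EIF neurons."""
    n_steps = int(round(duration_ms / dt))
    discard = int(round(discard_ms / dt))
    return float(_eif_mc_kernel(
        n_neurons, n_steps, dt, mu, sigma, neuron.E_L, neuron.Delta_T,
        neuron.V_T, neuron.tau_m, neuron.V_s, neuron.V_reset,
        int(round(neuron.T_ref / dt)), discard, int(seed) % (2**31 - 1)))


@njit(cache=False)
def _adex_net_kernel(n_E, n_I, dt, n_steps, discard_steps,
                     outE_idx, outE_ptr, outI_idx, outI_ptr,
                     E_L, Delta_T, V_T, tau_m, V_s, V_reset, ref_steps, Cap,
                     JEE, JIE, JEI, JII, cEE, cIE, cEI, cII, tsE, tsI,
                     dE_steps, dI_steps, sig_ext, mu_E_ext, mu_I_ext,
                     alpha, beta, tau_A, E_A, seed, rate_trace):
    np.random.seed(seed)
    N = n_E + n_I
    V = E_L + 5.0 * np.random.normal(0.0, 1.0, N)
    w = np.zeros(n_E)  # adaptation current (pA), excitatory neurons only
    sE = np.zeros(N)   # fraction of active excitatory synapses per neuron
    sI = np.zeros(N)
    refrac = np.zeros(N, dtype=np.int64)
    Ld = max(dE_steps, dI_steps) + 1
    spk_list = np.zeros((Ld, N), dtype=np.int64)
    spk_count = np.zeros(Ld, dtype=np.int64)
    # one presynaptic spike adds a PSC of amplitude c_ab, i.e. activates a
    # fraction c_ab/|J_ab| of the remaining inactive synapses
    aEE = cEE / abs(JEE)
    aEI = cEI / abs(JEI)
    aIE = cIE / abs(JIE)
    aII = cII / abs(JII)
    sqdt = np.sqrt(dt)
    spikes = 0
    for t in range(n_steps):
        # deliver spikes: to E targets after dE_steps, to I targets after dI_steps
        if t >= dE_steps:
            slot = (t - dE_steps) % Ld
            for k in range(spk_count[slot]):
                j = spk_list[slot, k]
                amp = aEE if j < n_E else aEI
                from_E = j < n_E
                for e in range(outE_ptr[j], outE_ptr[j + 1]):
                    i = outE_idx[e]
                    if from_E:
                        sE[i] += amp * (1.0 - sE[i])
                    else:
                        sI[i] += amp * (1.0 - sI[i])
        if t >= dI_steps:
            slot = (t - dI_steps) % Ld
            for k in range(spk_count[slot]):
                j = spk_list[slot, k]
                amp = aIE if j < n_E else aII
                from_E = j < n_E
                for e in range(outI_ptr[j], outI_ptr[j + 1]):
                    i = outI_idx[e]
                    if from_E:
                        sE[i] += amp * (1.0 - sE[i])
                    else:
                        sI[i] += amp * (1.0 - sI[i])
        slot_now = t % Ld
        spk_count[slot_now] = 0
        for i in range(N):
            exc = i < n_E
            sE[i] -= dt * sE[i] / tsE
            sI[i] -= dt * sI[i] / tsI
            if refrac[i] > 0:
                refrac[i] -= 1
                if exc:
                    w[i] -= dt * w[i] / tau_A
                continue
            if exc:
                mu_syn = JEE * sE[i] + JEI * sI[i]
                mu_ext = mu_E_ext
                Iw = w[i] / Cap
            else:
                mu_syn = JIE * sE[i] + JII * sI[i]
                mu_ext = mu_I_ext
                Iw = 0.0
            arg = (V[i] - V_T) / Delta_T
            if arg > 20.0:
                arg = 20.0
            dV = ((E_L - V[i] + Delta_T * np.exp(arg)) / tau_m
                  + mu_syn + mu_ext - Iw) * dt + sig_ext * sqdt * np.random.normal()
            V[i] += dV
            if exc:
                w[i] += dt * (alpha * (V[i] - E_A) - w[i]) / tau_A
            if V[i] >= V_s:
                V[i] = V_reset
                refrac[i] = ref_steps
                spk_list[slot_now, spk_count[slot_now]] = i
                spk_count[slot_now] += 1
                if exc:
                    w[i] += beta
                    rate_trace[t] += 1.0
                    if t >= discard_steps:
                        spikes += 1
    window_ms = (n_steps - discard_steps) * dt
    return spikes / (n_E * window_ms)  # kHz


def _out_csr(src: np.ndarray, tgt: np.ndarray, n_sources: int):
    """Out-adjacency in CSR form (targets grouped by source neuron)."""
    order = np.argsort(src, kind="stable")
    idx = tgt[order].astype(np.int64)
    ptr = np.zeros(n_sources + 1, dtype=np.int64)
    counts = np.bincount(src, minlength=n_sources)
    ptr[1:] = np.cumsum(counts)
    return idx, ptr


def simulate_adex_network(pop: PopulationParams, neuron: NeuronParams,
                          n_E: int = 8000, n_I: int = 2000,
                          duration_ms: float = 20000.0,
                          discard_ms: float = 2000.0,
                          dt: float = 0.1, seed: int = 0,
                          mu_E_ext: float | None = None):
    """Simulate a sparse recurrent AdEx network matching one ALN node.

    Each neuron receives ``K_E`` excitatory and ``K_I`` inhibitory inputs
    drawn uniformly at random.  Returns (mean excitatory rate in kHz over the
    post-discard window, per-step excitatory population rate trace in kHz).
    """
    rng = np.random.default_rng(seed)
    N = n_E + n_I
    K_E = int(pop.K_E)
    K_I = int(pop.K_I)
    src = np.concatenate([rng.integers(0, n_E, size=N * K_E),
                          n_E + rng.integers(0, n_I, size=N * K_I)])
    tgt = np.concatenate([np.repeat(np.arange(N), K_E),
                          np.repeat(np.arange(N), K_I)])
    in_E = tgt < n_E
    outE_idx, outE_ptr = _out_csr(src[in_E], tgt[in_E], N)
    outI_idx, outI_ptr = _out_csr(src[~in_E], tgt[~in_E], N)
    n_steps = int(round(duration_ms / dt))
    discard = int(round(discard_ms / dt))
    rate_trace = np.zeros(n_steps)
    rate = _adex_net_kernel(
        n_E, n_I, dt, n_steps, discard,
        outE_idx, outE_ptr, outI_idx, outI_ptr,
        neuron.E_L, neuron.Delta_T, neuron.V_T, neuron.tau_m, neuron.V_s,
        neuron.V_reset, int(round(neuron.T_ref / dt)), neuron.C,
        pop.J_EE, pop.J_IE, pop.J_EI, pop.J_II,
        pop.c_EE, pop.c_IE, pop.c_EI, pop.c_II,
        pop.tau_s_E, pop.tau_s_I,
        int(round(pop.d_E / dt)), int(round(pop.d_I / dt)),
        pop.sigma_ext, pop.mu_E_ext if mu_E_ext is None else mu_E_ext,
        pop.mu_I_ext, pop.alpha, pop.beta, pop.tau_A, pop.E_A,
        int(seed) % (2**31 - 1), rate_trace)
    rate_trace /= (n_E * dt)
    return float(rate), rate_trace
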