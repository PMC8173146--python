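"""Leaky integrate-and-fire E/I network with emergent inhibition-paced oscillations.

The circuit is two all-to-all coupled subpopulations of N = 10 cells each:
excitatory cells with fast (AMPA-like, tau_e = 5 ms) synapses and inhibitory
cells with slow (GABA_B-like, tau_i = 75 ms) synapses. Each cell obeys

    tau_v dv/dt = v_m - v + w_ji * s_i * (v_i - v) + w_je * s_e * (v_e - v)
                  + I_j + gamma(t)

with threshold/reset spiking, tonic drive I_j combining bottom-up (s) and
top-down memory (m) inputs, and extrinsic noise gamma made of white and
slow Ornstein-Uhlenbeck components. Population synaptic activity follows a
two-stage linear filter driven by the subpopulation spike train; an LFP
proxy is read out as a reversal-potential-weighted sum of the two synaptic
variables.

Integration is first-order explicit Euler-Maruyama with dt = 1000/2**15 ms,
so 1-s analysis segments hold exactly 2**15 samples. The production path is
a numba kernel; the single-step functions below define the identical update
rule and are used directly by the unit tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import DriveParams, NetworkParams, NoiseParams

__all__ = [
    "SimulationTrace",
    "input_current",
    "input_currents",
    "synapse_step",
    "ou_step",
    "step_network",
    "simulate_network",
    "lfp_proxy",
    "LFP_REFERENCE_POTENTIAL",
]

#: Near-rest potential used to weight synaptic currents in the LFP proxy (mV).
LFP_REFERENCE_POTENTIAL = -55.0


@dataclass
class SimulationTrace:
    """Output of one network run at fixed dt.

    spike_times holds one strictly increasing array of spike times (ms) per
    cell; cells 0..N-1 are excitatory, N..2N-1 inhibitory.
    """

    spike_times: list[np.ndarray]
    s_e_series: np.ndarray
    s_i_series: np.ndarray
    lfp: np.ndarray
    dt: float
    duration: float
    seed: int
    populations: np.ndarray = field(default=None)  # 'e'/'i' label per cell
    v_series: np.ndarray | None = None             # optional (2N, n_steps)

    def __post_init__(self) -> None:
        if self.populations is None:
            n = len(self.spike_times) // 2
            self.populations = np.array(["e"] * n + ["i"] * n)

    @property
    def n_cells(self) -> int:
        return len(self.spike_times)

    @property
    def n_steps(self) -> int:
        return self.lfp.shape[0]

    def rates(self, t_start: float = 0.0) -> np.ndarray:
        """Mean firing rate (Hz) per cell over [t_start, duration)."""
        window_s = (self.duration - t_start) / 1000.0
        return np.array(
            [np.count_nonzero(st >= t_start) / window_s for st in self.spike_times]
        )

    def population_rate(self, population: str, t_start: float = 0.0) -> float:
        """Mean rate (Hz) across cells of one subpopulation ('e' or 'i')."""
        mask = self.populations == population
        return float(self.rates(t_start)[mask].mean())


# ---------------------------------------------------------------------------
# Single-step update rules (reference semantics; mirrored by the numba kernel)
# ---------------------------------------------------------------------------

def input_current(
    subpop: str, n: int, s: float, m_flag: int, drive: DriveParams
) -> float:
    """Tonic input I_j = alpha_j*s + beta_j*m + I_base_j + dI_base*(n-1), mV.

    ``n`` is the 1-based cell index within the subpopulation.
    """
    if subpop not in ("e", "i"):
        raise ValueError("subpop must be 'e' or 'i'")
    if n < 1:
        raise ValueError("cell index n is 1-based")
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    if m_flag not in (0, 1):
        raise ValueError("m_flag must be 0 or 1")
    if subpop == "e":
        alpha, beta, base = drive.alpha_e, drive.beta_e, drive.I_base_e
    else:
        alpha, beta, base = drive.alpha_i, drive.beta_i, drive.I_base_i
    return alpha * s + beta * m_flag + base + drive.dI_base * (n - 1)


def input_currents(params: NetworkParams, drive: DriveParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectors of tonic currents for the e and i subpopulations."""
    n = np.arange(1, params.N + 1)
    I_e = drive.alpha_e * drive.s + drive.beta_e * drive.m_flag \
        + drive.I_base_e + drive.dI_base * (n - 1)
    I_i = drive.alpha_i * drive.s + drive.beta_i * drive.m_flag \
        + drive.I_base_i + drive.dI_base * (n - 1)
    return I_e, I_i


def _synapse_jump(N: int, tau_j: float, area_normalized: bool) -> float:
    # Per-spike increment of eta. Default: 1/N (per-spike area tau_j/N),
    # the convention that produces the published oscillatory regime;
    # area_normalized gives the area-1/N filter (increment 1/(N*tau_j)).
    return 1.0 / (N * tau_j) if area_normalized else 1.0 / N


def synapse_step(
    eta: float,
    s_j: float,
    spike_impulse: float,
    tau_j: float,
    dt: float,
    area_normalized: bool = False,
) -> tuple[float, float]:
    """One explicit-Euler step of the two-stage synaptic filter.

    ``spike_impulse`` is (number of subpopulation spikes this step) / N.
    Impulse response of s_j is the alpha function peaking at t = tau_j.
    """
    if tau_j <= 0:
        raise ValueError("tau_j must be positive")
    if spike_impulse < 0:
        raise ValueError("spike_impulse must be non-negative")
    jump = spike_impulse / tau_j if area_normalized else spike_impulse
    s_new = s_j + (dt / tau_j) * (-s_j + eta)
    eta_new = eta + (dt / tau_j) * (-eta) + jump
    return eta_new, s_new


def ou_step(zeta: float, noise: NoiseParams, dt: float, rng: np.random.Generator) -> float:
    """Euler-Maruyama step of the slow OU noise current (stationary
    variance sigma_c**2 * tau_c / 2)."""
    return zeta + (-zeta / noise.tau_c) * dt + noise.sigma_c * math.sqrt(dt) * rng.standard_normal()


def step_network(
    state: dict,
    params: NetworkParams,
    drive: DriveParams,
    noise: NoiseParams,
    rng: np.random.Generator,
) -> tuple[dict, np.ndarray]:
    """Advance the full network one Euler-Maruyama step (reference path).

    ``state`` holds v (2N,), eta_e, s_e, eta_i, s_i (scalars) and zeta (2N,).
    Returns the new state and a boolean spike mask over cells. Cells
    0..N-1 are excitatory. Slow but transparent; the numba kernel used by
    :func:`simulate_network` applies the identical update order.
    """
    N, dt = params.N, params.dt
    v = np.asarray(state["v"], dtype=float)
    zeta = np.asarray(state["zeta"], dtype=float)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(zeta))):
        raise FloatingPointError("non-finite network state")
    I_e, I_i = input_currents(params, drive)
    I = np.concatenate([I_e, I_i])
    # weight subscripts are (post, pre): e-cells receive w_ei*s_i and w_ee*s_e
    w_i = np.where(np.arange(2 * N) < N, params.w_ei, params.w_ii)
    w_e = np.where(np.arange(2 * N) < N, params.w_ee, params.w_ie)

    dv = (dt / params.tau_v) * (
        params.v_m - v
        + w_i * state["s_i"] * (params.v_i - v)
        + w_e * state["s_e"] * (params.v_e - v)
        + I
        + zeta
    )
    xi = rng.standard_normal(2 * N)
    v_new = v + dv + (noise.sigma_w / params.tau_v) * math.sqrt(dt) * xi
    xi2 = rng.standard_normal(2 * N)
    zeta_new = zeta + (-zeta / noise.tau_c) * dt + noise.sigma_c * math.sqrt(dt) * xi2

    spiked = v_new >= params.v_T
    v_new = np.where(spiked, params.v_R, v_new)

    imp_e = spiked[:N].sum() / N
    imp_i = spiked[N:].sum() / N
    eta_e, s_e = synapse_step(
        state["eta_e"], state["s_e"], imp_e, params.tau_e, dt,
        params.synapse_area_normalized,
    )
    eta_i, s_i = synapse_step(
        state["eta_i"], state["s_i"], imp_i, params.tau_i, dt,
        params.synapse_area_normalized,
    )
    new_state = dict(v=v_new, zeta=zeta_new, eta_e=eta_e, s_e=s_e, eta_i=eta_i, s_i=s_i)
    return new_state, spiked


# ---------------------------------------------------------------------------
# Production kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lif_kernel(
    n_steps, dt, N,
    v_T, v_R, v_m, v_e, v_i, tau_v, tau_e, tau_i,
    w_ee, w_ii, w_ie, w_ei,
    I, sigma_w, sigma_c, tau_c,
    jump_e, jump_i,
    v0, noise_seed, record_v,
):  # pragma: no cover - exercised via simulate_network
    np.random.seed(noise_seed)
    n_cells = 2 * N
    v = v0.copy()
    zeta = np.zeros(n_cells)
    eta_e = 0.0
    s_e = 0.0
    eta_i = 0.0
    s_i = 0.0

    s_e_series = np.empty(n_steps)
    s_i_series = np.empty(n_steps)
    v_series = np.empty((n_cells, n_steps if record_v else 0))

    cap = max(int(20.0 * n_steps * dt), 1024)  # ~1 kHz/cell aggregate bound
    spike_steps = np.empty(cap, dtype=np.int64)
    spike_cells = np.empty(cap, dtype=np.int32)
    n_spikes = 0

    sqrt_dt = math.sqrt(dt)
    wn = sigma_w / tau_v * sqrt_dt
    ou = sigma_c * sqrt_dt

    for t in range(n_steps):
        count_e = 0
        count_i = 0
        for c in range(n_cells):
            if c < N:
                w_in_i = w_ei   # inhibition onto e-cells (post, pre)
                w_in_e = w_ee
            else:
                w_in_i = w_ii
                w_in_e = w_ie   # excitation onto i-cells
            vc = v[c]
            dv = (dt / tau_v) * (
                v_m - vc
                + w_in_i * s_i * (v_i - vc)
                + w_in_e * s_e * (v_e - vc)
                + I[c]
                + zeta[c]
            )
            vn = vc + dv + wn * np.random.standard_normal()
            zeta[c] = zeta[c] + (-zeta[c] / tau_c) * dt + ou * np.random.standard_normal()
            if vn >= v_T:
                vn = v_R
                if n_spikes >= cap:
                    return (spike_steps, spike_cells, -1,
                            s_e_series, s_i_series, v_series)
                spike_steps[n_spikes] = t
                spike_cells[n_spikes] = c
                n_spikes += 1
                if c < N:
                    count_e += 1
                else:
                    count_i += 1
            v[c] = vn

        # two-stage synaptic filters (population level, old-value Euler)
        s_e = s_e + (dt / tau_e) * (-s_e + eta_e)
        eta_e = eta_e + (dt / tau_e) * (-eta_e) + jump_e * count_e
        s_i = s_i + (dt / tau_i) * (-s_i + eta_i)
        eta_i = eta_i + (dt / tau_i) * (-eta_i) + jump_i * count_i

        s_e_series[t] = s_e
        s_i_series[t] = s_i
        if record_v:
            for c in range(n_cells):
                v_series[c, t] = v[c]
        if (t & 32767) == 0 and not math.isfinite(v[0] + s_e + s_i):
            return (spike_steps, spike_cells, -2,
                    s_e_series, s_i_series, v_series)

    return spike_steps, spike_cells, n_spikes, s_e_series, s_i_series, v_series


def lfp_proxy(
    s_e_series: np.ndarray, s_i_series: np.ndarray, params: NetworkParams
) -> np.ndarray:
    """LFP proxy: reversal-weighted linear combination of synaptic activity.

    LFP(t) = (w_ee + w_ei)(vref - v_e) s_e(t) + c_i (vref - v_i) s_i(t)
    with vref = -55 mV; c_i is (w_ee + w_ei) by default (the published
    form) or (w_ie + w_ii) when ``params.lfp_inhibitory_corrected``.
    The inhibitory term dominates, so the proxy is positive-valued.
    """
    s_e_series = np.asarray(s_e_series, dtype=float)
    s_i_series = np.asarray(s_i_series, dtype=float)
    if s_e_series.shape != s_i_series.shape:
        raise ValueError("s_e and s_i series must have equal length")
    c_e = (params.w_ee + params.w_ei) * (LFP_REFERENCE_POTENTIAL - params.v_e)
    w_inh = (params.w_ie + params.w_ii) if params.lfp_inhibitory_corrected \
        else (params.w_ee + params.w_ei)
    c_i = w_inh * (LFP_REFERENCE_POTENTIAL - params.v_i)
    return c_e * s_e_series + c_i * s_i_series


def simulate_network(
    params: NetworkParams,
    drive: DriveParams,
    noise: NoiseParams,
    duration: float,
    seed: int,
    record_v: bool = False,
    v0: np.ndarray | None = None,
) -> SimulationTrace:
    """Run the network for ``duration`` ms and return spikes, synaptic series
    and the LFP proxy. Bit-reproducible for a given seed.

    Initial voltages are drawn uniformly in [v_R, v_T) to desynchronize the
    start (or taken from ``v0`` when given); analyses should discard an
    initial transient (~2 s) before computing stationary statistics.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_steps = int(round(duration / params.dt))
    ss = np.random.SeedSequence(seed)
    init_seed, noise_seed = ss.spawn(2)
    if v0 is None:
        rng = np.random.default_rng(init_seed)
        v0 = params.v_R + (params.v_T - params.v_R) * rng.random(2 * params.N)
    else:
        v0 = np.asarray(v0, dtype=float).copy()
        if v0.shape != (2 * params.N,):
            raise ValueError("v0 must have one entry per cell")
    noise_seed_int = int(noise_seed.generate_state(1)[0] % (2 ** 31))

    I_e, I_i = input_currents(params, drive)
    I = np.concatenate([I_e, I_i])
    jump_e = _synapse_jump(params.N, params.tau_e, params.synapse_area_normalized)
    jump_i = _synapse_jump(params.N, params.tau_i, params.synapse_area_normalized)

    spike_steps, spike_cells, n_spikes, s_e_series, s_i_series, v_series = _lif_kernel(
        n_steps, params.dt, params.N,
        params.v_T, params.v_R, params.v_m, params.v_e, params.v_i,
        params.tau_v, params.tau_e, params.tau_i,
        params.w_ee, params.w_ii, params.w_ie, params.w_ei,
        I, noise.sigma_w, noise.sigma_c, noise.tau_c,
        jump_e, jump_i,
        v0, noise_seed_int, record_v,
    )
    if n_spikes == -1:
        raise RuntimeError("spike budget exceeded: network is pathologically active")
    if n_spikes == -2:
        raise FloatingPointError("non-finite network state encountered")

    spike_steps = spike_steps[:n_spikes]
    spike_cells = spike_cells[:n_spikes]
    spike_times = []
    for c in range(2 * params.N):
        steps_c = spike_steps[spike_cells == c]
        spike_times.append((steps_c + 1) * params.dt)

    lfp = lfp_proxy(s_e_series, s_i_series, params)
    return SimulationTrace(
        spike_times=spike_times,
        s_e_series=s_e_series,
        s_i_series=s_i_series,
        lfp=lfp,
        dt=params.dt,
        duration=n_steps * params.dt,
        seed=seed,
        v_series=v_series if record_v else None,
    )
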