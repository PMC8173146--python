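"""Unit tests of the LIF network: single-step rules, closed-form oracles,
kernel/reference equivalence and reproducibility."""

import math
from dataclasses import replace

import numpy as np
import pytest

import wmosc
from wmosc.network import _synapse_jump


# ---------------------------------------------------------------------------
# input currents
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "subpop,n,s,m,expected",
    [
        ("e", 1, 0.0, 0, 0.42),            # published offset, first e-cell
        ("i", 1, 1.0, 1, 0.38 + 0.73 + 0.28),
        ("e", 10, 0.0, 0, 0.42 + 9 * 0.0089),
    ],
)
def test_input_current_published_values(subpop, n, s, m, expected):
    drive = wmosc.DriveParams(I_base_e=0.42, beta_e=0.625)  # published table
    assert wmosc.input_current(subpop, n, s, m, drive) == pytest.approx(expected)


def test_input_current_rejects_bad_arguments():
    drive = wmosc.DriveParams()
    with pytest.raises(ValueError):
        wmosc.input_current("e", 0, 0.0, 0, drive)
    with pytest.raises(ValueError):
        wmosc.input_current("e", 1, 1.5, 0, drive)
    with pytest.raises(ValueError):
        wmosc.input_current("x", 1, 0.0, 0, drive)


def test_drive_asymmetry_enforced():
    with pytest.raises(ValueError):
        wmosc.DriveParams(beta_e=0.8, beta_i=0.73)  # memory must favour i-cells
    with pytest.raises(ValueError):
        wmosc.DriveParams(alpha_e=0.3, alpha_i=0.38)


# ---------------------------------------------------------------------------
# synapse filter
# ---------------------------------------------------------------------------

def _impulse_response(tau, dt, n_steps, area_normalized, N=10):
    eta, s = 0.0, 0.0
    out = np.empty(n_steps)
    impulse = 1.0 / N
    for k in range(n_steps):
        eta, s = wmosc.synapse_step(eta, s, impulse if k == 0 else 0.0,
                                    tau, dt, area_normalized)
        out[k] = s
    return out


def test_synapse_quiescence_is_fixed_point():
    assert wmosc.synapse_step(0.0, 0.0, 0.0, 75.0, 0.03) == (0.0, 0.0)


@pytest.mark.parametrize("tau", [5.0, 75.0])
@pytest.mark.parametrize("area_normalized", [False, True])
def test_synapse_alpha_function_peak_and_area(tau, area_normalized):
    """A single spike produces the alpha-function response: s peaks at
    t = tau; the integral is tau/N (jump convention) or 1/N (normalized)."""
    dt = tau / 2000.0
    n = int(12 * tau / dt)
    s = _impulse_response(tau, dt, n, area_normalized)
    t_peak = np.argmax(s) * dt
    assert t_peak == pytest.approx(tau, rel=0.02)
    area = s.sum() * dt
    expected = (1.0 / 10) if area_normalized else (tau / 10)
    assert area == pytest.approx(expected, rel=0.01)
    assert np.all(s >= 0.0)


def test_synapse_jump_constant():
    assert _synapse_jump(10, 75.0, False) == pytest.approx(0.1)
    assert _synapse_jump(10, 75.0, True) == pytest.approx(1.0 / 750.0)


# ---------------------------------------------------------------------------
# OU noise
# ---------------------------------------------------------------------------

def test_ou_deterministic_decay():
    noise = wmosc.NoiseParams(sigma_w=0.0, sigma_c=0.0, tau_c=1000.0)
    rng = np.random.default_rng(0)
    z = 1.0
    for _ in range(1000):
        z = wmosc.ou_step(z, noise, 1.0, rng)
    assert z == pytest.approx(math.exp(-1.0), rel=1e-3)


def test_ou_stationary_variance(rng):
    """Long-run Var(zeta) -> sigma_c^2 * tau_c / 2 (Ito scaling)."""
    noise = wmosc.NoiseParams(sigma_c=0.001, tau_c=1000.0)
    dt = 5.0
    z = 0.0
    samples = np.empty(200_000)
    for k in range(samples.size):
        z = wmosc.ou_step(z, noise, dt, rng)
        samples[k] = z
    target = 0.001 ** 2 * 1000.0 / 2.0
    assert abs(samples.mean()) < 10 * math.sqrt(target)
    assert samples[2000:].var() == pytest.approx(target, rel=0.3)


# ---------------------------------------------------------------------------
# network stepping and full simulation
# ---------------------------------------------------------------------------

def test_leak_decay_toward_vm(quiet_network):
    """Synapses and inputs zeroed: v relaxes to v_m with time constant tau_v."""
    par, _, noi = quiet_network
    par = replace(par, v_m=-55.0)
    drive = wmosc.DriveParams(I_base_e=0.0, I_base_i=0.0, dI_base=0.0)
    state = dict(v=np.array([-50.0, -55.0]), zeta=np.zeros(2),
                 eta_e=0.0, s_e=0.0, eta_i=0.0, s_i=0.0)
    rng = np.random.default_rng(0)
    n = int(round(par.tau_v / par.dt))  # one membrane time constant
    for _ in range(n):
        state, spiked = wmosc.step_network(state, par, drive, noi, rng)
        assert not spiked.any()
    expected = -55.0 + 5.0 * math.exp(-1.0)
    assert state["v"][0] == pytest.approx(expected, abs=0.01)


def test_reset_voltage_after_spike(quiet_network):
    par, _, noi = quiet_network
    drive = wmosc.DriveParams(I_base_e=2.0, I_base_i=2.0, dI_base=0.0,
                              beta_e=0.0, beta_i=0.1)
    state = dict(v=np.array([par.v_T - 1e-6, par.v_R]), zeta=np.zeros(2),
                 eta_e=0.0, s_e=0.0, eta_i=0.0, s_i=0.0)
    rng = np.random.default_rng(0)
    state, spiked = wmosc.step_network(state, par, drive, noi, rng)
    assert spiked[0]
    assert state["v"][0] == par.v_R == -60.0


def test_noise_free_lif_period_matches_closed_form(quiet_network):
    """Uncoupled noise-free LIF: ISI = tau_v * ln((v_m+I-v_R)/(v_m+I-v_T))."""
    par, _, noi = quiet_network
    I = 1.0
    drive = wmosc.DriveParams(I_base_e=I, I_base_i=0.0, dI_base=0.0)
    trace = wmosc.simulate_network(par, drive, noi, 2000.0, seed=3)
    isis = np.diff(trace.spike_times[0])
    expected = par.tau_v * math.log((par.v_m + I - par.v_R) / (par.v_m + I - par.v_T))
    assert isis.size > 50
    assert np.allclose(isis, isis[0])  # deterministic firing
    assert isis[0] == pytest.approx(expected, rel=0.005)


def test_subthreshold_drive_never_spikes(quiet_network):
    par, _, noi = quiet_network
    drive = wmosc.DriveParams(I_base_e=-0.5, I_base_i=-0.5, dI_base=0.0)
    trace = wmosc.simulate_network(par, drive, noi, 1000.0, seed=4)
    assert all(st.size == 0 for st in trace.spike_times)


def test_kernel_matches_reference_steps():
    """The numba production kernel and the pure-python step functions apply
    the identical update rule (noise off, shared initial state)."""
    par, drv, _ = wmosc.default_network_params()
    noi = wmosc.NoiseParams(sigma_w=0.0, sigma_c=0.0)
    drv = drv.with_condition(0.3, True)
    n_cells = 2 * par.N
    v0 = np.linspace(par.v_R, par.v_T - 0.05, n_cells)
    n_steps = 4000

    trace = wmosc.simulate_network(par, drv, noi, n_steps * par.dt,
                                   seed=0, v0=v0)

    state = dict(v=v0.copy(), zeta=np.zeros(n_cells),
                 eta_e=0.0, s_e=0.0, eta_i=0.0, s_i=0.0)
    rng = np.random.default_rng(0)
    s_e_ref = np.empty(n_steps)
    spikes_ref = []
    for t in range(n_steps):
        state, spiked = wmosc.step_network(state, par, drv, noi, rng)
        s_e_ref[t] = state["s_e"]
        for c in np.nonzero(spiked)[0]:
            spikes_ref.append((t, c))

    np.testing.assert_allclose(trace.s_e_series, s_e_ref, rtol=0, atol=1e-12)
    spikes_kernel = sorted(
        (int(round(st / par.dt)) - 1, c)
        for c, times in enumerate(trace.spike_times) for st in times
    )
    assert spikes_kernel == sorted(spikes_ref)


def test_simulation_is_bit_reproducible():
    par, drv, noi = wmosc.default_network_params()
    a = wmosc.simulate_network(par, drv, noi, 500.0, seed=77)
    b = wmosc.simulate_network(par, drv, noi, 500.0, seed=77)
    np.testing.assert_array_equal(a.lfp, b.lfp)
    for sa, sb in zip(a.spike_times, b.spike_times):
        np.testing.assert_array_equal(sa, sb)
    c = wmosc.simulate_network(par, drv, noi, 500.0, seed=78)
    assert not np.array_equal(a.lfp, c.lfp)


def test_synaptic_series_nonnegative():
    par, drv, noi = wmosc.default_network_params()
    tr = wmosc.simulate_network(par, drv.with_condition(1.0, True), noi,
                                2000.0, seed=5)
    assert tr.s_e_series.min() >= 0.0
    assert tr.s_i_series.min() >= 0.0
    for st in tr.spike_times:
        assert np.all(np.diff(st) > 0)


# ---------------------------------------------------------------------------
# LFP proxy
# ---------------------------------------------------------------------------

def test_lfp_proxy_coefficients():
    par, _, _ = wmosc.default_network_params()
    ones = np.ones(4)
    zeros = np.zeros(4)
    np.testing.assert_allclose(wmosc.lfp_proxy(zeros, zeros, par), 0.0)
    np.testing.assert_allclose(wmosc.lfp_proxy(ones, zeros, par),
                               (0.002 + 0.02) * (-55.0), rtol=1e-12)
    np.testing.assert_allclose(wmosc.lfp_proxy(zeros, ones, par),
                               (0.002 + 0.02) * 45.0, rtol=1e-12)


def test_lfp_proxy_corrected_weighting_option():
    par, _, _ = wmosc.default_network_params()
    par = replace(par, lfp_inhibitory_corrected=True)
    np.testing.assert_allclose(wmosc.lfp_proxy(np.zeros(3), np.ones(3), par),
                               (0.04 + 0.02) * 45.0, rtol=1e-12)


def test_lfp_proxy_length_mismatch_rejected():
    par, _, _ = wmosc.default_network_params()
    with pytest.raises(ValueError):
        wmosc.lfp_proxy(np.zeros(3), np.zeros(4), par)
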