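"""Tests of the oscillation/spike statistics against constructed signals
with exactly known content."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wmosc
from wmosc import BandpassSpec

DT = wmosc.DT_MS
FS = 1000.0 / DT


def _phase_wrap(x):
    return np.angle(np.exp(1j * x))


# ---------------------------------------------------------------------------
# bandpass + instantaneous phase
# ---------------------------------------------------------------------------

def test_bandpass_passband_and_stopband():
    spec = BandpassSpec(8.0, 25.0, fs=FS)
    t = np.arange(int(4000 / DT)) * DT / 1000.0
    inband = np.cos(2 * np.pi * 15.0 * t)
    out = wmosc.bandpass(inband, spec)
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    amp = np.ptp(out[mid]) / 2.0
    assert 0.95 <= amp <= 1.05

    low = np.cos(2 * np.pi * 2.0 * t)
    amp_low = np.ptp(wmosc.bandpass(low, spec)[mid]) / 2.0
    assert amp_low < 0.1

    high = np.cos(2 * np.pi * 50.0 * t)
    amp_high = np.ptp(wmosc.bandpass(high, spec)[mid]) / 2.0
    assert amp_high < 0.1

    np.testing.assert_allclose(wmosc.bandpass(np.zeros(2048), spec), 0.0)


def test_bandpass_rejects_band_outside_nyquist():
    with pytest.raises(ValueError):
        BandpassSpec(8.0, FS, fs=FS)


def test_instantaneous_phase_of_cosine_and_sine():
    """Analytic phase of cos(2*pi*f*t) is wrap(2*pi*f*t): zero at crests;
    a sine lags by pi/2 everywhere."""
    spec = BandpassSpec(5.0, 15.0, fs=FS)
    t = np.arange(int(6000 / DT)) * DT / 1000.0
    cos_ph = wmosc.instantaneous_phase(np.cos(2 * np.pi * 10 * t), spec)
    expected = _phase_wrap(2 * np.pi * 10 * t)
    sel = cos_ph.valid
    err = _phase_wrap(cos_ph.phi[sel] - expected[sel])
    assert np.max(np.abs(err)) < 0.02

    sin_ph = wmosc.instantaneous_phase(np.sin(2 * np.pi * 10 * t), spec)
    lag = _phase_wrap(cos_ph.phi[sel] - sin_ph.phi[sel])
    np.testing.assert_allclose(lag, np.pi / 2, atol=0.02)

    assert cos_ph.phi.max() <= np.pi and cos_ph.phi.min() > -np.pi


def test_instantaneous_phase_rejects_constant():
    spec = BandpassSpec(8.0, 25.0, fs=FS)
    with pytest.raises(ValueError):
        wmosc.instantaneous_phase(np.ones(1024), spec)


# ---------------------------------------------------------------------------
# SPL
# ---------------------------------------------------------------------------

def test_spl_extremes():
    assert wmosc.spl(np.full(17, 0.8)).spl == pytest.approx(1.0)
    assert wmosc.spl(np.array([0.3, 0.3 + np.pi])).spl == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        wmosc.spl(np.array([]))


def test_spl_rayleigh_floor(rng):
    """E[SPL] for N uniform phases approaches sqrt(pi)/(2 sqrt(N))."""
    n, reps = 100, 400
    vals = [wmosc.spl(rng.uniform(-np.pi, np.pi, n)).spl for _ in range(reps)]
    expected = np.sqrt(np.pi) / (2 * np.sqrt(n))  # 0.0886
    assert np.mean(vals) == pytest.approx(expected, rel=0.1)


@settings(deadline=None, max_examples=25)
@given(st.floats(-10, 10))
def test_spl_invariant_under_global_rotation(rotation):
    phases = np.linspace(-2.0, 1.5, 37)
    a = wmosc.spl(phases).spl
    b = wmosc.spl(_phase_wrap(phases + rotation)).spl
    assert a == pytest.approx(b, abs=1e-12)


def test_spl_frequency_sweep_peaks_at_locking_frequency():
    # broadband noise makes off-band phase estimates decohere from the tone
    lfp = wmosc.make_sinusoid_lfp([10.0], [1.0], duration_ms=8000.0,
                                  noise_sd=1.0, seed=2)
    spec = wmosc.LockedSpikeSpec(freq_hz=10.0, kappa=4.0, rate_hz=20.0,
                                 duration_ms=8000.0, seed=1)
    spikes = wmosc.make_locked_spikes(spec)
    centers, vals = wmosc.spl_frequency_sweep(spikes, lfp, DT,
                                              centers=np.arange(4.0, 30.0, 1.0))
    assert abs(centers[np.nanargmax(vals)] - 10.0) <= 2.0


def test_spl_frequency_sweep_empty_grid():
    centers, vals = wmosc.spl_frequency_sweep(np.array([10.0]), np.ones(4096),
                                              DT, centers=np.array([]))
    assert centers.size == 0 and vals.size == 0


# ---------------------------------------------------------------------------
# modulation index
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("xi,xo,expected", [(2, 2, 0.0), (3, 1, 0.5), (0, 5, -1.0)])
def test_modulation_index_values(xi, xo, expected):
    assert wmosc.modulation_index(xi, xo) == pytest.approx(expected)


def test_modulation_index_undefined_for_zero_pair():
    with pytest.raises(ValueError):
        wmosc.modulation_index(0.0, 0.0)


@settings(deadline=None, max_examples=50)
@given(st.floats(0.001, 1e3), st.floats(0.001, 1e3))
def test_modulation_index_antisymmetric_and_bounded(a, b):
    mi = wmosc.modulation_index(a, b)
    assert -1.0 <= mi <= 1.0
    assert mi == pytest.approx(-wmosc.modulation_index(b, a), abs=1e-12)


# ---------------------------------------------------------------------------
# power spectrum
# ---------------------------------------------------------------------------

def test_power_spectrum_recovers_tone_dc_and_amplitude():
    x = wmosc.make_sinusoid_lfp([16.0], [2.0], dc=0.5, duration_ms=4000.0)
    res = wmosc.power_spectrum(x, DT)
    assert res.omega == pytest.approx(16.0, abs=1.0)
    assert res.dc_mean == pytest.approx(0.5, abs=1e-6)
    assert res.amplitude_at_omega == pytest.approx(2.0, rel=0.02)


def test_power_spectrum_constant_signal_flags_omega():
    res = wmosc.power_spectrum(np.full(2 ** 15, 3.0), DT)
    assert np.isnan(res.omega)
    assert res.dc_mean == pytest.approx(3.0)
    assert res.amplitude_at_omega == 0.0


def test_power_spectrum_dominant_component_wins():
    x = wmosc.make_sinusoid_lfp([10.0, 20.0], [1.0, 0.5], duration_ms=2000.0)
    assert wmosc.power_spectrum(x, DT).omega == pytest.approx(10.0, abs=1.0)


def test_power_spectrum_energy_identity():
    """Summed periodogram equals twice the segment-demeaned variance (one-
    sided amplitude convention); the mean is carried separately by dc_mean."""
    rng = np.random.default_rng(8)
    x = 1.5 + rng.standard_normal(2 ** 15)
    res = wmosc.power_spectrum(x, DT)
    assert res.power.sum() / 2.0 == pytest.approx((x - x.mean()).var(), rel=0.01)
    assert res.dc_mean == pytest.approx(1.5, abs=0.05)


def test_power_spectrum_rejects_short_signal():
    with pytest.raises(ValueError):
        wmosc.power_spectrum(np.zeros(1000), DT)


# ---------------------------------------------------------------------------
# Fano factor and rate ratio
# ---------------------------------------------------------------------------

def test_fano_constant_counts_zero():
    assert wmosc.fano_factor(np.full(10, 7)).fano == 0.0


def test_fano_poisson_is_one():
    counts = wmosc.make_poisson_counts(5.0, 10_000, seed=3)
    assert wmosc.fano_factor(counts).fano == pytest.approx(1.0, abs=0.05)


def test_fano_scales_linearly_with_count_doubling():
    counts = wmosc.make_poisson_counts(4.0, 5000, seed=4)
    f1 = wmosc.fano_factor(counts).fano
    f2 = wmosc.fano_factor(2 * counts).fano
    assert f2 == pytest.approx(2 * f1, rel=1e-9)


def test_fano_undefined_for_empty_windows():
    with pytest.raises(ValueError):
        wmosc.fano_factor(np.zeros(10))


@pytest.mark.parametrize("rate,omega,expected", [(10, 10, 1.0), (5, 10, 0.5), (0, 10, 0.0)])
def test_fr_omega_ratio(rate, omega, expected):
    assert wmosc.fr_omega_ratio(rate, omega) == pytest.approx(expected)


def test_fr_omega_ratio_undefined_omega_propagates():
    assert np.isnan(wmosc.fr_omega_ratio(5.0, float("nan")))


# ---------------------------------------------------------------------------
# cutoff sweep
# ---------------------------------------------------------------------------

def test_cutoff_sweep_recovers_planted_boundary():
    table = wmosc.make_toy_waveform_table(boundary=0.2, fr_effect=0.4,
                                          spl_effect=0.4, seed=9)
    res = wmosc.cutoff_sweep(table.widths, table.mi_fr, table.mi_spl)
    k = np.nanargmin(res["p_fr_narrow"])
    # strongest narrow-side FR significance at/above the planted boundary
    assert abs(res["cutoffs"][k] - 0.2) < 0.1
    assert np.nanmin(res["p_fr_narrow"]) < 1e-3
    assert np.nanmin(res["p_spl_broad"]) < 1e-3


def test_cutoff_sweep_null_mi_not_significant():
    widths = np.linspace(0.1, 0.5, 40)
    zeros = np.zeros(40)
    res = wmosc.cutoff_sweep(widths, zeros, zeros)
    assert np.all(np.isnan(res["p_fr_narrow"]))


def test_cutoff_sweep_shuffled_widths_flat(rng):
    """With widths shuffled, the planted structure is destroyed and minimum
    p-values over the sweep stay far above the planted-case significance."""
    table = wmosc.make_toy_waveform_table(boundary=0.2, fr_effect=0.0,
                                          spl_effect=0.0, noise_sd=0.1, seed=11)
    mins = []
    for _ in range(20):
        w = rng.permutation(table.widths)
        res = wmosc.cutoff_sweep(w, table.mi_fr, table.mi_spl)
        mins.append(np.nanmin(res["p_fr_narrow"]))
    # no planted effect: median best-p across shuffles is not extreme
    assert np.median(mins) > 1e-3
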