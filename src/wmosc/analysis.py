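"""Oscillation and spike-train statistics.

Implements the analysis layer used on network (or synthetic) signals:

* zero-phase bandpass filtering and Hilbert-transform instantaneous phase;
* spike phase locking (SPL) — the vector strength of spike-triggered
  oscillation phases, in [0, 1];
* modulation index MI = (X_in - X_out) / (X_in + X_out);
* mean-periodogram power spectra on 1-s (2**15-sample) segments, peak
  frequency Omega and the spectral amplitude at the peak;
* Fano factor of spike counts over fixed windows;
* the waveform-width cutoff sweep: signed-rank significance of MI
  distributions as a function of the narrow/broad segmentation cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

__all__ = [
    "BandpassSpec",
    "PhaseSeries",
    "SpectrumResult",
    "SPLResult",
    "FanoResult",
    "ALPHA_BETA_BAND",
    "THETA_BAND",
    "bandpass",
    "instantaneous_phase",
    "spl",
    "spl_from_trace",
    "spl_frequency_sweep",
    "modulation_index",
    "power_spectrum",
    "fano_factor",
    "fr_omega_ratio",
    "cutoff_sweep",
]

#: Canonical oscillation bands (Hz).
ALPHA_BETA_BAND = (8.0, 25.0)
THETA_BAND = (4.0, 7.0)

#: Fraction of samples at each end of a phase series treated as unreliable
#: (Hilbert-transform edge artifacts).
EDGE_FRACTION = 0.05

#: Number of samples per 1-s spectral segment (power of two for the FFT).
SEGMENT_SAMPLES = 2 ** 15


@dataclass(frozen=True)
class BandpassSpec:
    """A bandpass specification: edges in Hz, zero-phase Butterworth order
    (per pass), and the sampling rate of the signal."""

    f_lo: float
    f_hi: float
    fs: float
    order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi < self.fs / 2):
            raise ValueError("require 0 < f_lo < f_hi < Nyquist")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class PhaseSeries:
    """Instantaneous phase of a band-filtered signal, radians in (-pi, pi].

    ``valid`` marks the samples outside the edge-artifact margins; spike
    phases should only be read from valid samples.
    """

    phi: np.ndarray
    spec: BandpassSpec
    valid: np.ndarray

    def spike_phases(self, spike_times: np.ndarray, dt: float) -> np.ndarray:
        """Phases at the given spike times (ms); spikes in the unreliable
        edge regions or outside the series are dropped."""
        idx = np.asarray(np.round(np.asarray(spike_times) / dt), dtype=int)
        idx = idx[(idx >= 0) & (idx < self.phi.shape[0])]
        idx = idx[self.valid[idx]]
        return self.phi[idx]


@dataclass
class SpectrumResult:
    """Mean periodogram over non-overlapping 1-s segments.

    ``omega`` is the frequency of maximal power at or above ``f_min`` (NaN
    when the signal has no oscillatory content); ``amplitude_at_omega`` uses
    the 2|FFT|/L amplitude convention so a unit-amplitude sinusoid reads 1.
    ``dc_mean`` is the plain time average of the raw signal.
    """

    freqs: np.ndarray
    power: np.ndarray
    omega: float
    amplitude_at_omega: float
    dc_mean: float
    n_segments: int


@dataclass
class SPLResult:
    """Vector strength of spike phases with the circular mean phase."""

    spl: float
    n_spikes: int
    mean_phase: float


@dataclass
class FanoResult:
    fano: float
    window_ms: float
    n_windows: int
    mean_count: float


def bandpass(x: np.ndarray, spec: BandpassSpec) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass.

    Zero-phase filtering is essential here: a causal filter would shift the
    oscillation phase and bias every SPL estimate built on top of it.
    """
    x = np.asarray(x, dtype=float)
    sos = sps.butter(spec.order, [spec.f_lo, spec.f_hi],
                     btype="bandpass", fs=spec.fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def instantaneous_phase(filtered: np.ndarray, spec: BandpassSpec) -> PhaseSeries:
    """Phase of the analytic signal of a band-limited input.

    The first and last 5% of samples are flagged unreliable (transform edge
    effects). A (near-)constant input has no defined phase and is rejected.
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.ndim != 1 or filtered.shape[0] < 16:
        raise ValueError("need a 1-d signal of reasonable length")
    if np.ptp(filtered) == 0:
        raise ValueError("constant signal has undefined phase")
    analytic = sps.hilbert(filtered - filtered.mean())
    phi = np.angle(analytic)
    n = phi.shape[0]
    margin = int(np.ceil(EDGE_FRACTION * n))
    valid = np.zeros(n, dtype=bool)
    valid[margin:n - margin] = True
    return PhaseSeries(phi=phi, spec=spec, valid=valid)


def spl(spike_phases: np.ndarray) -> SPLResult:
    """Spike phase locking: modulus of the mean unit phasor of the spike
    phases. 1 = perfectly concentrated, ~N^{-1/2} for uniform phases."""
    phases = np.asarray(spike_phases, dtype=float)
    if phases.size == 0:
        raise ValueError("SPL is undefined for zero spikes")
    z = np.exp(1j * phases).mean()
    return SPLResult(spl=float(np.abs(z)), n_spikes=int(phases.size),
                     mean_phase=float(np.angle(z)))


def spl_from_trace(
    spike_times: np.ndarray,
    lfp: np.ndarray,
    dt: float,
    band: tuple[float, float] = ALPHA_BETA_BAND,
    order: int = 4,
) -> SPLResult:
    """SPL of a spike train against the band-filtered LFP phase."""
    spec = BandpassSpec(band[0], band[1], fs=1000.0 / dt, order=order)
    ph = instantaneous_phase(bandpass(lfp, spec), spec)
    return spl(ph.spike_phases(spike_times, dt))


def spl_frequency_sweep(
    spike_times: np.ndarray,
    lfp: np.ndarray,
    dt: float,
    centers: np.ndarray | None = None,
    half_width: float = 2.0,
    order: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """SPL versus band center frequency (default 4 Hz-wide bands, 1 Hz
    steps, 2-60 Hz). Returns (centers, spl values); bands with no usable
    spikes yield NaN."""
    if centers is None:
        centers = np.arange(2.0 + half_width, 60.0 - half_width + 1e-9, 1.0)
    centers = np.asarray(centers, dtype=float)
    values = np.full(centers.shape, np.nan)
    fs = 1000.0 / dt
    for k, fc in enumerate(centers):
        lo, hi = fc - half_width, fc + half_width
        if lo <= 0 or hi >= fs / 2:
            continue
        spec = BandpassSpec(lo, hi, fs=fs, order=order)
        ph = instantaneous_phase(bandpass(lfp, spec), spec)
        phases = ph.spike_phases(spike_times, dt)
        if phases.size:
            values[k] = spl(phases).spl
    return centers, values


def modulation_index(x_in: float, x_out: float) -> float:
    """Bounded contrast (x_in - x_out) / (x_in + x_out) in [-1, 1]."""
    if x_in < 0 or x_out < 0:
        raise ValueError("modulation index requires non-negative inputs")
    total = x_in + x_out
    if total == 0:
        raise ValueError("modulation index undefined when both inputs are zero")
    return (x_in - x_out) / total


def power_spectrum(
    x: np.ndarray,
    dt: float,
    f_min: float = 1.0,
    segment: int = SEGMENT_SAMPLES,
) -> SpectrumResult:
    """Mean amplitude-normalized periodogram over non-overlapping 1-s
    segments (2**15 samples at the native dt).

    The per-segment mean is removed before the FFT so DC leakage does not
    contaminate the low-frequency bins; the signal's DC component is
    reported separately as ``dc_mean``. Omega is the argmax of power at
    f >= f_min; it is NaN when the oscillatory part of the signal is
    indistinguishable from zero (e.g. a constant input).
    """
    x = np.asarray(x, dtype=float)
    n_seg = x.shape[0] // segment
    if n_seg < 1:
        raise ValueError(f"signal shorter than one {segment}-sample segment")
    segs = x[: n_seg * segment].reshape(n_seg, segment)
    dc_mean = float(x.mean())
    demeaned = segs - segs.mean(axis=1, keepdims=True)
    amp = 2.0 * np.abs(np.fft.rfft(demeaned, axis=1)) / segment
    freqs = np.fft.rfftfreq(segment, d=dt / 1000.0)
    power = (amp ** 2).mean(axis=0)
    sel = freqs >= f_min
    if not np.any(sel) or np.all(power[sel] <= 1e-24):
        omega, amp_at = float("nan"), 0.0
    else:
        k = np.argmax(power[sel])
        omega = float(freqs[sel][k])
        amp_at = float(np.sqrt(power[sel][k]))
    return SpectrumResult(freqs=freqs, power=power, omega=omega,
                          amplitude_at_omega=amp_at, dc_mean=dc_mean,
                          n_segments=n_seg)


def fano_factor(counts: np.ndarray, window_ms: float = 1000.0) -> FanoResult:
    """Variance/mean of spike counts over repeated windows."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two count windows")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("Fano factor undefined for zero mean count")
    return FanoResult(fano=float(counts.var(ddof=1) / mean),
                      window_ms=window_ms, n_windows=int(counts.size),
                      mean_count=float(mean))


def fr_omega_ratio(rate_hz: float, omega_hz: float) -> float:
    """Firing rate relative to the LFP peak frequency; ~1 means one spike
    per oscillation cycle."""
    if not np.isfinite(omega_hz) or omega_hz <= 0:
        return float("nan")
    return rate_hz / omega_hz


def cutoff_sweep(
    widths: np.ndarray,
    mi_fr: np.ndarray,
    mi_spl: np.ndarray,
    cutoffs: np.ndarray | None = None,
    min_group: int = 2,
) -> dict:
    """Significance of MI distributions as a function of a waveform-width
    segmentation cutoff.

    For each candidate cutoff the units are split into a narrow (< cutoff)
    and broad (>= cutoff) group, and a one-sample Wilcoxon signed-rank test
    of the group's MI values against zero median is run for the firing-rate
    MI on the narrow side and the SPL MI on the broad side (the two effects
    expected to segregate with putative cell class). Groups smaller than
    ``min_group`` or with all-zero MI yield NaN.

    Returns a dict with ``cutoffs``, ``p_fr_narrow``, ``p_spl_broad`` and
    the per-side group sizes.
    """
    widths = np.asarray(widths, dtype=float)
    mi_fr = np.asarray(mi_fr, dtype=float)
    mi_spl = np.asarray(mi_spl, dtype=float)
    if not (widths.shape == mi_fr.shape == mi_spl.shape):
        raise ValueError("widths and MI arrays must have equal shape")
    if cutoffs is None:
        uw = np.unique(widths)
        cutoffs = (uw[1:] + uw[:-1]) / 2.0
    cutoffs = np.asarray(cutoffs, dtype=float)

    def _p(values: np.ndarray) -> float:
        if values.size < min_group or np.allclose(values, 0.0):
            return float("nan")
        try:
            return float(stats.wilcoxon(values, zero_method="wilcox").pvalue)
        except ValueError:
            return float("nan")

    p_fr = np.empty(cutoffs.shape)
    p_spl = np.empty(cutoffs.shape)
    n_narrow = np.empty(cutoffs.shape, dtype=int)
    n_broad = np.empty(cutoffs.shape, dtype=int)
    for k, c in enumerate(cutoffs):
        narrow = widths < c
        broad = ~narrow
        n_narrow[k] = narrow.sum()
        n_broad[k] = broad.sum()
        p_fr[k] = _p(mi_fr[narrow])
        p_spl[k] = _p(mi_spl[broad])
    return {
        "cutoffs": cutoffs,
        "p_fr_narrow": p_fr,
        "p_spl_broad": p_spl,
        "n_narrow": n_narrow,
        "n_broad": n_broad,
    }
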