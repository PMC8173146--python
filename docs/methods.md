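# Methods

## Network model

Two populations of N = 10 leaky integrate-and-fire neurons (excitatory
*e*, inhibitory *i*) are coupled all-to-all, including self-coupling
(with N = 10 the self-term is negligible). Membrane voltage obeys

    τ_v dv/dt = v_m − v + w_ji s_i (v_i − v) + w_je s_e (v_e − v) + I_j + γ(t)

where the weight subscripts are (postsynaptic, presynaptic): e-cells
receive inhibition w_ei·s_i and recurrent excitation w_ee·s_e; i-cells
receive w_ii·s_i and w_ie·s_e. A cell spikes when v ≥ v_T after the Euler
update, is recorded at that step, and is reset to v_R; no refractory
period is imposed and no sub-step threshold interpolation is performed.

Synaptic activity per population is a two-stage linear filter

    τ_j dη/dt = −η + impulses,     τ_j ds_j/dt = −s_j + η

Each spike in population j increments η by 1/N, so the single-spike
response of s_j is the alpha function peaking at t = τ_j with area τ_j/N.
This jump normalization makes recurrent inhibition strong enough to
sustain the slow-GABA_B-paced rhythm that is the point of the model; the
alternative area-normalized filter (increment 1/(N·τ_j), area 1/N — the
form obtained by reading the δ-input of the rise equation as an area-1
impulse) weakens the coupling by a factor τ_j and leaves the circuit
asynchronous. It remains available via
`NetworkParams.synapse_area_normalized` for filter-level analyses.

Tonic drive is I_j = α_j·s + β_j·m + I_base,j + ΔI·(n−1) with bottom-up
control s ∈ [0, 1], memory flag m ∈ {0, 1}, and a per-cell offset gradient
that supplies rate heterogeneity. Bottom-up gain favours e-cells
(α_e = 0.8 > α_i = 0.38 mV) and memory gain favours i-cells
(β_i = 0.73 > β_e mV).

Noise is γ(t) = σ_w ξ₁(t) + ζ(t) with white ξ₁ and an Ornstein–Uhlenbeck
ζ (τ_c = 1000 ms, amplitude σ_c); both are integrated with Itô
(Euler–Maruyama) scaling, giving stationary OU variance σ_c²τ_c/2. At the
default amplitudes (σ_w = 0.05, σ_c = 0.001 mV) the voltage noise is small
(~0.01 mV sd); variability in the network arises mainly from the
heterogeneous, quasi-chaotic recurrent dynamics.

### Parameter defaults and calibration

All defaults are in `wmosc.params`. Two values deserve comment:

* **v_m = −50 mV (= v_T).** The leak reversal is a free constant of this
  formulation; placing it at threshold makes the 0.3–1.4 mV tonic currents
  directly suprathreshold, so the drive parameters alone set the operating
  point. It is exposed in `NetworkParams`.
* **β_e = 0.593, I_base_e = 0.40 mV (calibrated).** The model's defining
  constraint is *rate parity*: the memory input must leave baseline e-cell
  rates unchanged because its direct excitatory effect is cancelled by the
  extra inhibition it recruits. Parity depends on integrator conventions,
  so β_e was tuned once (bisection over seed-averaged 30-s runs) to
  equalize IN/OUT e-cell rates at s = 0 (residual −0.2%), and I_base_e to
  put that baseline at 4–5 Hz (4.87 Hz). Both are frozen; no other
  constant was adjusted.

The LFP proxy is LFP(t) = (w_ee+w_ei)(−55 − v_e)·s_e + (w_ee+w_ei)(−55 −
v_i)·s_i, the return-current-weighted synaptic drive of an e-cell at the
near-rest potential −55 mV (coefficients −1.21 and +0.99 with the default
weights; the proxy is positive, dominated by the inhibitory term). A
variant weighting the inhibitory term by (w_ie+w_ii) is available via
`NetworkParams.lfp_inhibitory_corrected`.

### Integration and reproducibility

Explicit first-order Euler–Maruyama with Δt = 1000/2¹⁵ ≈ 0.0305 ms, so a
1-s analysis segment holds exactly 2¹⁵ samples. Initial voltages are drawn
uniformly in [v_R, v_T) to desynchronize the start; all statistics discard
a 2-s transient. One root seed drives everything: `numpy.SeedSequence`
spawns per-run child seeds (initial state and the numba kernel's noise
stream), making traces bit-reproducible. The production path is a numba
kernel; pure-Python single-step functions (`step_network`, `synapse_step`,
`ou_step`) define the same update rule and the test suite verifies exact
kernel/reference agreement on noise-free runs. The kernel aborts with a
diagnostic on non-finite state or pathological spike budgets
(> ~1 kHz/cell sustained).

## Analysis layer

* **Bandpass**: zero-phase forward–backward Butterworth (order 4 per
  pass). Zero-phase filtering is non-negotiable here: any phase lag would
  bias every SPL estimate. Band edges: alpha–beta 8–25 Hz, theta 4–7 Hz.
* **Instantaneous phase**: angle of the Hilbert analytic signal computed
  over the full (demeaned) trace; the first and last 5% of samples are
  flagged unreliable and spikes there are excluded from phase assignment.
* **SPL**: modulus of the mean unit phasor over spike phases, with the
  circular mean phase; undefined (error, not 0) for zero spikes. Uniform
  phases give the Rayleigh floor √π/(2√N). The frequency sweep uses
  4 Hz-wide bands stepped by 1 Hz over 2–60 Hz.
* **Spectrum**: mean periodogram over non-overlapping 2¹⁵-sample segments,
  amplitude convention 2|FFT|/L (a unit sinusoid reads 1). Per-segment
  means are removed before the FFT; the DC component is reported
  separately as the plain time average. Ω is the raw argmax at f ≥ 1 Hz
  (harmonics are not merged); it is NaN for constant signals.
* **Fano factor**: variance/mean of spike counts in non-overlapping 1-s
  windows taken from one long post-transient run per condition — under
  stationarity this matches repeated independent trials and is far
  cheaper. Undefined at zero mean count.
* **Cutoff sweep**: for each candidate waveform-width cutoff, one-sample
  Wilcoxon signed-rank tests of MI against zero median — firing-rate MI on
  the narrow side, SPL MI on the broad side, matching the expected
  segregation of the two effects by putative cell class. Groups smaller
  than 2 units or with degenerate MI yield NaN and are skipped.

## Phase-oscillator reduction

Each e-cell is modeled feed-forward as dθ/dt = ω + R(θ)·s_LFP(t) + χ(t),
θ ∈ [0, 1) with a spike and reset at 1. θ may go below 0 under strong
input — a reflecting boundary would clip exactly the inhibitory-delay
mechanism the model exists to express. R(θ) = mθ + b with m = −0.058,
b = −0.0325 (flat variant: R ≡ M = −0.075); rates are in cycles/ms. The
tonic rate composes as ω = ω₀(variant, condition) + Δω·s + Δω_n(n), the
minimal linear rule over the tabulated symbols, with heterogeneity
Δω_n = 0.006 + 0.0013(n−1).

**Calibration.** ω₀ and Δω are not mechanism constants but fits that tie
the reduction to the specific network realization driving it: ω₀ is tuned
(per phase-coupling flag and condition) so the across-cell mean rate at
s = 0 equals the network e-cell baseline — the same parity constraint the
network obeys — and Δω so the full model matches the network e-cell rate
at s = 1. `run_phase_experiment` performs both calibrations against the
supplied inputs by default; the frozen table defaults remain available
with `calibrate=False`. Mean-linearized variants reuse their
counterparts' ω₀ (the chord correction vanishes at s = 0).

**Noise.** χ = σ_θ·(white) + ν with OU ν (τ_c = 1000 ms reused,
σ_ν = 1e−4). σ_θ = 0.003 was calibrated once so the full-variant IN SPL at
s = 0 matches the network e-cell SPL within 10% (0.934 vs 0.929), then
frozen.

**Mean linearization** replaces the mean-versus-s curve of the OUT
condition input by the chord through its endpoints, shifting each level's
baseline by (chord − original) while leaving the oscillatory component
untouched; the IN curve, already near-linear, is not modified.

## Synthetic fixtures

The generators produce inputs with exactly known statistics: sinusoid
composites (spectral content exact), von Mises phase-locked spike trains
(asymptotic SPL = I₁(κ)/I₀(κ), giving an analytic oracle), Poisson counts
(Fano 1), and a toy waveform-width/MI table with a planted narrow/broad
boundary (FR effect below, SPL effect above). They validate the analysis
operations end to end but do not emulate real extracellular data: no 1/f
background, no waveform shapes, no recording noise, no non-stationarity.
Passing round-trips therefore certify the estimators, not their behavior
on recorded signals.

## Default regime and known limitations

With the default parameter set this implementation produces: rate parity
at s = 0 (≈4.9 Hz both conditions); i-cell rates elevated IN at every s;
an LFP rhythm at ~7 Hz (OUT) and ~14–15 Hz (IN) at s = 0, accelerating to
~25–27 Hz at s = 1 in both conditions; LFP DC growth of ~0.33 (OUT) and
~0.40 (IN) a.u. across the sweep; e-cell SPL higher IN than OUT (≈0.93 vs
0.88); and a higher e-cell gain IN for low-to-mid bottom-up input with
convergence near s = 1.

Limitations to keep in mind:

* The oscillation frequency grows steeply with bottom-up drive; at high s
  the rhythm is paced by the fast e-cell volleys rather than the slow
  inhibitory decay, and Ω tracks the e-rate. Quantities tied to a slower
  high-drive rhythm (e.g. a mid-beta endpoint) are outside this regime.
* The LFP DC growth across the sweep is modest and slightly larger IN
  than OUT, and the OUT input-output curve is only weakly saturating. The
  phase-model ablations that read out input-mean structure (flat-R rate
  gain, mean-linearization inversion) therefore produce small, sometimes
  sign-reversed effects relative to what strongly saturating inhibition
  would give.
* At baseline the IN-condition e-cells fire at ~0.3–0.4 spikes per
  oscillation cycle (cycle skipping), which makes their spike counts
  *more* variable IN than OUT; Fano contrasts consequently favour OUT in
  this regime, and the stabilization expected for cells with rate ≈ Ω is
  not reached at the default operating point.
* i-cell SPL is high in both conditions and somewhat lower IN; the model
  makes no claim of i-cell SPL invariance here.
* SPL magnitudes are high overall (0.8–0.95): extrinsic noise is small,
  so spike timing is strongly rhythm-locked. Orderings between conditions
  are robust across seeds; absolute SPL values should not be compared to
  recordings with measurement noise.

Problem sizes used by the shipped runs: the sweep experiments simulate
22 s per (s, condition) level (20 s analyzed); the acceptance summary uses
5 × 32 s runs for the baseline rate and 100 one-second windows per
condition/level for Fano factors; the test suite uses 10 seeds × 30 s for
ordering checks and 12 s per level for sweep-shape checks.
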