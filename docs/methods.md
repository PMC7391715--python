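# Methods

This note records the models implemented in `trapnoise`, the default
parameter choices and why they were made, the numerical conventions,
and what the synthetic-data generator does and does not emulate.

## Trap kinetics and the telegraph model

A single oxide trap near the channel is a two-state continuous-time
Markov chain: empty (0) with capture rate λ = 1/τ_c, occupied (1) with
emission rate μ = 1/τ_e. The emission time is taken voltage-independent
and the capture time thermally activated,

    τ_c(V_G) = τ_c0 · exp(−q α (V_G − V0) / kT),    τ_e = τ_e0,

with α the gate-to-trap coupling (ratio of gate to tunneling
capacitance, 0 < α ≤ 1). This is the minimal model consistent with the
observed behaviour of liquid-gated nanowire FETs — near-constant
emission time, strongly gate-dependent capture time — and it implies a
logistic occupancy curve

    g(V_G) = 1 / (1 + exp(−q α (V_G − V0) / kT)),

whose slope g_g = g(1−g)·qα/kT peaks at g = 1/2. The occupancy-curve
fit in `extraction.g_curve` uses exactly this parameterization (scale
kT/qα), with a finite-difference fallback for model-free slopes.

Simulation is event-driven — exponential dwell sampling, then point
resampling onto the uniform grid — rather than per-step Bernoulli,
because the dwell-time statistics are the scientific object and must
not carry discretization bias. The cost is that dwells shorter than dt
can be lost; at dt = 0.01·min(τ_c, τ_e) this affects <1% of events.
The initial state is drawn from the stationary distribution so traces
have no transient.

## Noise models

All spectral densities are one-sided in ordinary frequency unless
stated otherwise (the measurement convention of a spectrum analyser).
Physical constants are the SI-2019 exact values k = 1.380649e-23 J/K,
q = 1.602176634e-19 C.

* Trap-number 1/f noise (many-trap limit, N_ot·A ≫ 1):
  S_q = q²N_ot A/f, S_VG = q²N_ot/(C_G² A f).
* Dielectric-polarization (DP) noise — the thermal limit:
  S_q = 2kT·tgδ·C/(πf), S_VG = 2kT·tgδ/(πCf) with C = C_G·A the total
  gate capacitance and tgδ the loss tangent (3.8e-3 for SiO₂).
* Single-trap RTS Lorentzian:
  S_VG = 4g(1−g)²τ_e (q*/C)² / (1 + (2π(1−g)τ_e f)²). Where this form
  is sometimes quoted with the per-area capacitance symbol, the total
  capacitance C_G·A is meant; this package normalizes to total
  capacitance everywhere.
* Corner frequency f₀ = (λ+μ)/2π = 1/(2π(1−g)τ_e), reducing to
  1/(2πτ_c) at high occupancy.
* RTS maximum relative to a 1/f background: evaluating the Lorentzian
  at its corner at g = 1/2 gives (1/4π)·(q*/C)²/f₀. The exact 1/(4π) =
  0.0796 is used in computation; 0.08 is its conventional rounding.

The effective trapped charge defaults to q* = 0.5q, the image-charge
reduced value for a trap in SiO₂.

## Occupancy ("g-factor") noise

The windowed occupancy g^Θ(t) is the telegraph state filtered by a
boxcar of width Θ. Its autocorrelation is computed by numeric double
quadrature of the joint occupation probability (relative tolerance
1e-8, the |u−v| kink split at u = v), valid for λ ≠ μ. For the
symmetric chain the spectrum has the closed form

    S_g(ω) = 2γ(1 − cos Θω) / (Θ²ω²(4γ² + ω²)),

with S_g(0) = 1/(4γ). Conventions fixed here once, by calibration
against the simulation oracle and pinned by a regression test:

* The closed form is a two-sided density in angular frequency. The
  one-sided density in f that a Welch estimator measures on sliding-g
  data is `ONE_SIDED_SCALE` (= 2) times the closed form at ω = 2πf.
* The (1 − cos) factor has exact nulls at f = k/Θ; pointwise comparison
  with estimated spectra is meaningless there. Comparisons therefore
  use the mean of the exact form over each analysis band
  (`sg_theta_band_mean`, dense trapezoid — adaptive quadrature
  misjudges this oscillatory integrand), or the smooth envelope with
  (1 − cos) → 1 (`sg_theta_envelope`), which is the local band average
  only for f ≥ 1/Θ and diverges below; it is never used under that
  limit.
* Sliding-window traces use stride = dt by default (a continuous
  slide); coarser strides alias the occupancy spectrum and are offered
  for speed only.
* For asymmetric chains the same boxcar-filter route applied to the
  telegraph autocovariance g(1−g)e^{−(λ+μ)|s|} gives
  S_g(ω) = [2g(1−g)r/(r²+ω²)]·[2(1−cos Θω)/(Θω)²], r = λ+μ, which
  reduces exactly to the symmetric form and is cross-checked against
  the double-quadrature autocorrelation in the tests.

## State extraction

A two-state Gaussian HMM (hmmlearn) is initialized from a two-cluster
split of the amplitude histogram, fitted by EM on the standardized
trace (raw currents are nA-scale; without standardization EM
covariance floors swamp the emission variance), and decoded by the
most-probable-path (Viterbi) algorithm. Posterior per-sample decoding
is deliberately not used: isolated single-sample flips would fragment
the dwell statistics. The trap-occupied state maps to the lower
current level by default (depletion-mode convention; configurable).

Fitted levels closer than 3 emission sigmas are rejected as "no
two-level structure" — this threshold separates genuine RTS
(separation ≥ 4σ in the regimes studied here) from unimodal noise,
where a forced 2-Gaussian split lands near 2.7σ. Boundary dwells are
censored (their true length is unknown) and dropped, standard
single-channel-kinetics practice; dwell estimates with ≤ 200
transitions carry a warning, the count below which occupancy estimates
become statistically unreliable.

## Signal-to-noise analysis

S/N = δV_Th / √(∫_{f1}^{f2} S df) for both readouts, with S = S_VG
(voltage readout) or S = S_gg = S_g/g_g² (occupancy readout). The
reference signal is the ideal Nernstian ISFET response
ln(10)·kT/q·ΔpH = 5.9 mV for 0.1 pH at 298 K.

The integration band defaults to 0.1–100 Hz. The band must extend
below the smallest analysed corner frequency for the occupancy
estimator's averaging benefit to register: with f1 = 1 Hz the S/N
versus corner frequency is non-monotone near f₀ ≈ 1–3 Hz because the
band then clips the plateau region where slow and fast traps differ
most, while 0.1 Hz (= 1/Θ for the 10 s reference window) restores the
expected monotone rise. The upper edge brackets the 10 Hz reporting
frequency used throughout. S/N integrals use the exact oscillatory
spectrum below 1/Θ and its envelope above (in log-frequency, for
conditioning); both choices are validated against each other in tests.

A caution on the 10 Hz reporting point: S_gg(10 Hz) as a function of
corner frequency peaks at f₀ = 10 Hz (the density at a fixed frequency
is maximal when the corner sits on it), so "occupancy noise falls with
rising corner frequency" holds only for f₀ above the reporting
frequency; the sweep tests assert it on f₀ ∈ [20, 1000] Hz.

## Synthetic data and the reference scenario

`compose_trace` builds I(t) = baseline ∓ ΔI·X(t) + g_m·v_DP(t) + white
noise, with ΔI = g_m·q*/(C_G·A) and v_DP synthesized 1/f noise at the
device's DP level. The 1/f synthesizer works in the frequency domain
(amplitudes ∝ f^(−1/2), independent uniform phases, conjugate
symmetry) for exact spectral control at O(N log N); its low-frequency
cutoff defaults to 1/duration, below which the spectrum is held flat.

The reference scenario (`fixtures`) emulates a 100 nm × 100 nm
liquid-gated Si nanowire FET: C_G·A = 7.1e-17 F — the capacitance at
which the calculated DP noise is 1.4e-8 V²/Hz at 10 Hz — tgδ = 3.8e-3,
g_m = 1 µS, N_ot = 1e8 cm⁻², and a trap switching symmetrically at
γ = 488 s⁻¹ with α = 0.5. The fixture trap carries an effective charge
of 3q rather than 0.5q: with the single-charge amplitude, the
gate-referred step (1.1 mV) would be buried in the device's own
full-band DP background (~1.3 mV rms), whereas measured nanoscale-FET
RTS is cleanly resolved — channel-current percolation around the
trapped charge is known to enhance RTS amplitudes well beyond the
uniform charge-sheet estimate. The enhanced value reproduces that
observed amplitude-to-background ratio. All analytic noise formulas
keep q* = 0.5q.

What the generator does not emulate: multi-trap traces and inter-trap
Coulomb correlation, electrochemical drift and other low-frequency
instabilities, anomalous or three-level RTS, amplitude drift, and any
frequency dependence of tgδ. Passing tests therefore demonstrate
correctness of the kinetic, spectral and S/N machinery under the
stated stationary two-level model — not robustness to drifting or
multi-trap measured data.

## Problem sizes and numerical tolerances

Simulation-backed checks run at desk scale, chosen to keep Monte-Carlo
error comfortably inside each assertion: the occupancy-spectrum oracle
uses 30 × 200 s traces at dt = 50 µs (Welch, Hann, 50% overlap, 50 s
segments; the lowest two Fourier bins are excluded from plateau
estimates because per-segment mean removal attenuates them); HMM
recovery uses ten 4 s replicates at dt = 20 µs with ΔI/σ = 4
(~2000 transitions each). Dwell-time K-S tests run on ~10⁴ dwells at
the 1% level. Logistic fits use least squares with the midpoint seeded
by interpolation at g = 1/2; Lorentzian + 1/f spectral fits run in
log-log space on log-rebinned spectra (otherwise dense high-frequency
bins dominate) with positivity enforced by fitting log-parameters.
All stochastic operations take an explicit integer seed; identical
seeds give identical output.
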