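# Methods

## The phasegram pipeline

A uniformly sampled scalar signal x[i] (rate f_S) is analysed in sliding
windows [x[i−m] … x[i+m]] whose centres advance by round(f_S · hop_s).
Per window:

**Embedding.** Delay embedding plots (x[j], x[j+n]); the delay n is, by
default, the first zero crossing of the signal's autocorrelation function
(linearly interpolated, rounded to the nearer lag), computed **once on the
full signal** so the portrait axes stay comparable across windows. When
the ACF has no zero within the search bound the estimator falls back to
the first strict local minimum of the lagged mutual information
(histogram estimate, 16 bins). A Hilbert embedding (real vs imaginary
part of the analytic signal) is available for signals with variable
cycles or no clear fundamental. For two synchronized observables (the
vocal-fold model's left and right displacement) the portrait is simply
the two-channel plane.

**Sections.** The Poincaré section is the line through the origin at
angle θ ∈ [0, π). For each trajectory segment whose perpendicular
coordinate s = −u sinθ + v cosθ changes sign, the crossing is placed by
linear interpolation and stored as the signed coordinate along
(cosθ, sinθ). Points exactly on the line attach to the following segment,
so a tangent touch counts once. Both crossing directions are kept and
binned together.

**Histograms and colour.** Crossing positions are binned on a uniform
grid symmetric about zero with one bin centred at 0 (bin width 0.005 by
default for signals normalized to [−1, 1]; the useful range is roughly
0.001–0.01). All windows share one grid; if a crossing falls outside the
grid the grid is extended, never truncated. Colour intensity is linear,
col[k] = h[k]/hist_max with hist_max the global maximum bin count, so
intensities are comparable across the whole image. (An alternative
log-compression is available for display only.)

**Angle selection.** The default section is horizontal (θ = 0), which
suits origin-crossing oscillatory signals. The automatic mode evaluates a
grid of 40 candidate angles over [0, π) on up to 10 portraits sampled
across the signal and picks the angle maximizing the mean Shannon entropy
of the crossing histogram — sections that spread crossings over many bins
reveal more attractor structure than sections that collapse them. Ties
resolve to the smallest angle. This objective is this package's own
formalization of "choose the section that reveals the attractor";
published figures produced with other selection rules (e.g. an angle of
0.375 π for the vocal-fold model) are reproduced here by passing the
angle explicitly.

## Reading regimes off the phasegram

Per column, contiguous runs of bins with intensity ≥ 0.05 merge into one
"line" at their intensity-weighted centroid. Column labels follow the
line count: 0–1 static, 2 periodic, 2n subharmonic(n) (4 = period
doubling, 6 = tripling, …), odd counts irregular. Equal-label columns
merge into segments; segments shorter than 0.1 s are absorbed into their
longer neighbour.

Stability has two roles and two definitions:

* **Demotion to irregular** uses *local* stability: the fraction of
  adjacent column pairs whose lines persist (same count, each line moving
  ≤ one bin). Segments of nominally periodic/subharmonic columns with
  local stability < 0.8 are relabelled irregular. Local stability keeps
  slowly drifting lines (a swept system parameter) stable while
  column-to-column jumps (chaos) are demoted — the "locally stable lines"
  reading.
* The **reported** `RegimeSegment.stability` field is global: the
  fraction of columns whose line positions stay within one bin of the
  segment median. For stationary regimes the two agree; for swept
  parameters the global value is low even for clean limit cycles, which
  is informative in itself.

Bifurcation events are the segment boundaries. The bifurcation diagram
plots each column's line positions against a control parameter
interpolated to the column time, split into rising/falling branches at
the control's global maximum; hysteresis is flagged where the two
branches' dominant labels differ over the same control interval.

## Synthetic reference systems

**Logistic sweep.** x[i+1] = a_i x[i](1−x[i]) iterated once per sample at
1000 Hz, a linear in sample index (default 3.4 → 3.65 over 10 s),
starting from x0 = 0.5 with no transient removed. The orbit is
mean-centred, scaled to peak 1, then sinc-upsampled to 44.1 kHz
(Hann-windowed sinc kernel, half-width 32 input samples; band-limited
interpolation may overshoot ±1 slightly between original samples). The
upsampling turns the sample-alternating orbit into smooth limit cycles so
delay portraits become closed curves. Known effect: during the sweep the
observed period-doubling appears *later* than the static bifurcation
parameter, because the orbit tracks the weakly unstable previous cycle
until its deviation grows out of the numerical floor (dynamic bifurcation
delay). This is a property of the swept system, not of the pipeline; on
stationary plateaus and step changes the classifier recovers change
points within one hop.

**Lorenz sweep.** Explicit-Euler difference equations of the Lorenz
system (σ = 10, b = 8/3) at dt = 1/882 s, r linear from 250 to 28 over
the first 308 700 steps then held for 132 300 steps; the 441 001-sample
train (initial state + one per step) is replayed at 44 100 Hz, i.e. 50×
faster than simulated, giving a 10 s audio-rate signal. A finer-step
integration serves as the test oracle; Euler at this step is the product,
matching the difference-equation formulation. For the chaotic r = 28
regime the autocorrelation zero sits at the slow lobe-switching scale
(several orbital periods), so analyses of Lorenz-like signals should
bound the delay search (`max_delay_s` ≈ 5 ms at playback rate puts the
delay near a quarter orbital period).

**Phase-randomized surrogates.** rFFT magnitudes are kept; phases of the
positive-frequency bins are drawn uniformly on [0, 2π) from a seeded
generator; DC and Nyquist keep zero phase so the inverse transform is
exactly real. The amplitude spectrum is preserved to rounding error while
deterministic phase structure (e.g. the logistic map's exact parabolic
successor map) is destroyed.

**Two-mass vocal-fold model.** Each fold is a lower (0.125 g) and upper
(0.025 g) mass on springs (k1 = 0.08, k2 = 0.008, coupling kc = 0.025, in
g/ms² units), damping ratios 0.1 / 0.6, driven by Bernoulli pressure on
the lower masses while the glottis is open and convergent:
P1 = Ps [1 − Θ(a_min)(a_min/a1)²] Θ(a1), force P1·l·d1 with fold length
l = 1.4 cm and lower-mass thickness d1 = 0.25 cm. Glottal areas are
a_i = a0_i + l(x_il + x_ir) with rest areas 0.05 cm²; a closed area adds
collision stiffness 3k_i acting on a_i/(2l). Asymmetry Q scales the left
fold (masses /Q, stiffnesses ×Q), lowering its eigenfrequency by Q — the
standard model of unilateral laryngeal asymmetry. Integration is explicit
Euler at dt = 0.05 ms (20 kHz); all four masses start displaced 0.01 cm
because the rest position is an exact equilibrium. Internal units are g,
cm, ms (1 pressure unit = 100 kPa); the API takes kPa and seconds.

Phonation thresholds: the oscillation envelope is the rolling 25 ms
peak-to-peak of each lower-mass trace (insensitive to the slow
pressure-driven equilibrium shift); the threshold is 5% of the envelope's
maximum over the run, and "sustained" means held for ≥ 50 ms. Onset is
the start of the first sustained run (rising ramp), offset the end of the
last (falling ramp), both read off the pressure profile. The default
protocol is a symmetric triangular ramp 0 → 2.5 → 0 kPa over 10 s.

## Known limitations

* **Two-mass threshold pressures.** This implementation's asymmetric
  (Q = 0.51) model oscillates from ≈0.37 kPa on the rising ramp and down
  to ≈0.21 kPa on the falling ramp (onset > offset, i.e. the hysteretic
  direction holds). Published threshold values for this configuration are
  substantially higher (≈1.1–1.2 kPa). An exact linear-stability analysis
  of the implemented equations confirms the low threshold is intrinsic to
  this transcription of the model and not a numerical artifact; the
  regime structure above ≈1.2 kPa (1:1 locking, then subharmonic locking
  from ≈1.6 kPa) does match published behavior. Reported thresholds are
  also protocol-dependent for subcritical oscillators: they are what the
  stated ramp and amplitude criterion produce, not universal constants.
* The synthetic generators are noise-free and perfectly stationary per
  window; real signals add measurement noise ("noisy" portraits), drift
  (use the zero-phase high-pass, cutoff 1–2 Hz) and amplitude modulation.
  Passing tests on the synthetic suite shows the geometry, counting and
  labelling machinery is correct — not that classification is robust at
  low signal-to-noise ratio.
* The mutual-information delay estimator is ill-conditioned on *exactly*
  noiseless periodic signals (binning artifacts make the MI-lag curve
  jagged); with any realistic noise it recovers T/4 for a sinusoid.
* Sections are anchored at the origin and transversality is not
  verified; signals that do not cross zero need DC removal (done by
  default) or detrending before the portrait is meaningful.
* Embeddings are two-dimensional by design; attractors needing higher
  embedding dimension fold over themselves, which the phasegram shows as
  apparent irregularity. No quantitative chaos measures (correlation
  dimension, Lyapunov exponents) are computed.

## Test and acceptance problem sizes

The test suite runs the full 10 s / 44.1 kHz logistic sweep and the full
10 s / 20 kHz two-mass simulation once each (session fixtures); Lorenz
properties use the stationary tail (3 s) and a 2 s decay run; property
tests (crossing conservation, rotation covariance, surrogate spectra) use
seeded random portraits of ≤ 200 points. The acceptance script runs the
complete logistic sweep and two-mass protocols from scratch.
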