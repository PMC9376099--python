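# Methods

This note documents the models, conventions, and numerical choices
behind `wavepipe`, in the order the pipeline applies them, and states
what the synthetic tests do and do not establish about real data.

## Signal model and the synthetic generator

The generator (`wavepipe.synth`) emulates a 64-channel surface grid
(11 rows × 6 columns, 0.5 mm pitch; 66 sites in the full lattice) and
32-channel laminar probes (25 µm spacing). Its planar-wave model is

  x(p, t) = A · env(t) · cos(2π f t − φ(p) + φ₀ + ξ_trial) + σ · n(t),

with φ(p) = (2π/λ)(d̂ · p) for propagation direction d̂ (a unit vector),
spatial wavelength λ (mm/cycle) and temporal frequency f (Hz). The
trial-to-trial jitter ξ enters the initial phase only — wavelength and
direction are fixed across trials, matching the tight cross-trial
phase-offset distributions such waves show. A spatially varying local
wavelength can be supplied as λ(s); the spatial phase is then the
integral of 2π/λ(s) along the propagation axis, and the generator emits
the per-site local λ as ground truth.

Defaults are the study conditions used throughout the tests: 100 trials,
SNR 10 dB, fast wave 12.7 mm / 40 Hz with a 350 ms burst, slow wave
12.5 mm / 4.5 Hz with a 900 ms burst, epochs from −0.4 to +1.0 s at
1 kHz. The envelope is a raised-cosine burst with a 10 ms rise,
matching the brief-flash stimulation regime; the evoked-response shape
is otherwise a free parameter of the generator, not an empirical claim.
SNR is defined as the ratio of the strongest wave's plateau RMS to the
noise SD, with background noise spectrally shaped to 1/f (exponent
configurable), the generic spectrum of brain signals.

The coupled-oscillation generator emits a slow carrier whose
instantaneous frequency wanders slowly around the band center
(fractional SD 0.1, low-passed at 0.5 Hz, clipped to the band) and a
fast carrier whose envelope is exactly
baseline·(1 + depth·cos(θ_slow − θ_pref)). The frequency drift is
deliberate: against a strictly periodic carrier, a circular phase shift
merely rotates the preferred phase and leaves the modulation index
unchanged, so shift surrogates would have no power. Real narrowband
rhythms drift; the generator reproduces that property. Spike trains are
inhomogeneous Poisson with intensity ∝ exp(κ·cos(θ − μ)), normalized by
its empirical time average so the expected count is exactly
baseline_rate × duration for every κ.

What the generator does *not* emulate: conduction-delay networks,
biophysical laminar structure, non-planar (radial or spiral) waves,
behavioral-state covariates, electrode drift, or line noise. Passing
the recovery tests therefore shows the estimators are correct and
well-calibrated for coherent planar waves in 1/f noise — not that every
real recording contains such waves.

## Conditioning

All filters are zero-phase (forward–backward application), so latencies
are unbiased. The broadband stage is a least-squares linear-phase FIR
low-pass at the 325 Hz edge (transition to 1.15× the edge, ~3.3·fs/Δf
taps). The nominal 0.1 Hz lower edge is realized as exact per-channel
mean subtraction: a genuine FIR transition at 0.1 Hz would need a
kernel longer than typical epochs, whereas mean removal eliminates the
DC component exactly and perturbs in-band components only at O(1/n).
Consequently, content between ~0.01 and ~0.1 Hz is *not* attenuated;
for epoch-length analyses this is immaterial.

Epochs are half-open windows [−pre, post) at sample resolution, with
time 0 at the stimulus sample. Out-of-bounds trials are dropped with a
logged warning. Automated QC replaces manual screening: channels whose
SD exceeds 8× the median channel SD (or is zero) are rejected, and
trials with any sample beyond 10× the robust (MAD-based) SD are
rejected; both thresholds are configurable stand-ins for judgment calls
that have no printed numeric rule.

The inclusion rule for a visually responsive electrode is |trial
average| > 5 pre-stimulus SDs within 100 ms of the stimulus; onset
latency is the first post-stimulus sample opening a run of ≥ 3
consecutive samples above 3 SDs.

Mean re-referencing (subtracting the across-channel mean per time
point) is provided and is the right tool against volume conduction in
real recordings. It is **off by default in the synthetic demo**: when
the wavelength (≈12.5 mm) exceeds the grid extent (2.5 × 5 mm), the
across-channel mean carries a large coherent component of the wave
itself, and removing it steepens local phase gradients, biasing
recovered wavelengths low by roughly 15% under the default conditions.
This is a property of the operator on small apertures, worth knowing
when interpreting re-referenced wavelength estimates.

## Time–frequency machinery

The Morlet CWT uses the common nondimensional center frequency ω₀ = 6
(the toolbox default this analysis style relies on; implemented via
PyWavelets' complex-Morlet family with matched Gaussian width). The
default grid is 0.1–150 Hz in 0.25 Hz steps. Band filtering by
coefficient masking zeroes all rows outside the band and inverts with
the delta-function reconstruction Σ Re W(f,t) · w(f); for an arbitrary
frequency grid the scale measure ds/s becomes df/f, giving weights
df/(f·√s). The overall constant is calibrated empirically on a unit
sinusoid at a well-resolved grid frequency (≤ fs/25, where the discrete
wavelet is densely sampled) and cached per grid. Round-trip accuracy on
band-limited signals is ~2% relative L2 over interior samples
(documented tolerance 5%); a tone at the center of a masked band is
returned at 0.8–0.9 of its amplitude because the mask truncates the
wavelet bandwidth tails — phase, which drives all downstream wave
quantities, is unaffected, and the wavelet and Butterworth routes give
wavelength estimates agreeing within 5%.

The Butterworth route uses order 6 for the fast band (30–50 Hz) and
order 3 for the slow band (3–6 Hz), SOS form, forward–backward. The
analytic signal is the frequency-domain Hilbert transform of the full
epoch; the first and last max(5% of samples, 2 cycles of the band low
edge) are excluded from downstream statistics (`edge_mask`) because
filter and Hilbert transients concentrate there. Multitaper spectra use
5 DPSS tapers at NW = 3, normalized so the spectrum integrates to the
signal variance.

## Complex SVD and wave kinematics

`A = U diag(S) V*` by LAPACK SVD; the conjugate-transpose convention is
the one under which the factorization of a complex matrix exists with
orthonormal factors, and the binding contract is the reconstruction
identity ‖A − U·S·V*‖/‖A‖ < 10⁻¹⁰. Variance fractions are sᵢ/Σs.
Temporal phase is read from the rows of V* directly, so a
positive-frequency analytic oscillation has increasing θₜ.

Mode selection considers the first 10 modes, z-scores each mode's
temporal amplitude against its own 400 ms pre-stimulus mean and SD, and
takes the argmax of the post-window mean z (window 350 ms fast /
1000 ms slow; 1500 ms is the convention for long grating stimuli). The
summary statistic is the mean (a max option exists); ties break to the
lower mode index, i.e., the larger singular value. Modes with zero
pre-stimulus variance are skipped. When no candidate reaches mean
z ≥ 2 the trial is flagged non-responsive — under stationary noise the
argmax is unstable across seeds and should not be interpreted.

The phase gradient at each electrode comes from conjugate products with
lattice neighbors along the ML and AP axes: arg(zᵢ · z̄ᵢ₊₁)/pitch.
With spatial loadings ∝ e^(−i k·p), the product with the *next*
neighbor yields +k, so the gradient points along the propagation
direction (increasing phase delay); this sign convention is validated
against generator waves of known direction. Interior sites circularly
average the two one-sided estimates; edges keep the single available
one; a missing neighbor leaves that component NaN (never zero). Row
index increases toward −AP, so the row-axis estimate is negated to
express the AP component in stereotaxic coordinates.

Wavelength is 2π/‖∇θₛ‖ per site; temporal frequency is the
least-squares slope of the unwrapped θₜ over the post-stimulus window
with analytic-signal edge samples excluded; velocity is |fₜ|/‖∇θₛ‖.
Sites with ‖∇θₛ‖ below 10⁻¹² rad/mm report NaN (undefined, not
infinite). All of these are invariant under the SVD gauge freedom
U → e^{iφ}U, V → e^{−iφ}V (property-tested). Cross-trial gradient maps
project each trial's per-site direction onto the unit circle and report
the circular mean with 1 − circular variance as consistency.

Under the default study conditions (100 trials, SNR 10 dB) the chain
recovers wavelength and velocity within ~1.5% (tolerance 5%) and
direction within a fraction of a degree (tolerance 10°) for both bands,
and separates superposed opposing waves by ~180° of mean gradient
direction.

## Laminar CSD

CSD(z) = −[φ(z+2Δz) − 2φ(z) + φ(z−2Δz)]/(2Δz)², evaluated after
extending the potential profile by two duplicated end channels
(Vaknin-style boundary estimation), so the output has one CSD trace per
input channel. The five-point span makes the quadratic-profile result
exactly −2a and leaves linear profiles at exactly zero; closed-form
phantoms (`generate_laminar_phantom`) exercise both plus the sin(kz)
transfer identity sin²(kΔz)/Δz².

Layer assignment offers two schemes. The granular-referenced scheme
finds the channel with the earliest post-stimulus sink — CSD below −3
pre-stimulus SDs for ≥ 3 consecutive samples, the same run-length logic
as the LFP latency rule, ties to the shallower channel — and labels it
granular (layer 4), with supra/infragranular above/below. The
depth-banded scheme locates the cortical surface as the first channel
whose evoked-CSD RMS exceeds 10% of the probe maximum (channels above
it have "converged to zero") and bands the first 350 µm as superficial
and the next 400 µm as deep. The −3 SD sink threshold and the 10% RMS
criterion are documented stand-ins; no printed numeric rule exists for
either.

## Coupling statistics

The phase axis is cut into 20 equal bins on (−π, π], left-open /
right-closed. For PAC, the mean fast-band amplitude per slow-phase bin
is computed per trial over the first 900 ms post-stimulus, averaged
across trials, then normalized; MI = Σ pⱼ log(pⱼ/(1/20)) / log 20, so
MI ∈ [0, 1] with 0 for uniform and 1 for a single-bin delta. Bins empty
in one trial are skipped in the cross-trial average; bins empty in all
trials trigger a pooled-sample fallback (logged). The preferred phase
is reported both as the maximal bin center (default) and as the
distribution-weighted circular mean; the latter is the lower-variance
estimator at realistic spike counts since the max-bin estimate is
quantized to the 0.314 rad bin width.

SFC applies the identical construction to spike counts per field-phase
bin (canonically the 3–6 Hz phase of the CSD at the unit's own channel;
intersite SFC is the same code path with the other region's field).
Zero spikes in the window make the statistic undefined (an error), not
zero.

Significance uses the three matched surrogate constructions: ITPC —
re-epoching at random stimulus times (uniform over the valid range,
consecutive surrogate stimuli at least one epoch apart via the
sorted-uniform-plus-gaps construction); MI — circular shifts of the
phase series relative to the amplitude, independently per trial, with
shifts kept at least 5% of the series length from zero so no surrogate
nearly reproduces the original alignment; SFC — Poisson trains
simulated from the unit's own rate estimated in a 200 ms boxcar slid
sample-by-sample, which preserves slow rate modulation but destroys
phase locking. Each observed statistic is z-scored against 100
surrogates; a zero surrogate SD yields a flagged NaN rather than an
infinite z. Pooled across the three null families, the empirical
|z| ≥ 1.96 rate is ~3–6% over 200 runs, inside the 2.5–8.5% calibration
band.

Cross-correlograms histogram pairwise delays (other − reference) with
lag bins centered on integer multiples of the bin width (zero lag is a
bin center) and are normalized to firing probability per reference
spike. Recovered peak lags are therefore quantized to the bin width
(5 ms default).

## Spatial statistics and inference

Electrode registration is a rigid map fitted from the two laminar-probe
anchor sites known in both the grid-local and stereotaxic frames: the
rotation angle is the angle between the inter-anchor vectors, and the
translation pins the first anchor. Distances are preserved to 10⁻⁹
(property-tested); the second anchor maps exactly when the two frames
agree on the inter-anchor distance, as a rigid map requires.

Query-grid averaging pools per-electrode values from multiple animals
onto a fixed lattice (ML −3.5…0, AP −5…0, 0.5 mm spacing) with a
truncated Gaussian kernel, W(d) = (σ√2π)⁻¹ exp(−d²/2σ²) for d ≤ 0.3 mm
and 0 beyond, σ = 0.15 mm, renormalized over contributing electrodes.
Circular quantities average as weighted resultant vectors. Queries with
no electrode in support are NaN. (The kernel is stated in one published
account with a positive, unsquared exponent; that form is not a
Gaussian and diverges with distance, so the standard Gaussian is
implemented.)

The Rayleigh test uses Z = nR² with the standard finite-n series
correction; it matches a 5000-draw Monte Carlo null within 0.02 at
n = 30 and an independent reference implementation to 10⁻⁴. Stouffer
combination is Σz/√k; Bonferroni thresholds are α/m over spatial
locations — for the default query grid's 8 × ~10.5 ≈ 84 locations,
0.05/84 ≈ 0.0006.

## Problem sizes and determinism

Test and acceptance problem sizes are chosen as the smallest that make
each property statistically decisive: recovery runs use the full
100-trial, 66-channel study condition (a few seconds each); null
calibrations use 200 runs of 30 s signals at 250 Hz; spike tests use
10–20 spikes/s over 30–500 s depending on the estimator's variance.
Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); fixed seeds give bit-identical ensembles,
surrogate draws, and pipeline output checksums.

## Known limitations

- Gradient estimation assumes a locally planar wave on a complete
  rectangular lattice; optical-flow or phase-latency methods for
  non-planar fields are out of scope.
- The windowed ITPC extracts one phase per window from the band-center
  DFT component under a Hann taper; for the slow band a 450 ms window
  holds under two cycles, so that phase is a windowed estimate, not a
  cycle-resolved one. The convention is isolated in one function.
- The inverse CWT is approximate (delta reconstruction); amplitude after
  narrow-band masking is systematically ~15% low. Use the Butterworth
  route when absolute band amplitude matters.
- Mean re-referencing distorts wavelength estimates when the aperture is
  much smaller than the wavelength (see Conditioning).
- CSD assumes uniform conductivity and spacing; inverse methods (iCSD,
  kCSD) are not implemented.
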