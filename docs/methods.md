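# Methods

`bas` models a single-particle fluorescence burst experiment end to
end: membrane-labelled liposome populations in free solution, their
first-order fission into smaller vesicles, the photon-count traces an
instrument would record, and the analysis chain that turns traces back
into size/concentration distributions, kinetics and FCS diffusion
times. This note records the model, the defaults and the design
choices, and what the synthetic data do and do not capture.

## Liposome populations

A population is a mixture of species, each a truncated-normal diameter
distribution parameterized by its mean (nm) and coefficient of
variation (CV). The location and scale of the underlying normal are
solved numerically so that the *post-truncation* mean and CV equal the
requested values; with plain truncation at zero the sample CV would run
~1% low at CV = 0.35 and several percent low at CV = 0.5. Extruded
liposome standards are modelled at 35% CV (extrusion specifications say
±25%, measured dispersions run 35–50%), fission products at 30% CV.

Membrane labels distribute over the bilayer, so particle brightness is
proportional to surface area: `brightness = label_density * pi * d^2`.
All headline intensity scalings (4-fold for 200 vs 100 nm, 16-fold for
200 vs 50 nm, ~100-fold for 200 vs 20 nm) follow from this single
assumption. `label_density` also serves as a brightness multiplier for
modelling multilamellar contaminants; there is no deeper photophysics
(no bleaching, blinking or triplet states).

## Fission model

A fraction `1 - exp(-k t)` of parents converts after time `t` (rate
constant `k`, s⁻¹). Two product mechanisms bracket the unknown true
one:

- **direct** — a converted parent of diameter D becomes products near
  the product mean diameter Dp; at the species level the product
  concentration is `converted * E[D^2]/E[Dp^2]`, conserving total
  membrane area exactly (exactly 100 products for monodisperse
  200 → 20 nm). The per-particle path draws product diameters until the
  parent's area is spent, discarding at most one product's area.
- **cascade** — repeated area-halving steps (D → D/√2 per daughter);
  the number of steps a particle has taken after time `t` is
  Poisson(k t), truncated at the generation reaching the product size.
  Intermediate generations populate a broad band of medium sizes.

Label partitioning at fission is unbiased by default
(`partition_bias = 0`), so total brightness (concentration × mean
brightness) is invariant through `evolve_fission`; the bias knob exists
only as a diagnostic.

The kinetics presets use k = 0.05 min⁻¹ for the 23 °C scenario and
twice that at 37 °C. These are scenario parameters chosen so the
smallest products plateau near 60 and 30 minutes respectively; they are
not measured constants.

## Trace simulation

Burst mode models a stage-scanned confocal acquisition: particle
transits arrive as a Poisson process with rate
`detection_rate_constant × concentration`, each depositing a Gaussian
packet of expected counts (temporal sigma = transit_time/2) whose peak
rate is `brightness_scale × brightness × exp(-2 b²/w₀²)`, with the
impact parameter `b` uniform on [0, 1.5 w₀]. Photon noise is Poisson
per bin over a Poisson background. Overlapping transits sum in the
trace but stay separate rows in the ground-truth table, so coincidence
errors are measurable. A warning is raised above the single-particle
limit (~500 pM).

Defaults (chosen once, recorded here): bin width 0.1 ms, duration 60 s,
background 1000 counts/s, transit time 0.5 ms,
detection_rate_constant 0.05 bursts s⁻¹ pM⁻¹, brightness_scale
8000 counts s⁻¹ per brightness unit, κ = 5, w₀ = 300 nm, T = 296 K,
η = 0.93 mPa·s. The flux calibration and transit time were set so that
at the 500 pM single-particle limit the coincidence dead-time loss is a
few percent — the regime in which burst counting is linear in
concentration, as the assay requires. Several analyses (kinetics,
dilution merging) use a 4× higher flux calibration and longer traces
purely for counting statistics; those sizes are stated where used.

The beam-attenuation factor spans exp(-4.5) ≈ 0.011–1, so detected
amplitudes of a monodisperse species spread over ~2 decades. This is a
deliberately simple stand-in for the real (poorly known) instrument
point-spread function; no deconvolution is attempted.

## Burst detection

Background is estimated by iterative sigma-clipping (3σ, integer-aware
for sparse backgrounds) followed by a truncated-Poisson debias; sigma
is the Poisson value √(mean counts/bin). Detection thresholds at
`background + k_sigma · sigma`, elevated to the matched Poisson
quantile when the per-bin background is far below the Gaussian regime —
at the default 0.1 counts/bin a literal 5σ rule would trigger on
ordinary shot noise many times a minute, while the matched quantile
keeps the false-positive rate below one burst per minute. Runs of
strictly-above-threshold bins at least `min_bins` long (default 2),
merged across gaps of at most `gap_bins` (default 1), become events.

The integration window is then padded by one transit time per side so
that dim-burst wings below threshold still contribute to the amplitude
(without padding, amplitudes of the dimmest products lose up to ~20%).
Where padded windows of distinct bursts would overlap, they are split
at the midpoint: padding must not extend the coincidence dead window.
Amplitude is the background-subtracted integrated count; the peak bin
is retained for QC. Raising `k_sigma` cannot increase the count of
isolated bursts; a coincident double-peaked event can legitimately
split in two at a higher threshold.

## BAS histograms and the dilution series

Burst amplitudes are binned on log-spaced edges (24 bins/decade).
`C_i = (events in bin i)/(detection_rate_constant × duration)` gives pM
as measured in the cuvette; the dilution factor is metadata. A single
acquisition is quantitative only in a window; a bin is *valid* when

1. it holds ≥ 5 events;
2. its intensity is within ~100-fold of the brightest well-populated
   (≥ 20 events) bin — the instrument's per-measurement dynamic range;
3. the cumulative measured concentration from the brightest bin down
   has not yet reached the 500 pM single-particle limit;
4. expected coincidence events in the bin are < 20% of its observed
   events. This pile-up estimate is a pairwise self-convolution of the
   event histogram with coincidence window 2 × transit_time, ignoring
   pairs whose smaller member adds < 25% (those barely move the larger
   event). It catches the fake-event tail that a high concentration of
   small products deposits a few-fold above its own peak — the
   "resolution deteriorates for low-intensity events" regime that
   motivates measuring dilution series in the first place.

`merge_dilution_series` rescales each histogram to undiluted
concentrations, anchors the least-dilute histogram, and brings each
more-dilute histogram on with a least-squares scale factor fitted on
the complementary cumulative concentration over overlap bins that are
well populated (≥ 20 events) and pile-up-clean *on both sides*; when no
such bins exist the calibrated dilution factor is trusted (scale 1).
Fitting the scale on contaminated overlap was the single largest error
source in development: the crossover region between a rare bright
species and an abundant dim one is exactly where pile-up fakes live.
Merged totals still run ~10% low against ground truth because the
~100-fold window clips the dimmest beam-attenuated tail; the acceptance
band for merged recoveries (15%) reflects that known truncation.

## CV inference

`estimate_cv` matches the observed burst-intensity distribution against
Monte Carlo templates (diameters from the truncated normal at each grid
CV, intensity ∝ d²) by the Kolmogorov–Smirnov statistic on
median-normalized intensities. The KS distance is binning-insensitive
and the median normalization makes the match scale-free, which matters
because burst amplitudes are in counts while templates are in
brightness units. A consequence is that the template shape depends only
on CV, so the mean diameter is not identified by the shape match; it is
derived from the data median when an intensity-per-area calibration is
supplied (and snapped to a grid if given), and reported as NaN
otherwise. Grid-boundary optima raise a warning. With ≥ 10⁴ events the
estimator separates neighbouring 5% grid points cleanly (the KS
distance at the true CV is ~5–10× smaller than at ±5%).

## Kinetics

Heat-map rows are fractional fluorescence per bin,
`I_i C_i / Σ_n I_n C_n`, so each row sums to 1; `total_signal_series`
is `Σ I_i C_i` per time normalized to the series maximum — near 1
throughout for a lossless reaction. The smallest-product window
defaults to bins whose mean intensity is at most 2× the modal
(most-concentrated) bin of the final histogram.

`time_to_plateau` returns the first time the windowed concentration
crosses `frac` (default 0.95) of its final value, by linear
interpolation. The plateau reference is the last sample, so time grids
should extend to ~5/k; the presets and tests sample 8 points over
[0, 5/k] for every rate constant, which makes static measurement
distortions (coincidence loss, window truncation) cancel exactly in
plateau-time *ratios* between rate constants. Near the plateau the
crossing slope is shallow, so the estimate amplifies counting noise by
~18×; the simulated time courses therefore use a few ×10⁴ events per
time point to keep the ratio uncertainty in the few-percent range.

## FCS

`autocorrelate` implements a multi-tau estimator (16 linear lags per
octave, factor-2 coarsening) of G(τ) = ⟨δF δF⟩/⟨F⟩²; per-lag sigmas
come from splitting the trace into 8 blocks. `fit_diffusion` fits the
standard single-component 3D Gaussian-volume model
`G0 (1+τ/τ_D)⁻¹ (1+τ/(κ²τ_D))^{-1/2}` with κ fixed (default 5; a
single curve barely constrains it). The fit is unweighted by default:
on traces of a few hundred diffusion times the block sigma estimates
are noisy enough to bias τ_D low by ~10%, which the unweighted fit
avoids. Polydisperse samples yield a single "average" τ_D by design.

The FCS simulator places the number of particles implied by the
concentration in a periodic box (half-widths 3 w₀ laterally, 3 κw₀
axially), moves them by Stokes–Einstein Brownian steps and integrates
a 3D Gaussian detection profile; G(0) ≈ 1/(C·π^{3/2} w₀² z₀) and
τ_D = w₀²/4D emerge rather than being imposed. Fitted τ_D for the
slowest species (200 nm, τ_D ≈ 10 ms) runs a few percent low on 12 s
traces — a finite-measurement effect that shrinks with duration.
Setting viscosity to infinity freezes the field (shot noise only),
which is the immobile-limit check.

## What the synthetic data do not capture

No photophysics, no multilamellar populations beyond a brightness
multiplier, no instrument drift between acquisitions, no detector dead
time or afterpulsing, no surface-hydrophobicity correction for FCS
radii, and a one-parameter beam-attenuation stand-in for the real PSF.
Tests passing on these simulations validate the *analysis chain*
(detection, histogramming, merging, inference) against known ground
truth under the stated noise model; they do not validate the noise
model itself against a real instrument.

## Problem sizes and determinism

Every simulation takes an explicit integer seed and is bit-reproducible
under it. The test suite and the reproduction script use trace
durations of 4–20 minutes of simulated acquisition per measurement —
sized so Monte-Carlo error on each ratio-type result sits several-fold
below the band being checked — and complete in minutes on one CPU.
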