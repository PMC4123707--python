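# Methods

This note documents the model and procedures implemented in `numtex`, the
choices made where the design was genuinely open, and what the synthetic
stimuli do and do not establish about real displays.

## Stimulus model

**Dot displays.** A stimulus is a dimensionless contrast image (background 0,
clipped to [−1, 1]) with a pixel pitch of 1.25 arcmin/px.  Each dot is a 2-D
Gaussian

    c(x, y) = A(s) · exp(−((x − m_x)² + (y − m_y)²) / (2 s²)),
    A(s)    = 0.4 · (2 / s) · contrast_scale,

rendered analytically over a ±4 s window.  The 1/s amplitude law makes the
dot's contrast energy A² π s² independent of blur (±1%, verified against the
analytic integral), while peak contrast falls from 0.4 at s = 2 px to 0.133
at s = 6 px.  Polarity (white/black) is an independent fair coin per dot.

**Polygons and placement.** The bounding "notional polygon" is star-shaped:
5–12 vertices at sorted random angles, radii uniform in [0.5, 1]·R, rescaled
isotropically to the target area (50,000 px² for the standard; exact by
construction, tested to ±2% by a shoelace oracle).  Dots are placed by
rejection sampling, uniform within the polygon subject to a minimum
centre-to-centre distance of

    exclusion = min(4 · s_max, 0.6 · sqrt(area / n)).

The 4·s_max term keeps dots essentially non-overlapping wherever geometry
allows; the cap at 60% of the mean spacing is needed because the dense
conditions (e.g. a density-varying test with 128 dots at s = 6 px) would
otherwise demand a packing beyond the ~0.55 jamming limit of random
sequential placement.  The aperture experiment uses a fixed 10 px exclusion
so dots never touch.

**Trial pairs.** The standard has 64 dots; the test has round(64(1 ± W))
with W on the 5%-step grid (0.05–1.00; W = 1 never occurs with negative
sign, which would leave an empty stimulus).  Conditions: *density-varies*
(test area = standard area), *size-varies* (test area scaled so density
matches), *equal blur* (s = 2 both), *unequal blur* (one blur per stimulus,
each uniform on [2, 6] px), and the *kitchen sink* design (each element's
blur independently uniform on [2, 6] px; test and standard areas
independently scaled uniform on [1, 2] × 50,000 px²; optional independent
contrast scales uniform on [0.13, 1]; the test always the more numerous).
Each stimulus is rendered on its own canvas: polygon bounding box plus dot
supports plus a 33 px pad, which covers the 3 s dot margin and the
half-support of the largest analysis kernel.

**Other stimulus classes.**  Blob textures: white pixel noise of fixed
contrast convolved with a balanced difference-of-Gaussians
(centre:surround = 1:1.6); increasing the centre scale genuinely removes
contrast energy (the input, not the output, has fixed contrast).
Thresholding sets pixels within 1 s.d. of the mean to the mean; blobs are
8-connected components of the survivors (verified against a flood-fill
oracle, and the count decreases with blur scale as neighbouring blobs
coalesce).  Mixed textures: 64 + x elements (x uniform on 0–21, defeating
total-count strategies) of two interleaved classes differing only in
polarity, spatial frequency (×2, DoG micropatterns of scale 2 vs 4 px),
contrast (×2), phase (90°), orientation (90°, even Gabors with σ = 3 px and
0.125 c/px carrier) or size (×2).  The micropattern parameterizations are
our own: only the ×2 / 90° class relations are constrained.

## Filters and energy

Channels are zero-DC, unit-L2 kernels; "energy" is the sum of squared
responses over the `valid` convolution region, so padding never contributes.
The isotropic channels are centre-positive Laplacians of Gaussians at
σ = 2 px (high SF) and σ = 8 px (low SF, two octaves apart).  The unit-L2
normalization is our convention — the quantity the observers compare is
invariant to any fixed rescaling, and the blur-normalization step absorbs
convention differences in the energy–blur relation.  Oriented channels are
even-symmetric second derivatives of an elongated Gaussian (aspect 2);
rotating the image by 90° exchanges the two channel energies.  Half-wave
rectification splits a response into on/off energies that sum exactly to the
full energy.  The CSF observer weights the stimulus spectrum by
g(f) = (f/f₀)·exp(1 − f/f₀) with peak sensitivity at f₀ = 3 c/deg
(configurable; the classic band-pass shape, Parseval-equivalent to spatial
filtering).

## Blur estimation and normalization

The model observer estimates blur directly from the image: it selects the 5
dots with the most distant nearest neighbours, takes horizontal and vertical
profiles through each centre, pre-smooths with a 0.5 px Gaussian, forms the
discrete second derivative, and locates by linear interpolation the two zero
crossings flanking the central zero-bounded region.  For a Gaussian of
standard deviation s the crossings sit at ±s, so the estimate is half the
crossing separation (with the pre-smoothing variance subtracted); the
convention is pinned by an analytic/numerical oracle in the tests.  The
per-stimulus estimate is the median over sampled dots, reported in arcmin.

Calibration renders single-dot stimuli at 9 blur levels spanning
2.5–7.5 arcmin and fits log(mean E) = a·ŝ² + b·ŝ + c by least squares
against the *estimated* blur ŝ, so any small estimator bias cancels at
normalization time.  For the σ = 2 px channel the fit gives a ≈ 0.009,
b ≈ −0.63 arcmin⁻¹ (residual RMS < 0.05): energy falls ~14-fold over the
stimulus blur range.  Normalization divides a stimulus's energy by
exp(a ŝ² + b ŝ + c); estimates outside the calibration range ±20% are
extrapolated with a warning.

## Observers

The energy observer computes (optionally compressed, optionally
blur-normalized) channel energy for test and standard and picks the larger
as "more numerous"; exact ties are a fair coin, and no decision noise is
added — all stochasticity comes from the stimuli, so the model sees exactly
what a human trial sequence provides.  Contrast compression is

    c → sign(c) · log(1 + |c|/c₀) / log(1 + 1/c₀),

odd, monotone, fixing 0 and ±1.  The library default c₀ = 0.05 places the
knee just below the minimum element contrast; the documented calibration
grid for the kitchen-sink analysis is {5·10⁻², 10⁻², 10⁻³, 10⁻⁴, 10⁻⁶},
whose lower end is the pure-logarithm limit ("reduce the contrast range
logarithmically").  The benchmark battery screens this grid on a paired
300-trial run and reports the best member; in practice the pure-log limit
wins by a wide margin.

The mixed-texture observer uses the log energy ratio of two channels
(polarity → off/on half-wave pair; frequency and size → LoG scales 2 and
8 px; contrast → one channel's response magnitudes split at two thresholds,
25% and 75% of the observed peak; orientation → oriented pair 90° apart),
comparing each trial's ratio to the running mean of the stimuli seen before
that trial (first trial: fair coin).  Phase is not modelled: the task is
impossible for human observers and the energy ratio carries no signal.

The ideal aperture observer counts visible dots without error; with B black
among N = 64 dots and n visible, the probability that the visible majority
matches the true majority is computed exactly from the hypergeometric
distribution (ties count 1/2), and its Weber fraction comes from the same
84%-correct criterion as everything else.  Sampling efficiency is the
visible count n\* at which this ideal curve matches a full-view texture
observer.

## Psychometric analysis

Responses are fitted by maximum likelihood with a two-parameter cumulative
Gaussian — P(choose test | W) = Φ((W − μ)/σ) for signed designs, or
P(correct | W) = Φ(W/σ) (μ ≡ 0) when the test is always more numerous — with
five deterministic restarts around moment-based initial values and σ bounded
to [10⁻³, 10]; a fit pinned at the lower bound flags responses perfectly
separated at the grid's resolution.  No lapse parameter is fitted (exposed
as a config only).  JND = 64 σ dots (the 84% point); Weber % = 100 σ.
Confidence intervals are parametric bootstrap: 160 simulated re-runs at the
fitted parameters and placements, refitted, central 95% (coverage verified
at 90–99% on simulated truth).  Per-point binomial CIs (Clopper–Pearson)
accompany the psychometric plots.  Trial placement is constant-stimulus
(uniform on the W grid) for all benchmark runs, removing placement as a
variable; the adaptive rule (10 uniform burn-in trials, then the grid value
nearest μ̂ ± σ̂, alternating) is provided for experiment emulation.

## Benchmark battery and problem sizes

`numtex.benchmarks.run_all_targets` regenerates everything from a single
seed: calibration (9 levels × 20 single-dot repetitions), 1000 trials per
condition for equal-blur (high- and low-SF observers yoked to the same
sequences, both area conditions), unequal-blur (raw high, raw low and
blur-normalized observers yoked), and the kitchen-sink design with and
without contrast randomization (compressed and uncompressed observers
yoked).  1000 trials put the bootstrap CI on a Weber fraction at roughly
±10% relative; the test suite runs a 400-trial version of the same battery.
These sizes are the package's choices for precise-yet-quick replication;
all of them are arguments.

## Known limitations

* The synthetic displays emulate the *statistical* structure of the
  published stimuli (counts, areas, blur and contrast distributions,
  polarity statistics), not the physical displays: no luminance calibration,
  display gamma, quantization or presentation timing.  Passing tests show
  the model pipeline behaves as specified on ideal contrast images, not that
  it predicts any particular human data set.
* The raw high-SF observer's unequal-blur and kitchen-sink Weber fractions
  are dominated by how strongly channel energy depends on blur, which
  follows from the stated amplitude law and is sensitive to the (elsewhere
  unstated) filter conventions; the blur-normalized results are robust to
  those conventions, which is precisely the argument for normalization.
* Mixed-texture micropatterns and the Experiment-3 DoG scales are
  parameterized by reasonable defaults (documented above) rather than
  published values; only their class relations (×2, 90°) are constrained.
* The MIRAGE-style blur measure implements only the zero-bounded-region
  blur code, not a full multi-scale sensor-fusion reconstruction, and
  assumes reasonably isolated dots (it medians over the most isolated five).
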