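# Methods

## The amplitude-threshold model

Each clock cycle *c* of one embryo side draws a collective oscillation
amplitude

A_c = s · exp(μ + σ Z_c),  Z_c ~ N(0, 1) i.i.d.,

and the somite boundary determined by that cycle (boundary 10 + *c*,
counting the first post-7-somite-stage wave as boundary 11) is intact iff
A_c ≥ θ. The per-cycle defect probability is therefore
Φ((ln θ − ln s − μ)/σ), which the simulator tests use as a closed-form
oracle.

Assumptions and choices:

- **Log-normal amplitudes.** The amplitude law is not dictated by data; a
  log-normal was chosen because amplitudes are positive and gene-expression
  noise is predominantly multiplicative. μ and σ are free parameters
  (defaults 0 and 0.5).
- **Multiplicative environment.** The environment factor *s* scales
  amplitude, so an unfavorable environment (s < 1) proportionally lowers
  both the count of supra-threshold cycles and the count of successful
  segmentations; an additive action could drive amplitudes negative and was
  rejected.
- **Independence.** Cycles are i.i.d. and the two body sides draw
  independently (an optional correlation `lr_rho` exists, default 0),
  reflecting the empirical finding that consecutive and left–right boundary
  phenotypes in clock mutants are uncorrelated.
- **Seeding.** One root seed spawns a child stream per embryo (and per
  side), so cohorts are bit-reproducible and the first *k* embryos do not
  change when the cohort grows.
- Neither the amplitude distribution's true shape nor the threshold's value
  is empirically identified; they are calibrated only through the defect
  fractions they imply (e.g. θ at the 45 % quantile reproduces the ~0.45
  defect fraction seen in *her7* mutant scoring).

The model deliberately does **not** simulate the her1/her7 delayed
negative-feedback oscillator itself: amplitude is drawn, not mechanistically
generated, so conclusions about oscillator dynamics are out of reach.

## Boundary statistics

Boundaries 11–30 are scored 0 (intact) / 1 (defected) / NA (unscorable).
An embryo is *defected* iff any non-NA boundary on either side in the
scored range is 1. Expressivity is the per-side defect count; NA entries
are excluded from counts and reported.

Correlations are Pearson product-moment coefficients: per side between the
lagged copies (boundaries 11–29 vs 12–30, pairwise-complete, at most 2 NA)
and per embryo between left and right (11–30). Constant vectors make r
undefined; such units are excluded from means and histograms and counted.
Histograms use 0.1-wide bins over [−1, 1], half-open with the rightmost bin
closed so r = 1 is representable. Percent changes are rounded half-up
(62.5 → 63). Two-group comparisons use the two-sided Mann–Whitney U test,
penetrance contrasts the two-sided Fisher exact test, and ≥ 3 groups
Kruskal–Wallis with a hand-implemented Dunn post hoc (rank z statistic with
tie correction, Bonferroni-adjusted); Welch/Brown–Forsythe ANOVA with
Games–Howell and normality testing are intentionally not provided.

**Finite-sample bias of the lag correlation.** The Pearson r between the
two lagged copies of an i.i.d. 20-entry series (19 pairs) is biased:
E[r] ≈ −1/(n_pairs − 1) = −1/18 ≈ −0.056, not 0. Over many simulated
cohorts the mean consecutive-boundary r concentrates at −0.055 ± 0.016 (222
sides), so a "mean within a few SE of zero" check is the wrong null for
this statistic; the tests assert the corrected expectation. The left–right
correlation pairs two independent vectors and is unbiased. Notably, an
observed mean consecutive correlation of magnitude ≈ 0.05 in real scoring
data is indistinguishable from this estimator bias under full independence.

## Kymograph amplitude extraction

Pipeline (defaults in parentheses): LOI kymograph (15-px band, mean across
the band, posterior at column 0) → determination-front trajectory at
fraction *f* (0.5, mid-PSM) of the per-frame PSM extent → 4-px-wide front
profile, band centered on the round-half-up pixel with the extra column of
an even band on the anterior side → Savitzky–Golay smoothing (window 9
frames, order 2) → linear resampling onto a 10× uniform grid → contiguous
detection windows of the approximate clock period (12 frames at 21.5 °C, 7
at 26 °C, 5-min frames) tiled from the 7-somite frame, 15 waves → within a
window, peak = largest interior strict local maximum, trough = smallest
interior strict local minimum, amplitude = peak − trough, and 0 if either
is missing (window-edge samples never count as extrema; this
operationalizes the zero rule for monotone or flat windows) → wave *k* →
boundary *k* + 10 → normalization by the mean intact-boundary amplitude of
the same experiment (so the intact-group mean is exactly 1 per experiment)
→ group comparison by medians and Mann–Whitney U.

Numerical notes:

- Windows tile contiguously from the 7-somite frame; a sliding per-wave
  alternative is not implemented. Peak and trough are sought anywhere
  within the same window regardless of temporal order.
- Window length is specified in pre-resampling frames and converted to
  resampled samples through the uniform re-gridding map.
- Detection is linear in intensity, so amplitudes are exactly equivariant
  under intensity scaling and invariant under intensity offsets.
- The Savitzky–Golay filter attenuates a sinusoid of period 12 frames by
  ≈ 8 % (window 9, order 2). The attenuation is common to all waves of an
  experiment and cancels in normalized amplitudes, but raw-amplitude
  round-trips at 12 frames/period recover planted values only to ~8 %. The
  synthetic studies therefore sample the same 60-min clock at 2.5-min
  frames (24 frames/period), where attenuation is ≈ 1 % and noiseless
  round-trips recover planted amplitudes within 2 %.

## Synthetic kymographs

Intensity is a raised-cosine traveling wave,
I(x, t) = B + A(x, t) · (1 + cos φ(x, t))/2 + ε, with linear phase
φ = 2π(vt − x)/λ (posterior at x = 0, wave moving anteriorly) and
ε ~ N(0, noise_sd²). Two deliberate choices make planted amplitudes exactly
recoverable:

- The phase origin puts the determination front at phase −π/2 at the
  7-somite frame, so in every period-long window the peak falls a quarter
  period in and the trough three quarters in — both strictly interior.
- The per-cycle amplitude index switches at the wave troughs (phase π mod
  2π), where the intensity equals the baseline from both sides. The
  noiseless signal is then C¹-continuous — a time-gated amplitude switch
  would jump mid-slope and smear through the smoothing filter — and the
  noiseless trough-to-peak range of cycle *c* at the front equals A_c
  exactly.

The generator does not model PSM growth, cell movement, wave-period
gradients along the axis, or photobleaching; a green round-trip test
establishes that the extraction chain is faithful to this idealized wave,
not that it is robust to those real-data effects.

## Synthetic cell fields and slicing

Cells are uniform in a PSM rectangle (defaults 500 × 100 µm, 2000 cells,
the scale of one imaged embryo). Counts are Poisson with rate
b + λ₀(1 + m cos(2πx/λ + η)) (λ₀ = 50, m = 0.9, λ = 200 µm giving 2–3
stripes); gene 2 gets an extra fixed phase offset Δ plus its own
independent per-cell jitter η′ ~ N(0, κ²). κ = 0, Δ = 0 emulates coherent
wild-type stripes (spatial r ≈ 1); κ = π randomizes per-cell phase and
drives r to ≈ 0, emulating mutant decorrelation.

Slicing projects each cell onto the stripe normal, p = x sin α − y cos α
(α = 90° ⇒ p = x), and takes slice = floor(p / thickness); the angle is a
single fixed config value (the mutant procedure — position-dependent
angles are not fitted) and the thickness is a required config with default
10 µm (≈ one cell diameter; the choice is not data-derived). Slice means
subtract a per-gene background and clamp at zero. The slice-center
fraction is where the slice mid-plane crosses the anteroposterior axis,
as a fraction of PSM length from the posterior; the region filter keeps
the closed interval [0.4, 0.8]. The spatial correlation is the Pearson r
of the two genes' slice-mean profiles (≥ 3 slices, undefined for constant
profiles).

## Acceptance quantities

`scripts/acceptance.py` recomputes three numbers by running the package:
the two independence-null correlation magnitudes (222 sides / 111 embryos,
i.i.d. defect probability 0.45) and the end-to-end recovered percent
difference for a planted 0.6 amplitude-median ratio (225 waves, noise
0.02). The independence simulation runs at its protocol-fixed seed because
the |mean consecutive r| bound sits exactly at the −1/18 estimator bias
(see above) and is realization-dependent; the amplitude-recovery world is
derived from the `--seed` argument.

## Known limitations

- The threshold model reproduces marginal defect statistics, not dynamics;
  it cannot speak to period, synchrony, or wave propagation.
- PSM extent is an input to front location, never segmented from images.
- The stripe angle and slice thickness are config inputs; fitting angles to
  images is out of scope.
- TIFF output quantizes to 16-bit integers; synthetic kymographs written
  to TIFF should use intensities on a scale of hundreds of counts (the
  in-memory pipeline is float throughout).
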