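# somiteclock

Quantitative analysis of variable somite-segmentation phenotypes in
zebrafish segmentation-clock mutants (*her1*, *her7*), built around a
stochastic amplitude-threshold model of the clock.

## The scientific problem

Sibling embryos carrying the same clock mutation differ widely in how many
somite boundaries they fail to form (incomplete penetrance, variable
expressivity). The working model implemented here: during each clock cycle
a group of presomitic-mesoderm (PSM) cells produces a collective
oscillation whose amplitude *A* is random,

&nbsp;&nbsp;&nbsp;&nbsp;*A* = *s* · exp(*μ* + *σZ*), *Z* ~ N(0, 1),

with *s* > 0 a multiplicative environment factor (lower at low temperature
or under hypoxia). The cycle yields an intact boundary iff *A* ≥ *θ*, an
amplitude threshold; otherwise that boundary is defected. The per-cycle
defect probability is the closed form

&nbsp;&nbsp;&nbsp;&nbsp;P(*A* < *θ*) = Φ((ln *θ* − ln *s* − *μ*)/*σ*).

Because cycles — and the left and right sides of an embryo — fail
independently, the binary phenotype series along the axis behaves like coin
flips, which the correlation statistics below test.

## What the package does

- **`somiteclock.synthetic`** — generators for the three data modalities:
  boundary-phenotype tables from the threshold model, reporter kymographs
  carrying traveling waves with planted per-cycle amplitudes, and striped
  two-gene per-cell transcript fields with tunable phase jitter.
- **`somiteclock.boundaries`** — penetrance (embryo defected iff ≥ 1
  defected boundary on either side), expressivity (defect counts per side,
  boundaries 11–30), consecutive-boundary Pearson correlation (11th–29th vs
  12th–30th), left–right correlation (11th–30th), 0.1-binned histograms,
  percent-change summaries, and rank/exact hypothesis tests.
- **`somiteclock.kymo`** — kymograph construction from a time-lapse stack
  along a line of interest (15-px band), determination-front trajectory
  (fraction *f* of PSM length from the posterior), 4-px front profile,
  Savitzky–Golay smoothing + 10× resampling, windowed trough-to-peak wave
  detection (zero amplitude when a window has no interior extremum), wave →
  boundary mapping (wave *k* → boundary *k* + 10), per-experiment
  normalization to the mean intact amplitude, and intact-vs-defected group
  comparison.
- **`somiteclock.smfish`** — fixed-angle slicing of a per-cell count field,
  background-subtracted slice means, 40–80 % posterior-PSM region filter,
  and the spatial Pearson correlation of the two genes' slice profiles.
- **`somiteclock.pipeline` / `segclock` CLI** — simulate → analyze → report
  orchestration with one root seed and byte-reproducible outputs.

## Worked example

```sh
$ python analysis/02_boundary_independence.py
222 sides: mean consecutive r = -0.0224 (SE 0.0155; the 19-pair estimator's null expectation is -1/18 = -0.056)
111 embryos: mean left-right r = -0.0182 (SE 0.0200; unbiased null expectation 0)
-> both correlations are consistent with independent per-cycle failures
temperature expressivity change (median 8 -> 13): 62.5% -> 63%
hypoxia expressivity change (mean 8.9 -> 11.5): 29.2% -> 29%
```

The first two lines simulate 111 embryos (222 sides) whose 20 boundaries
each fail independently with probability 0.45, then measure the two
correlation statistics: both means sit at their independence-null
expectations, so neighboring boundaries — and the two body sides — carry no
predictive information about each other. The percent changes apply the
expressivity-change operation to published summary statistics: cooling
raises the median defect count per side from 8 to 13 (+63 %), and chemical
hypoxia raises the mean from 8.9 to 11.5 (+29 %).

```sh
$ python analysis/03_amplitude_recovery.py
225 waves (117 intact, 108 defected)
normalized medians: intact 0.980, defected 0.602
recovered percent-less: 38.6% (planted 40%), Mann-Whitney p = 1.07e-25
```

Here 15 synthetic kymographs are planted with a defected:intact
amplitude-median ratio of 0.6 and pushed through the full extraction
pipeline; the recovered 38.6 % deficit (planted: 40 %) shows the
measurement chain is faithful end to end.

The other drivers: `analysis/01_simulate_cohorts.py` writes the synthetic
datasets (TSV/TIFF/CSV) under `results/data/`, and
`analysis/04_smfish_jitter_sweep.py` shows the spatial two-gene correlation
decaying from ≈ 1 to ≈ 0 as per-cell phase jitter grows from 0 to π.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the absolute mean consecutive-boundary
correlation over 222 simulated independent sides (t3), the absolute mean
left–right correlation over 111 simulated embryos (t4), and the
end-to-end recovered percent difference between defected- and
intact-boundary median normalized amplitudes with a planted 0.6 ratio (t5),
writing one JSON object with a `value` and problem size `n` per quantity.

## Layout

```
src/somiteclock/   library (generators, statistics, extraction, pipeline)
analysis/          numbered narrative drivers writing under results/
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    model, assumptions, numerical choices, limitations
```
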