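# Methods

## The measurement model

A session trace is modelled as

    SC(t) = L + d_r · (t − t_r)/60 + Δ(t) + Σ_i a_i · h(t − t_i) + ε(t)

where `L` is the tonic level (default 10 μS — a typical resting SCL),
`d_r` a per-run linear drift in μS/min (defaults −0.04 and −0.05,
emulating the slow downward drift from charge accumulation at dry
electrodes; drift restarts at each run because electrodes come off at the
break), `Δ(t)` a condition-coupled tonic shift active during trial
intervals (repetition shift `exposure_scl_delta`, default 0.1 μS on
second hearings; optional pleasure coupling `pleasure_scl_slope`, default
0 — the no-coupling condition), `ε` white sensor noise (sd 0.02 μS at
256 Hz), and the sum a train of phasic responses.

The SCR kernel is the bi-exponential difference

    h(t) = (e^(−t/τd) − e^(−t/τr)) / peak,   τr = 0.75 s, τd = 2.0 s,

zero at onset, normalised to a unit interior peak at
`t* = τd·τr/(τd−τr) · ln(τd/τr)` ≈ 1.16 s. Events arrive as a
homogeneous Poisson process at `scr_rate_base` (default 8 events/min,
matching the reported nSCR level of ≈4 responses per 30-s excerpt once
detection losses are accounted for) inside trials, plus
`exposure_rate_delta` on second hearings; baselines run at half the base
rate so rest is calmer than task. Amplitudes are positive-truncated
normal (0.30 ± 0.10 μS).

Ratings are integer-rounded, scale-clipped Gaussians around a linear
predictor: pleasure = 1.5 + 1.0·(familiarity bin) and arousal = 4.0 +
0.75·(familiarity bin), both with sd 2.0 before rounding; the bin is
0 / 1 / 2 for familiarity ratings 0 / 1–5 / 6–10. In the single-exposure
design the familiarity bin is drawn with probabilities 0.70 / 0.20 /
0.10 — deliberately more balanced than a purely novel-music session would
produce, because the three-level Familiarity contrasts the pipeline
computes need all bins populated per subject. In the repetition design
first hearings are novel (familiarity 0) and second hearings are
"recognized" with probability 0.3, then rated 1–5 — repeats raise
conductance without most being explicitly recognized.

Per-subject seeds are `master + subject index`; excerpt order is
counterbalanced by cyclic rotation across subjects, and in the repetition
design run 2 replays run 1's excerpts in a non-identity permutation.
`SimConfig.resampled(rate)` changes the sampling rate while scaling
`noise_sd` by `sqrt(rate_new/rate_old)`, keeping the white-noise power
spectral density — hence the noise actually inside the sub-hertz analysis
band — invariant. All Monte-Carlo tests and the acceptance script run the
design at 32 Hz on this basis; the problem sizes there (7 or 33 subjects,
2 × 35 trials, 200–1000 replicates) are the package's chosen study sizes.

## Preprocessing

Stages run in the order filter → detrend → baseline-subtract →
range-correct, each recorded in the output's provenance.

* **Low-pass filter.** 4th-order Butterworth applied forward-backward
  (zero phase, so SCR latencies are not shifted). Since two passes square
  the magnitude response, the design cutoff is pre-warped by
  `(√2 − 1)^(−1/(2·order))` so the *overall* response is −3 dB at the
  nominal 0.6 Hz. Reflection padding of ten cutoff periods removes the
  edge transient (a pure ramp passes through to ~1e−13).
* **Piecewise detrend.** Ordinary least squares per segment (default: one
  segment per run), subtracting only the slope component `b·(t − t̄)`.
  Segment means are preserved deliberately: full residualisation would
  zero every segment mean and make the subsequent baseline subtraction
  vacuous. Segments with fewer than two samples are an error.
* **Baseline subtraction.** Each run's samples are centred by the mean
  over that run's 2-min silent baseline.
* **Range correction.** `(SCL − SCLmin)/(SCLmax − SCLmin)` with the
  session-wide minimum and maximum (the subject's individual range), so
  output lies in [0, 1] with both endpoints attained. A numerically
  constant trace (range ≤ 1e−9 relative) is a typed degeneracy error
  rather than a division by zero.

The full chain is invariant under positive affine rescaling of the raw
trace — amplifier gain and offset cancel — which is the property that
makes range-corrected values comparable across subjects.

## Features

Trials are cut into epochs of `floor(duration × rate)` samples on
half-open intervals (removing the ±1-sample ambiguity). Mean SCL is the
epoch mean of the 0.6 Hz-band signal.

SCR counting is trough-to-peak: every local maximum is measured against
the minimum since the previous maximum and accepted when the rise reaches
`min_amplitude` (default 0.01 of the unit range — the classical
0.01–0.05 μS amplitude convention mapped onto the range-corrected scale)
with at least `min_inter_peak` = 1 s between accepted peaks. Two
robustness choices matter:

* **Detection band.** Counting runs on a parallel range-corrected chain
  filtered at 2 Hz (`ScrParams.detection_cutoff`) rather than on the
  0.6 Hz SCL signal: the tonic band smears responses closer than ~2 s
  into a single trough-to-peak pair. Setting `detection_cutoff=None`
  restores single-signal behaviour.
* **Search window.** The window extends `search_post` = 2 s past the
  epoch (an SCR peaks ~1.2 s after onset), and a peak is attributed to
  the epoch containing its onset trough, so responses elicited at the end
  of an excerpt are not lost to the rating gap.

`min_amplitude` remains the dominant sensitivity parameter and is fully
configurable. A structural limitation is intrinsic to trough-to-peak
scoring: two bi-exponential responses closer than ~1.4 s produce no
intervening local minimum at any filter setting, so Poisson event trains
at the default rate lose counts to merging on a minority of trials; the
acceptance script reports the measured within-one-count recovery rate on
generator trials alongside the other quantities.

## Design rules

Per-analysis trial filters: novel-music analysis keeps pleasure ≥ 0 AND
familiarity = 0; the familiarity analysis keeps pleasure ≥ 0; the
repetition analysis keeps pleasure ≥ 0 AND familiarity ≤ 5. The
familiarity exclusion uses each subject's own rating. Subjects enter the
single-exposure analyses only if every pleasure level 0–5 has ≥ 5 trials
(the variance criterion). Factors: Pleasure (levels 0–5; negative trials
are already excluded), Arousal (0–10), Run (1–2), Exposure (1–2),
Familiarity (three bins). The 11-level Arousal factor frequently leaves
empty cells; subjects missing a level are dropped listwise for that
specific ANOVA (recorded as a report warning), mirroring standard
repeated-measures practice. Cell means are never imputed. The
recognized-repeat contrast labels each excerpt by the familiarity bin of
its own second-hearing rating and compares exposures within label.

## Inference

* **RM-ANOVA.** Classical within-subject decomposition;
  `F = MS_level / MS_(subject×level)`. Greenhouse–Geisser
  `ε̂ = tr(PSP)² / ((k−1)·tr((PSP)²))` from the sample covariance `S` of
  level scores (`P` the centring projector), clipped to `[1/(k−1), 1]`;
  both the raw p and the ε̂-corrected p are always reported (the
  corrected one is conventionally primary when ε̂ < 0.75). `ε̂` carries a
  known downward finite-sample bias (mean ≈ 0.86 at n = 20, k = 4 under
  compound symmetry, approaching 1 as n grows), which makes the corrected
  test mildly conservative, never anti-conservative — the calibration
  tests assert exactly that.
* **Friedman.** Mid-rank ties with the tie-corrected statistic
  `(k−1)·Σ(R_j − n(k+1)/2)² / (Σ r² − nk(k+1)²/4)`; chi-square reference
  with k−1 df, or the exact permutation null by full enumeration of
  within-row rearrangements when the enumeration is small (≤ 3·10⁵
  assignments).
* **Wilcoxon signed-rank.** Zero differences dropped; `T` is the smaller
  rank sum; z uses the tie-corrected variance and a 0.5 continuity
  correction; exact p by enumerating the 2ⁿ sign assignments for n ≤ 15.
  Effect size `r = z/√n` with the sign of the median difference.
  Bonferroni multiplies by the family size (3 for the familiarity
  post-hocs), capped at 1.
* Two-sided tests throughout; Pearson correlations use the t-based p.

All tests error on missing cells rather than imputing, directing the
caller to explicit listwise handling.

## Determinism and artifacts

Everything downstream of a `SimConfig` is a pure function of seed and
config: rerunning with the same seed reproduces reports byte-for-byte
(provenance contains a config hash and seed, no timestamps). Every stage
reads/writes plain text (CSV trace with fixed-decimal time and
17-significant-digit conductance for exact float round-trips, TSV
ratings/features, JSON layouts/results), so any stage is independently
re-runnable from files.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis assumes: tonic
level, drift, Poisson phasic trains with a fixed kernel, condition-coupled
tonic/rate/rating shifts, integer rating scales, counterbalanced two-run
layouts. It does **not** emulate: inter-subject kernel-shape variability,
non-Poisson (bursty or habituating) SCR timing, movement artifacts above
the filter band, rating drift or anchoring effects, or any audio-driven
structure within an excerpt. Passing tests therefore demonstrate that the
pipeline recovers effects of the assumed form at realistic noise levels
and sample sizes — not that real recordings satisfy those assumptions.

## Known limitations

* No SCR deconvolution (CDA-style decomposition); counting is direct,
  with the ~1.4 s merge resolution noted above.
* The Greenhouse–Geisser correction is computed from ε̂ only; no
  Huynh–Feldt alternative.
* Ratings are conditionally independent across trials given the
  familiarity bin; no excerpt-specific taste heterogeneity.
* Between-subject factors (sex, musicianship) are out of scope.
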