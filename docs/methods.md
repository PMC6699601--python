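# Methods

## The model

`teamneuro` quantifies *team neurodynamic organization* from multichannel
EEG of a small team (typically a triad) performing a shared task. The chain
is a physical-to-informational transformation: microvolt signals become
bits of organization.

1. **Band power per second.** Each member's raw EEG is split into
   non-overlapping 1-s epochs; a tapered periodogram per epoch is summed
   into forty 1-Hz bins (1–40 Hz) per sensor. The result is a power tensor
   indexed by (member, sensor, frequency bin, second).
2. **Tertile symbolization.** Each (member, sensor, bin) power stream is
   discretized into three levels — low (−1), average (1), high (3) — at the
   33.33rd/66.67th empirical percentiles of that stream's whole-recording
   distribution.
3. **Team symbols.** The ordered member levels at a second form a team
   neurodynamic symbol, encoded base-3 (digit map −1→0, 1→1, 3→2, member 1
   most significant). For n = 3 members the state space holds 3³ = 27
   symbols. The per-second symbol sequence for one (sensor, bin) is a
   neurodynamic data stream (NDS); m members with c sensors and f bins
   yield c·f team streams and m·c·f individual streams.
4. **Neurodynamic information.** The plug-in Shannon entropy H of a 60-s
   causal sliding window over an NDS, updated each second, is inverted as
   NI(t) = log₂(S) − H(t), S the state-space size (27 team, 3 individual).
   Sustained dwelling in a few symbols — regardless of whether the
   underlying power is high or low — lowers H and raises NI.
5. **Randomized baseline.** Each member's level stream is permuted
   independently (non-missing positions only), team symbols rebuilt and NI
   recomputed, R times; the pooled 25th–75th percentile band is the null
   reference. This preserves level marginals while destroying temporal
   structure, so it sits exactly at the plug-in estimator's bias floor.

Downstream analyses: member NI decomposition (per-stream NI with S = 3,
averaged over a member's sensors/bins), lagged Pearson cross-correlation
between member NI traces (positive lag = first series leads), frequency-band
and scalp-region aggregation, ±60-s event bracketing, raw-level composition
within events, and rank-based contrasts (Mann–Whitney/Wilcoxon rank-sum,
Kruskal–Wallis).

## Assumptions

- Input EEG is already clean: re-referencing, line-noise removal, ICA and
  artifact rejection are upstream of this package.
- Members share a task clock; alignment marks absences as missing rather
  than dropping seconds.
- Power streams are analyzed marginally per (member, sensor, bin); no
  cross-channel normalization is applied. Because discretization is
  rank-based, any strictly monotone per-stream transform (log, unit
  changes) leaves all downstream results unchanged, which also makes the
  question of whether power "should" be normalized before categorization
  immaterial here.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| window | 60 | s | long enough that a 27-state window can approach uniform occupancy; short enough to resolve task events lasting tens of seconds |
| step | 1 | s | symbol rate is 1 Hz; NI reported each second |
| levels | 3 | — | low/average/high; the state space grows as kⁿ, so k > 3 rapidly outpaces a 60-symbol window |
| missing tolerance | 20% | of window | windows with more missing seconds yield missing NI instead of silently using fewer symbols |
| shuffles R | 100 | — | quartiles of the pooled null stabilize well below R = 100 for recordings of a few hundred seconds |
| max cross-correlation lag | 60 | s | one entropy window; reported lags in team coordination sit well inside this |
| band schemes | A / B | Hz | A: delta/theta 3–7, alpha 8–11, mu 12–17, low beta 18–22, high beta/gamma 23–40; B splits 23–32 / 33–40 |

Numerical conventions: tertile cuts and IQRs use linearly interpolated
percentiles; boundary ties discretize to the lower category; a constant
(degenerate) stream maps to "average" everywhere; NI is timestamped at the
window *end* (causal, usable in real time; the first window−1 seconds are
warm-up), so an organization epoch's NI elevation trails its end by up to
one window; NI is clipped to [0, log₂ S] against floating-point drift;
Hmax is always computed as log₂(S) — 4.755 bits for 27 symbols, 3.17 for
9 — never hard-coded. Entropy is the uncorrected plug-in estimate; a
Miller–Madow option exists but is off by default, since the shuffle
baseline already absorbs the bias floor. Rank-sum Z uses the tie-corrected
normal approximation (exact p below 20 samples per group); the
anterior/posterior fold change is a ratio of means; no multiple-testing
correction is applied and reports carry the count of tests performed.

## The synthetic generator

Real recordings for this kind of study are not publicly deposited, so the
generator provides ground truth: background power is exp(N(0, 1)) i.i.d.
per stream (power is positive and right-skewed; an `ar1-lognormal` option
adds latent AR(1) autocorrelation with φ = 0.6 while preserving the
marginal). Organization epochs force designated streams into one tertile
of the *theoretical* background law via inverse-CDF draws, with a
configurable per-second occupancy probability (> 1/3, i.e. above chance);
coupling replicates a leader's levels into a follower at a signed lag by
bootstrap-resampling the follower's own values within the matching
tertile; missing spans become NaN sentinels, never zeros. Defaults emulate
the study conditions: 3 members, the 9-sensor wet simulation montage
(F3/Fz/F4/C3/Cz/C4/P3/Pz/P4), forty 1-Hz bins, 800 s.

Two deliberate limitations. First, when an epoch heavily over-occupies one
tertile, the whole-recording empirical cuts shift toward it, so realized
occupancy is slightly diluted (≈80% for a 100-s full-occupancy epoch in
600–800 s); this is inherent to whole-recording tertiling, affects real
data identically, and the recovery analyses (NI-peak location, exceedance
of the shuffle envelope) are robust to it. Second, the generator makes no
claim to physiological realism: no 1/f spectral shaping beyond the AR
option, no artifacts, no volume conduction, no cross-frequency structure.
Passing tests therefore demonstrate that the *pipeline* recovers known
symbolic organization, not that real EEG contains it.

The raw-signal generator (`generate_raw_eeg`) sums band-limited sinusoids
with epoch-driven amplitude modulation plus broadband noise, and exists to
exercise the spectral stage end to end.

## Design choices where the method was open

- **Tertiles, not mean ± SD:** balanced categories maximize baseline
  entropy so NI peaks measure deviation from a common floor; an
  alternative thresholding can be supplied as frozen cuts.
- **Taper:** Hann by default. At 1-s epochs the Hann main lobe spans
  ~4 Hz, so even an on-bin sinusoid leaves ~1/6 of its power in each
  neighboring bin; the boxcar option concentrates on-bin tones exactly but
  leaks badly off-bin. Rank-based discretization downstream is indifferent
  to the common rescaling involved, so the choice mostly matters for
  visual inspection of power maps.
- **Pooled baseline quartiles** (over shuffles and seconds) by default;
  a per-second envelope is available.
- **Montage mismatch** between scenarios is resolved by intersecting
  sensor labels, never positionally.
- **Lag estimator:** Pearson at integer lags on overlapping valid pairs,
  best = max |r| with ties to the smaller |lag|. On 60-s-smoothed NI
  traces the correlation profile is a broad plateau, so the recovered lag
  jitters around the truth; with member NI from a *single* (sensor, bin)
  stream a 10-s lead is recovered within ±2 s in only ~90% of seeds,
  while averaging as few as three streams (still far below the study's
  9-sensor × 40-bin geometry) raises this to ~99%. The validation suite
  therefore uses 3-stream member NI for lag recovery.

## Problem sizes used in the validation suite

The test suite and the acceptance script run on deliberately small
configurations — single-sensor single-bin streams of 400–600 s for
epoch/lag recovery (20 seeds each), 1,000-s streams for the entropy-oracle
comparison (50 seeds), 10,000 s for marginal-uniformity checks, and the
full 3 × 10 × 40 geometry only for stream bookkeeping — chosen so each
property is measured at the smallest size where it is informative.

## Known limitations

- The plug-in entropy bias floor (~0.3–0.5 bits for S = 27, 60-s windows)
  means absolute NI values are estimator-dependent; only comparisons
  against the shuffle envelope, or between conditions with the same S and
  window, are meaningful.
- `levels_k ≠ 3` is supported in the quantile/encoding primitives but the
  orchestrated pipeline fixes k = 3.
- EDF input requires the optional `mne` dependency; EDF export is not
  provided (CSV is the interchange format).
- The statistical layer reports raw p-values by design; interpret families
  of tests accordingly.
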