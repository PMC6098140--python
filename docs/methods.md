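# Methods

## The problem and the unit of analysis

A receiver worn by each focal hen registers, once per second, which of
five aviary zones she occupies (1 wintergarden, 2 litter, 3 lower tier,
4 nestbox tier, 5 upper tier). The unit of analysis is the **hen-day**:
one hen's occupancy series over the fixed daily window [02:00:00,
17:00:00), i.e. the lit period, 54,000 one-second samples. The window is
kept half-open so that "02:00:00 through 16:59:59 inclusive" and the
54,000-sample count coincide without off-by-one bookkeeping. Day indices
are 1-based, and hen-days are labelled `henID.dayIndex` (e.g. `7.3`).

With 13 hens and seven contiguous complete days the pipeline produces 91
hen-days; this is the reference configuration for all end-to-end tests.

## Synthetic flock model

Real zone-tracking data of this kind is rarely deposited, so the
simulator is a first-class component, not a test stub. It generates the
statistical structure the analyses rely on, per hen:

* **Semi-Markov core.** While the lights are on, the hen occupies one
  zone at a time. Dwell times are log-normal with a per-zone median
  modulated by a smooth per-hen hour-of-day activity curve
  (sigma 0.45 on the log scale); the next zone is drawn from a per-hen
  5×5 destination matrix with zero diagonal. Destination mass combines
  zone attractiveness with a proximity decay along the physical axis of
  the house (zones are ordered bottom-outward), so most moves are to
  adjacent zones.
* **Hen individuality.** Each hen draws, from her archetype's documented
  ranges: a target daily transition total (dwell medians are rescaled so
  the expected lit-window visit count matches it), per-zone
  attractiveness jitter (log-normal, sigma 0.85), one extra "home-zone"
  bias (×2.5–5), an hour-of-day activity phase/amplitude, a roost zone,
  and her nest rhythm. Archetypes: `high-transitioner` (110–150
  transitions/day), `low-transitioner` (18–32), `zone5-avoider` (35–55,
  upper tier forbidden, evening wintergarden bout), `nest-cycler`
  (55–90, guaranteed oviposition rhythm of 24.0 h or 25.5 h), `uniform`
  (60–95). The default 13-hen flock assigns these archetypes to ids
  1–58 mirroring the contrasts observed in commercial flocks (two very
  active hens, one upper-tier avoider, several nest-cyclers).
* **Scheduled events.** A nest visit (25–45 min contiguous stay on the
  nestbox tier) recurs each day at an anchor time that drifts by
  (cycle − 24 h) per day; when the drifted anchor would leave the lit
  window the visit is skipped and the phase resets to the base anchor —
  the pause that lets a hen reset her laying rhythm. Zone 1 is only
  enterable while the pophole is open (10:00:00–16:45:00 by default) and
  is vacated when it closes; the avoider archetype adds an end-of-day
  wintergarden bout. Outside the lit period the hen sits on her roost
  zone, so full-day logs are emitted but the analysis window is
  unaffected.
* **Noise.** `day_noise` (default 0.25, dimensionless) scales day-to-day
  jitter: a shared log-normal multiplier on dwell medians (sd
  0.20·noise), per-zone destination-weight jitter (sd 0.25·noise), and a
  Gaussian shift of the nest anchor (sd 900 s·noise). `misread_rate`
  (default 0) substitutes a uniformly wrong zone per sample i.i.d.,
  emulating receiver zone-assignment error; temporal offset error is not
  modelled.

**Determinism.** Every hen-day has its own RNG substream derived from
(master seed, CRC-32 of the hen id, day index), so a single hen-day is
reproducible in isolation and flock runs are bit-identical under a fixed
seed.

**Calibration.** The study conditions the generator emulates are: a
flock-mean total of roughly 77 transitions/day with zone shares of
approximately 12/36/33/15/5 % (wintergarden/litter/lower/nest/upper),
and between-hen contrasts strong enough that hen-days are ~85–95 %
recoverable — the defining property of the observed data, where most
hens showed visually near-repeating daily patterns. Dwell-time sigma and
the between-hen spread parameters were fixed once to land in that
regime: day-to-day count variance in a renewal process scales with the
dwell-time coefficient of variation, so sigma 0.45 yields the tight
within-hen daily counts that real location rasters display. No
quantitative within-hen variability was available to fit, so `day_noise`
remains an explicit knob.

**What the simulator does not emulate** — and hence what passing tests
do not establish about real data: social interaction and resource
competition, within-zone position, sensor dropouts and temporal offset
error (only uniform misreads), seasonal/age trends, and the possibility
that real between-hen differences are smaller than the archetype
contrasts. Recovery rates on synthetic flocks validate the machinery,
not the field-data effect size.

## Preprocessing

`clean_log` forward-fills sensor gaps of at most 60 s with the last
registered zone (longer gaps stay missing) and, when a minimum dwell is
requested, absorbs shorter runs into the surrounding zone iteratively to
a fixpoint, which makes cleaning idempotent. The defaults are minimally
invasive (no debouncing) since the original acquisition protocol
describes none. Transition records carry entry time, origin, destination
and the completed dwell; each day opens with an origin-free record for
the zone occupied at the first covered second — an *occupancy*, not a
visit. Hen-days whose window is not fully covered after cleaning are
excluded with a logged warning.

## Features

A visit is an entry into a different zone, counted inside the window;
the opening occupancy is not a visit. This makes `total = Σ zone visits`
an exact identity (the flock-level zone-percentage columns then sum to
100 % exactly). The flock summary reports, per variable, the mean over
all hen-days, the pooled standard error (sample SD/√N over hen-days, the
convention behind a single SE per zone; a per-hen-first alternative is
available via the feature table), and the percent-of-total
(zone mean / total mean × 100). With a single hen-day the SE is NaN —
undefined and flagged, rather than a silent zero.

## LDA and stepwise selection

The classifier is the standard equal-covariance Gaussian discriminant:
pooled within-class covariance on n − C degrees of freedom, priors
proportional to class sizes (equal at 7 days/hen), posteriors from
class-conditional likelihoods normalised with log-sum-exp. Discriminant
directions come from the whitened symmetric eigenproblem of W⁻¹B. When
the pooled covariance is near-singular (condition number > 1e12) a ridge
of 1e-8 × mean diagonal is added and logged; passing `ridge=0` turns the
fallback into an explicit error.

The stepwise rule operationalises "dropped and re-entered if the model
improved by 5 % or more of variance", which does not pin down a
statistic. Here the scalar criterion is the subset's discriminatory
power tr(W⁺B) as a proportion of the full six-variable model's; a
variable is dropped while its removal costs < 5 % of that proportion
(cheapest first) and re-entered when adding one back gains ≥ 5 %
(largest gain first), iterated to stability with ties broken toward the
earlier variable in (z1…z5, total) order. The threshold is configurable;
at threshold 0 nothing is dropped. At least one variable is always
retained, so six exact duplicates collapse to a single representative.
Evaluation is resubstitution (fit on all hen-days, predict the same), as
in the reference procedure; leave-one-day-out is available but not the
default. Which variables the original data would select cannot be
reproduced without that data; the selected set is a report field.

## Banded DTW

Daily series are encoded ordinally (zone codes as numbers 1–5). The
local cost defaults to |Δzone| — the zones are ordered along the house's
physical/functional axis, so the absolute code difference approximates
locomotor displacement; a 0/1 symbolic mismatch cost is selectable since
the original metric is unstated. Steps are symmetric unit moves
(diagonal/insert/delete, each adding one local cost) with no slope
weighting and **no path-length normalisation**, because Ward clustering
consumes the raw dissimilarities.

The Sakoe–Chiba half-width is round(window_frac × longer length) with
window_frac defaulting to 0.10. For 54,000-point series that is 5,400
samples; the band is specified as a fraction, and the absolute width in
use is logged. A band narrower than the length difference of the two
series is an explicit error.

All-pairs DTW at 1 Hz over 4,095 pairs is computationally heavy, so the
pipeline default bins each series to 60 s majority zones (ties → the
zone seen earlier in the bin), giving 900-point series and a band of 90;
the full-resolution path stays available for subsets. A regression guard
checks that 60 s and 30 s binnings agree on nearest neighbours for ≥
90 % of hen-days on a seeded flock. The banded kernel is a numba-compiled
two-row dynamic program; tests pin it against an unconstrained DP and
against exhaustive warping-path enumeration on short series.

## Ward clustering and consistency scoring

Linkage follows the `ward.D` convention — the Lance–Williams recurrence
with coefficients αᵢ=(nᵢ+nₖ)/(nᵢ+nⱼ+nₖ), αⱼ=(nⱼ+nₖ)/(nᵢ+nⱼ+nₖ),
β=−nₖ/(nᵢ+nⱼ+nₖ) — applied to the dissimilarities exactly as provided,
with **no pre-squaring** (this is R's `ward.D`, not `ward.D2`; scipy's
`ward` implements the latter, which is why the linkage is authored here
and cross-checked against R's `hclust` in the tests). Feature-space
distances are unscaled Euclidean by default, mirroring the plain
`hclust` call on raw counts; z-scoring sits behind a flag. Merge ties
break on lowest height, then the lexicographically smallest pair of
cluster ids (leaves 0…N−1, merged clusters numbered in creation order),
making trees platform-reproducible. Ward's coefficients satisfy
reducibility, so merge heights are monotone non-decreasing.

Cutting k groups undoes the last k−1 merges. The consistency score of a
hen is the largest number of her days in any single group; groups may
serve several hens (two hens sharing their best group both score it),
which is flagged with a "grouped together" footnote, as is a hen whose
days scatter over three or more subgroups. The sub-cut nuance of a group
dividing further is reported as a footnote only, not scored specially. A
stricter one-to-one hen↔group metric via maximum-weight bipartite
assignment is provided as an alternative. `best_grouping` scans
k = n_hens … n_hens+2 and keeps the cut maximising the pooled count,
preferring the smallest k on ties.

## Numerical and degenerate-case choices

* Dwell draws are rounded to whole seconds with a 1 s floor.
* Destination rows gated to zero mass (e.g. pophole closed, forbidden
  zones) fall back to a uniform draw over the remaining legal zones.
* DTW distances are exact DP optima; no pruning or lower bounding.
* `cut_tree` group ids are assigned in leaf order; scoring is invariant
  to relabelling (tested).
* Posteriors are computed in log space; they sum to 1 to float accuracy.
* Empty inputs raise (`flock_summary`, `dtw_matrix`, `plot_location`);
  a one-observation class is a fit-time error for LDA.

## Problem sizes in the test-suite and acceptance runs

The reference flock is the full 13 hens × 7 days = 91 hen-days with DTW
at 60 s bins (matrix of 4,095 pairs, ~3 s compiled). Oracle-equivalence
suites use short random series (lengths ≤ 16 against the brute DP,
≤ 8 against path enumeration) and random dissimilarity matrices of up to
12 observations against a set-based re-agglomeration oracle. Noise-grid
and identical-flock comparisons rerun the full flock a handful of times;
the complete suite runs in well under a minute after numba compilation.

## Known limitations

* The stepwise criterion is one defensible reading of an ambiguous
  verbal rule; selected variable sets can differ under other readings
  (e.g. Wilks' Λ shares or accuracy-based selection).
* The published overall percentages are reproduced here as arithmetic on
  the published per-hen counts; end-to-end reproduction on the original
  tracking data is impossible without that data, and synthetic-flock
  consistencies depend on the generator's calibration.
* `ward.D` on non-Euclidean dissimilarities (the DTW matrix) is a
  heuristic, as in the original analysis: merge heights are not
  within-cluster variance increments in any embedding.
* The simulator draws each day independently given the day-level jitter;
  it does not model multi-day autocorrelation beyond the nest-cycle
  drift.
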