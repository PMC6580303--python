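# Methods

## Record streams and inclusion rules

The package operates on three delimited-text streams: live-stranding
records (date, sex, age class, cause label, alive-at-recovery), daily or
weekly detection series per species, and a shark-incident log in the
style of public shark-attack files. Cause of stranding is taken as a
given label; no bite forensics are performed.

Before any demographic or seasonal inference, pup (<6 months) strandings
are excluded unconditionally and geriatric (>10 years) strandings are
excluded unless shark-attributed, because both demographics strand for
reasons of their own. Records are grouped into consecutive triennial
bins (default start 1997, width 3 years); records preceding the start
year are excluded with an explicit report entry, never silently.
Records of unknown sex are retained in totals but dropped from
sex-stratified analyses, with a report entry per record.

Incident logs are filtered to rows that simultaneously match a species
label, a region, unprovoked and injurious flags, and a year range
(defaults: white shark, California, 1997–2018). The filter is a pure
predicate — order-preserving and idempotent.

The published 1997–2017 otter tally ships with the package as a pair of
constants (cells and per-bin totals). In four bins the published shark
cells do not sum to the published shark total; `tally_consistency_report`
surfaces exactly these discrepancies and the package never reconciles
them silently. The per-bin "proportion shark bitten" is implemented as
the quotient shark/non-shark (matching every printed value, e.g.
4/12 = 0.33); the alternative fraction shark/(shark+non-shark) is also
emitted, clearly labelled.

## Phenology

Event phenologies are kernel density estimates on the 366-day calendar
circle, evaluated on a 1-day grid and normalised to unit mass. The
kernel is a wrapped Gaussian, implemented by replicating each event at
multiples of ±366 days — enough copies that 4σ of kernel mass is always
represented — and renormalising on [1, 366]. Circularity matters because
winter strandings straddle the new year; a linear-domain smoother would
leak mass off the calendar edges.

Bandwidth is configurable; `"auto"` applies Silverman's rule to the
unwrapped sample, floored at 3 days (below that, a 1-day grid
under-resolves the kernel). Detection series enter as count weights on
their day-of-year, making the density invariant to the overall count
scale; stranding and incident phenologies use unweighted event dates.
CDFs accumulate density from a stated origin day, wrapping once; peaks
are grid argmaxes with ties broken toward the earliest day; lags between
two phenologies are circular differences mapped to (−183, +183].

## Demographic tests

χ² tests of independence use the classic formula Σ(|O−E|−c)²/E with the
Yates continuity constant c = 0.5 for 2×2 tables by default (c = 0 on
request; plain Pearson for larger tables). The Yates default anchors the
dialect: the published male maturity-by-cause statistic (6.92 on the
summed cells [[58, 67], [28, 71]]) is reproduced exactly only with the
correction. P-values come from the χ² distribution on (r−1)(c−1) df. No
multiple-testing correction is applied anywhere; p-values are raw.

Wilcoxon comparisons implement both the rank-sum (statistic: the
first-sample Mann–Whitney count, the convention of R's `wilcox.test`)
and the paired signed-rank (zero differences discarded). With combined
n ≤ 12 (or ≤ 12 nonzero pairs) the two-sided p-value is exact, by full
enumeration over the actual midrank multiset — i.e. conditional on ties;
otherwise a tie-corrected normal approximation with continuity
correction is used, and the mode is always reported.

Male bias in a stratum is the male proportion; its sampling uncertainty
is quantified by a nonparametric bootstrap (default 1,000 replicates)
that resamples individual records with replacement either pooled across
the stratum or within triennial bins with bin-size weighting (the
default). The summary is the replicate median and the central 95%
percentile interval. Both groupings are exposed because they answer
slightly different questions: pooled resampling reproduces the published
adult medians (0.78 shark-bitten vs 0.42 other causes); for immatures
the median across per-bin point estimates is also informative and is
available via `observed_bias_by_bin`.

## Seasonal-window inference

The core procedure asks whether the season of shark-attributed
strandings has expanded and advanced. Within each bin, each of
`n_replicates` bootstrap replicates (default 1,000) draws n_b records
with replacement and replaces every drawn date d with a truncated-normal
perturbation d* ~ N(d, σ_b) bounded to d ± 365 days, applied on the
continuous date axis so the new year is no barrier.

The scale σ_b = max(sd_floor, MAD_b / scale(n_b)) is fitted to the bin:

* **MAD_b** is the *seasonal* median absolute deviation — each date is
  reduced to its signed circular day-of-year deviation from the bin's
  circular mean day, and the MAD is taken of those deviations. A naive
  MAD of raw dates in a multi-year bin is dominated by which calendar
  year a record falls in (deviations of ±365 days and more), not by its
  season; it would inflate σ far beyond the seasonal spread the
  perturbation is meant to represent and destroy parameter recovery.
  The circular deviation also avoids inflation for seasons straddling
  the new year.
* **scale(n)** defaults to √n (selectable: n, or 1), so well-sampled
  bins stay tightly constrained to their observed dates while sparse
  bins are smoothed more.
* **sd_floor** defaults to 1 day; it also covers the single-record case
  where the MAD is undefined.
* Truncation at ±365 days keeps the distribution proper and local; with
  typical σ of a few days the bounds are effectively never hit.

Per replicate, the core season is the central-coverage interval (default
80%: the 10th–90th percentile span, type-7 interpolation) of the
adjusted day-of-year sample, unwrapped onto a linear axis from a
configurable origin (default day 1; days before the origin shift forward
one year). Bin summaries take medians of replicate endpoints; lengths
are reported in days and mean Gregorian months (30.44 days). Bins with
fewer than two records are flagged low-confidence.

The trend is an OLS regression of replicate median day-of-year on bin
index, reported as days per bin-step (3 years under default binning),
with R², p, and the total advance |slope| × (n_bins − 1). Replicate-level
regression (one point per replicate per bin) is the default; a bin-level
variant (one point per bin) is provided because with seven bins it
yields an honest slope standard error — replicate-level points within a
bin share the same observed data, so the replicate-level standard error
understates sampling variability.

## Synthetic data: what it emulates, and what it does not

Shark-cause stranding dates are wrapped-normal on the 366-day circle
with per-bin centre and σ = width80/(2 × 1.2816), so the central 80% of
draws spans the configured window; other-cause dates are uniform over
the bin's calendar span (the neutral null of no seasonality for
non-shark causes). Cell counts are generated exactly. Detection series
are Poisson counts around a raised-cosine arrival/peak/departure curve
(shark, daily) and a circular-Gaussian census bump (seal, weekly).
Incident logs mix fully valid rows with distractors violating at least
one inclusion criterion each, flags attached. A JSON sidecar records the
true window endpoints, stratum male biases, and implied centre-trend
slope.

`published_scale_config` reproduces the scale of the 1997–2017 record:
431 records in seven triennia with the published cell layout. Where the
published shark cells conflict with the published totals, the totals are
taken as authoritative and redistributed over the cells by largest
remainder; season centres advance linearly (default −13.73 days/bin from
day 250) and window widths grow 60 → 240 days (~2 → ~8 months).

The generator draws dates independently across records and years: it has
no spatial structure, no effort variation, no reporting lags, no
covariance between demographic composition and date. Passing recovery
tests therefore demonstrates estimator correctness under the stated
seasonal laws, not robustness to those real-data complications.

## Problem sizes and numerical choices in the recovery tests

The window-recovery check uses 2,000 records per bin. This isolates the
estimator's error from raw sampling noise: the sampling standard
deviation of a sample 80%-range for a 240-day-wide window is ≈30 days at
n = 50 and shrinks with 1/√n, so only around n ≈ 2,000 does estimator
error dominate a 15-day tolerance. Windows in that check are centred
mid-year (day 183) so that even the widest window's tails stay inside
the calendar year — an asymmetrically wrapped tail biases linear-axis
medians. The trend-recovery check uses constant 90-day windows, n = 50
per bin and 1,000 replicates, with the slope judged against the
bin-level OLS standard error for the reason given above.

Other fixed choices: quantiles are type-7 (linear interpolation)
throughout; density grids are 1-day (matching the daily cadence of the
sources); stage-level random streams are derived by hashing the stage
name with the master seed, so adding a stage never shifts another
stage's stream; degenerate inputs (single-record bins, identical dates,
zero-count series, empty bins) follow the explicit rules above rather
than erroring where a defined answer exists.

## Known limitations

* The perturbation scheme is a smoothing device, not a posterior:
  nothing is learned about phenology parameters beyond the replicate
  distributions themselves.
* Linear-axis core intervals depend on the origin when a season truly
  spans the new year; the circular seasonal MAD is immune, but interval
  endpoints are calendar-bound by design.
* The Wilcoxon exact path enumerates up to 2¹² sign assignments /
  C(12, k) subsets; beyond that the normal approximation is used even
  though moderately small samples might warrant exactness.
* Detection phenologies assume one pooled site; multi-site stratification
  and effort correction are out of scope.
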