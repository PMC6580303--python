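# strandphen

Phenology, demographic risk, and seasonal-window inference for wildlife
stranding surveillance records — built around the California sea otter
(*Enhydra lutris nereus*) live-stranding record and the white shark
(*Carcharodon carcharias*) bites that increasingly appear in it.

White sharks do not eat sea otters (or humans); bites on both are
mistargeted, non-trophic interactions that cluster in the season when
sharks transition back to coastal habitat, *before* their focused fall
foraging on elephant seals. `strandphen` turns the surveillance streams
around that phenomenon into reproducible statistics:

* **Phenology** — wrapped (circular) Gaussian kernel densities of events
  over day-of-year, their CDFs, peaks, and circular lags, for stranding
  dates, tag-detection series, and filtered shark-incident logs.
* **Demographics** — contingency tables over sex × maturity × cause with
  Yates-corrected χ² tests, exact/approximate Wilcoxon comparisons, and a
  within-stratum bootstrap of the male proportion ("male bias") with
  percentile confidence intervals.
* **Seasonal expansion** — the core inference: per-triennium bootstrap in
  which every resampled stranding date is perturbed by a truncated normal
  whose scale is the bin's seasonal median absolute deviation (MAD)
  shrunk by sample size (σ = MAD/√n by default), the central-80% "core
  season" of each replicate, and an OLS trend of replicate median dates
  across bins.
* **Synthetic data** — a generator with known ground truth (per-bin
  seasonal windows, demographic composition, detection pulses, incident
  distractors) so every estimator is testable end-to-end.

## The model in brief

Stranding dates in bin *b* are treated as draws from a seasonal law on
the 366-day circle. Within each of `n = 1000` bootstrap replicates the
observed dates are resampled with replacement and each drawn date *d*
is replaced by

> *d\** ∼ Normal(*d*, σ_b) truncated to *d* ± 365,  σ_b = max(1 day, MAD_b/√n_b),

where MAD_b is the seasonal MAD of the bin's observed dates. The core
season is the interval [q₀.₁, q₀.₉] of each replicate's day-of-year
sample; bin summaries are medians of replicate endpoints, and the
long-term signal is the OLS slope of replicate median dates on bin index
(days per 3-year step; negative slope = seasonal advance).

## Worked example

Run the pipeline on a synthetic dataset generated at the scale of the
published 1997–2017 otter stranding record (431 live strandings in seven
triennia, seasonal windows widening from 60 to 240 days and centres
advancing 13.73 days per bin):

```
$ strandphen run --seed 1 --out demo_run
$ strandphen report demo_run
records: 431 total, 431 after exclusions
per-bin shark/non-shark quotients:
  1997-1999: 0.33
  2000-2002: 0.13
  2003-2005: 0.15
  2006-2008: 0.12
  2009-2011: 0.59
  2012-2014: 0.67
  2015-2017: 0.67
male bias immature_other: median 0.49 (95% CI 0.404-0.568)
male bias immature_shark: median 0.51 (95% CI 0.377-0.642)
male bias mature_other: median 0.42 (95% CI 0.344-0.494)
male bias mature_shark: median 0.81 (95% CI 0.708-0.889)
season 1997-1999: days 227-259 (1.1 months)
season 2000-2002: days 181-259 (2.6 months)
...
season 2012-2014: days 50-266 (7.1 months)
season 2015-2017: days 73-261 (6.2 months)
trend: -12.38 days/bin (total advance 74 days, R^2 0.471)
```

Reading the output: the quotient column is shark-attributed over
non-shark-attributed strandings per triennium (0.33 → 0.67: shark trauma
makes up a growing share of the record); mature shark-bitten strandings
are strongly male-biased (median 0.81) while other causes are not
(0.42); the estimated core season widens from about 1 month to 6–7
months and its median date advances by roughly 12 days per triennium.
`strandphen simulate` writes the raw synthetic CSV streams plus a
ground-truth sidecar, and `strandphen run --config run.yaml` accepts
file inputs and column mappings for real data.

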