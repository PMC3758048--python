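# Methods

## Data model

A normalized price report is one black-market transaction observation:
drug (eight oral/sublingual opioids: hydromorphone, buprenorphine,
oxymorphone, methadone, oxycodone, hydrocodone, morphine, tramadol, via
an extensible synonym registry), unit strength in mg, unit count, total
price in US$, and the derived price per milligram of active ingredient
`total / (units × mg)`. Three source dialects feed this schema:

* **crowdsourced** — anonymous website submissions carrying a
  formulation, a 1–5 price rating (endpoints mean "cheap" and
  "overpriced"), a hashed submitter IP, a submission timestamp, a source
  attribution (personal / "someone who isn't me" / internet), and a
  bulk-purchase flag (>10 units);
* **law_enforcement** — quarterly officer-survey rows reporting the
  price of the most common dosage strength encountered; unit quantity is
  assumed 1 and the transaction is dated at mid-quarter;
* **marketplace** — anonymous-marketplace listings priced in Bitcoin,
  converted at the daily weighted-average USD/BTC rate *of the posting
  day* — a missing rate for a date is a per-row rejection, never
  interpolated, and the table is interpreted as US$ per BTC (≈$11/BTC in
  October 2012).

Monetary values are rounded half-to-even at 4 decimals internally and 2
decimals for display, so cent-level arithmetic is reproducible across
platforms. Rows whose mandatory fields cannot be parsed (unknown drug,
missing price or date, missing exchange rate) are emitted to a rejects
stream with a reason; parsed + rejected always equals the input row
count.

## Credibility filters

Rules run in a fixed order — eligibility (date window, country,
marketplace ship-origin), completeness (dose strength present;
optionally formulation for crowdsourced rows), outlier ratings,
near-duplicate collapse, optional bulk exclusion — and each records its
removal count. Design choices where the underlying procedure was
ambiguous:

* **Outlier ratings.** Only crowdsourced reports *identified* by users
  as rating 1 or 5 are removed; unrated reports pass. The excluded set
  is configurable.
* **Deduplication.** Within each (IP token, drug) group ordered by
  submission time, a report is removed when it falls strictly less than
  10 s (configurable) after the most recently *retained* report of the
  group — a sliding anchor. The earliest report of a burst is always
  kept (it is the original entry); chains like 0 s/6 s/12 s therefore
  keep {0, 12}. This generalizes the pairwise ("dyad") description to
  longer bursts and is verified against a subset-enumeration oracle.
* **Window date.** The eligibility window is evaluated on the submission
  timestamp where available (falling back to the transaction date); a
  `window_on="transaction"` switch flips this.
* **Bulk purchases** are flagged, not excluded, by default; exclusion is
  a config switch.
* Reports attributed to "internet" sources are retained; no attribution
  rule is applied.

For rules with pairwise-independent predicates, permuting the rule order
changes only the audit attribution, never the final kept set, provided
deduplication runs last (dedup decisions depend on which neighbors
survive earlier rules); a property test asserts this.

## Estimation

Per (drug, source) cell the summary is the geometric mean of per-mg
prices with a 95% CI on the log scale using the Student-t quantile —
the standard interval for strongly right-skewed positive prices, exact
for the median of a log-normal law. A percentile-bootstrap CI is a config
alternative. Cells with one report carry a point estimate and an
explicitly undefined CI; zero-price reports (free sharing) are excluded
with an audit count because only prices actually paid are analyzed.
Multiple unit strengths of a drug are pooled after per-mg conversion.

## Cross-source validation

Agreement between sources is Spearman's ρ on the vectors of per-drug
geometric means shared by a source pair (Pearson correlation of average
ranks; the untied closed form 1 − 6Σd²/(n(n²−1)) otherwise), requiring
at least 3 shared drugs. With only ~8 drugs per comparison, the
two-sided p-value is computed by exhaustive enumeration of all n! rank
arrangements for n ≤ 10 (the observed arrangement guarantees p > 0);
larger n falls back to the t approximation t = ρ√((n−2)/(1−ρ²)). Note
that at n = 8 and ρ = 0.9286 the exact two-tailed p is 90/40320 ≈
0.0022, about 2.6× the t-approximation's 8.6×10⁻⁴ — exact inference is
the package's default precisely because the asymptotic formula is
anti-conservative at this sample size.

Per-drug price differences across sources use a heteroscedastic one-way
(Welch) ANOVA on log prices (via `pingouin.welch_anova`), chosen for
robustness to the very unequal group sizes and variances of the three
streams; with two groups it reduces to the squared Welch t statistic.
No multiple-testing correction is applied across drugs (each drug is a
separate substantive question); a Bonferroni switch would be a trivial
wrapper and is deliberately left to the caller.

## Predicted relative potency

A drug's mean price per mg divided by morphine's is its street-implied
("predicted") relative potency. Prices can also be re-expressed per
morphine-milligram-equivalent by dividing by the clinical equianalgesic
factor (VA/DoD 2012 guideline, shipped as an editable CSV: hydromorphone
4, oxymorphone 3, methadone 1.5, oxycodone 2, hydrocodone 1, morphine 1,
tramadol 0.3; buprenorphine has no factor there and is excluded from
comparisons). The ratio's CI is a nonparametric bootstrap of the
log-ratio: the two report groups are resampled independently (2000
resamples by default, percentile interval, fixed seed). Naive interval
arithmetic on the two per-drug CIs would be wrong (it ignores the
numerator/denominator sampling split) and demonstrably cannot reproduce
published ratio CIs, so the bootstrap is the package's documented
choice. The comparison label is read off the CI: `indistinguishable` if
it contains the clinical factor, `valued_higher`/`valued_lower` if it
lies entirely above/below. Ratios print at 1 decimal (CI bounds below
0.5 at 2 decimals). Routes of administration and time-release mechanisms
are ignored, and outputs carry a "should not be used for clinical
conversion" caveat.

## Synthetic data generator

Each (drug, source) cell draws n per-mg prices log-normally around a
true geometric mean. The default parameterization takes the published
2012 benchmark table as ground truth: the printed per-cell geometric
means and report counts, with the per-cell log-SD back-solved from the
printed CI half-width by inverting the log-t interval
(s = ln(hi/lo)/2 · √n / t₀.₉₇₅,ₙ₋₁). The true dispersion of real
submissions is unknown beyond those intervals, so the back-solved values
are an approximation and are labeled as such.

Crowdsourced cells are contaminated to emulate the live data stream:

* **outliers** (default 25% — the share of submissions the original
  stream saw rated at the extremes): price multiplied or divided by a
  Uniform(4, 10) factor with equal probability, and the rating set to
  the matching extreme (5 = overpriced, 1 = cheap). The coupling of
  extreme prices to extreme ratings mirrors the premise of the rating
  filter and is configurable to probe filter robustness;
* **duplicates** (default 2%): clones with the same IP token and drug,
  offset 5 s — inside the 10 s window;
* **missing strength** (default 3%), **non-US submissions** (default
  2%), **unrated share among non-outliers** (default 20%), and **bulk
  flags** (default 10%, the positively-indicated share reported for the
  original stream). The duplicate/missing/foreign/unrated fractions are
  not reported anywhere for the real data; the defaults are modest rates
  a submission stream of this kind would plausibly show, set once.

Removal of every contaminant class is independent of the clean price
draw, so filtering leaves the retained sample an i.i.d. log-normal
sample: recovered geometric means are unbiased for the cell truth and
the log-t CI keeps nominal coverage. The recovery study
(`recovery_study`) verifies exactly this, running generate → filter →
summarize over replicates and reporting per-cell relative bias and
empirical CI coverage; at 200 replicates bias on cells with n ≥ 40 stays
well under 2% and mean coverage within a point of 95%. Nominal cell
sizes are pre-filter counts, so retained crowdsourced cells run ~25–30%
smaller than nominal.

Each cell uses its own RNG stream keyed by (seed, CRC32 of
"drug|source"), so adding a cell never perturbs another cell's draws and
a fixed seed reproduces output bitwise. What the generator does *not*
emulate: price trends over time, geographic price variation, submitter
history/addiction-stage effects, counterfeit listings, and any coupling
between rating behavior and region or drug — so passing recovery tests
demonstrate estimator correctness under the stated noise model, not
robustness to every real-world artifact.

## Pipeline and determinism

`run_pipeline` chains ingest → filter → estimate → cross-validate →
potency and writes CSV/JSON artifacts plus a filter audit and a
run-metadata file (SHA-256 of the analysis-relevant config, seed,
library versions). The only stochastic step downstream of ingestion is
the bootstrap, seeded from the config, so identical config + inputs
reproduce every artifact byte for byte. Stage errors (missing files,
invalid alpha, absent reference drug) raise before any artifact is
written.

## Problem sizes used in the shipped checks

The recovery study in the test suite and acceptance script uses the full
24-cell benchmark parameterization (1,838 nominal reports per replicate)
at 200 replicates — enough to bound per-cell relative bias below 2% with
Monte-Carlo error ≈0.9% and to estimate mean coverage with SE ≈0.4
points. Per-cell coverage is additionally checked against an
exact-binomial 99.9% band around 0.95, which controls the family-wise
false-alarm rate across the 13 cells tested at ~1%. Exact permutation
p-values are cross-checked by exhaustive enumeration at n ≤ 6 (≤720
arrangements) where an independent closed-form enumerator is cheap.
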