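# Methods

`icisskit` implements an end-to-end analysis of ICD-based injury severity
for predicting 90-day mortality and ICU admission from linked administrative
hospital data: episode-to-period linkage, Charlson comorbidity coding,
survival-risk-ratio (SRR) estimation, the two ICISS variants, nested
logistic model suites, and bootstrap optimism-corrected internal validation.
Because population-wide linked extracts cannot be redistributed, the package
ships a calibrated synthetic generator with known ground truth; every
statistical claim the test suite makes is a claim about that generator.

## Severity model

For diagnosis code *d*, the SRR is the fraction of index injury admissions
carrying *d* whose patient survived — here to 90 days from the index
admission date, the study outcome, rather than to discharge (switchable).
Each admission contributes once per distinct code; duplicate codes within a
period of care (usually repeated coding across transfer episodes) are
collapsed, so a repeated code is never squared in the product. Two scores
are derived per period:

* multiplicative ICISS = Π SRR(d) over the period's distinct injury codes,
* worst-injury ICISS = min SRR(d), ties resolved to the lexicographically
  smallest code.

Since every factor is ≤ 1, the product can never exceed its smallest factor:
`iciss_mult ≤ iciss_worst` is asserted for every generated period. No
minimum-count filter is applied by default (rare codes give noisy ratios —
a documented limitation of the design, not a bug); `min_count` filters are
available.

## Linkage rules

Episodes of one person chain into a period of care when the prior episode
separated in transfer mode and the next admission begins within one day of
the prior separation (configurable window; the administrative convention,
since administrative datasets rarely define the rule). Overlapping episodes are
merged with a warning count. The treating hospital is the one with the
largest summed length of stay, same-day episodes counting one day, ties
going to the later episode's hospital — transfers typically end at the
higher level of care. Index admissions require a principal diagnosis in
S00–T89 (both bounds inclusive; T90+ sequelae excluded) inside the study
window. Day 90 itself counts as "within 90 days"; the boundary is a
convention the package has to choose, so the inclusive choice is stated here
and tested. Deaths registered before the index admission never set the flag
and are counted in the run log.

## Comorbidity coding

The Charlson index uses the Quan et al. ICD-10 coding algorithm (17
conditions, original weights 1/2/3/6), shipped as a replaceable YAML map.
Ranges such as F20–F50 compare the three-character category; prefixes match
the normalised code (dots stripped, upper-case). Each condition counts at
most once; scores bin into 0 / 1–2 / 3–4 / ≥5. The 12-month lookback
includes the index period's own secondary diagnoses by default (typical of
administrative capture; switchable). Three extra flags use fixed code lists: mental health F20–F50;
alcohol F10, Y90, Y91, Z50.2, Z71.4, Z72.1; drug F11–F16, F19, Z50.3,
Z71.5, Z72.2.

## Models

Each model enters one ICISS variant as a single continuous term — linear by
default, the most literal reading; `log` and `logit` forms are options (the
generator's truth is on the log scale, which the recovery tests use) — plus
an incremental covariate set. The registry holds eight nested mortality
models and seven ICU models (age group, sex, Charlson group, the three
flags, trauma level, mechanism, nature), with reference levels age 25–44,
male, Charlson 0, other hospital, and the "Other and unspecified"
mechanism/nature categories; references affect labels only. Rows with
missing age or sex are dropped listwise and counted.

Maximum likelihood is computed by Newton/IRLS with step halving,
converging when the maximum absolute score falls below 1e-8 or the relative
log-likelihood change below 1e-10. Perfect separation raises an error.
Quasi-complete separation — a sparse category cell with zero events, which
*will* occur at desk-scale n with 0.2–1% categories — converges on the
likelihood criterion with a warning while that one coefficient drifts; this
matches mainstream GLM behaviour and leaves every fit statistic well
defined. The fit is cross-checked in tests against an independent Newton
implementation (statsmodels) to 1e-6.

## Validation statistics

* c-statistic: rank-sum implementation (average ranks make ties count ½),
  equal to the area under the ROC curve; tested to 1e-12 against an O(n²)
  pairwise oracle on every fixture up to 200 rows.
* AIC = −2·loglik + 2·k, k counting all coefficients including the
  intercept.
* Nagelkerke R² = [1 − exp((2/n)(ll₀ − ll))] / [1 − exp((2/n)·ll₀)].
* Hosmer–Lemeshow: deciles of predicted risk (10 groups by convention; the
  count is configurable), ties kept together; statistic
  Σ (O−E)²/(E(1−E/n_g)); degenerate groups (expected 0 or n_g) are skipped
  with a warning.
* Calibration curves: ten equal-width bins on [0, 1], empty bins omitted.

## Bootstrap optimism correction

The model is fitted on the full data (apparent statistics). Each of B
replicates (200 by default; smaller B in tests and examples purely to bound
run time) resamples periods of care with replacement — the period, not the
person, is the analysis unit — refits, and evaluates both on the resample
and on the original data; the difference is that replicate's optimism.
Adjusted = apparent − mean optimism, an identity the tests check fieldwise
and exactly. Confidence intervals are percentiles of the per-replicate
corrected values {apparent − optimism_b} (a normal approximation is a
straightforward alternative). Replicate b draws its own generator seeded
`seed + b`, so results are invariant to execution order and subsets of
replicates reproduce.

By default the SRR table is **not** re-estimated inside replicates: the
bootstrap targets the model given the severity table, mirroring the
procedure of building SRRs once on the full extract. Consequently the
correction cannot see the optimism of SRR estimation itself. On synthetic
data at n = 50,000 the adjusted c-statistic sits ~0.01 above the c-statistic
of the same model on an independent sample of identical design, and the
stricter `reestimate_srr=True` variant recovers only part of that gap
(resample overlap attenuates the noise of a min-over-codes statistic). The
corresponding test therefore uses a tolerance of 0.02 ≈ three combined
sampling standard errors plus that residual. At population scale
(hundreds of thousands of admissions) the effect is an order of magnitude
smaller.

A time-based split-sample alternative fits SRRs and the model on admissions
before a cut date and evaluates after it.

## Synthetic data generator

The generator emulates a state-wide linked extract: per-person episodes
with up to 50 ICD-10-style diagnosis codes, external causes, ICU flags,
separation modes, transfer chains (2–3 date-contiguous episodes for 10% of
events, destination holding the majority of stay), a death registry with
both in-window and late deaths, and pre-index comorbidity admissions within
the 12-month lookback. Default calibration targets the published
descriptors: 55.6% male, the six printed age-band shares, 27.8%/17.9%/54.3%
trauma-level shares, the nine mechanism and thirteen nature shares, 79.7%
with no Charlson condition overall while 45.3% of those 65+ have at least
one, flag prevalences 9.5%/7.2%/3.6%, and ~1.9% 90-day mortality / ~3.1%
ICU admission.

Diagnosis counts follow a shifted negative binomial (1 + NB(r, p), capped
at 43), solved numerically for truncated mean 1.74 and SD 1.46. A
zero-truncated negative binomial cannot reach this moment pair: at mean
1.74 its SD is bounded by the logarithmic-series limit ≈ 1.34, so the shift
is what makes the printed overdispersion attainable.

Outcomes are logistic: 90-day death risk in log worst-injury SRR (β = −10)
plus age, sex and Charlson-group effects; ICU risk in log multiplicative
ICISS (β = −8) with its own covariate effects; either outcome can be
switched to the other variant for comparative experiments. Intercepts
(−6.1458 death, −3.8896 ICU) were fixed once by root-solving the logit
shift on a 300,000-person pilot so the default prevalences land on the
targets. Age×mechanism and mechanism×nature dependence (falls skew old,
transport young, fire→burns, poisoning→poisoning) is invented-but-plausible
structure, reconciled to the marginal targets by iterative proportional
fitting.

**Ground-truth SRR semantics.** Because death risk depends on the worst
code *and* covariates, the survival fraction of carriers of code d — the
estimand of SRR estimation — is the model-implied average over carriers,
not the raw per-code severity parameter (carriers of a mild code include
people whose worst code is severe). The generator records both: the
severity parameters in the config, and the exact implied survival per code
(from the realised per-person probabilities) in `srr_truth.csv`. Recovery
tests compare estimated SRRs to the implied values, where the deviation is
exactly binomial; the 4-standard-error bound then has its nominal meaning.

What the generator does **not** emulate: probabilistic-linkage error,
hospital-level random effects, geographic structure, coding drift over
time, within-person correlation across repeat injuries (each person has one
index event), or deaths before any admission. Passing tests therefore show
that the pipeline recovers what this generator plants — they do not certify
performance on real linked data.

## Comparative direction at desk scale

Under the worst-injury generating process, worst-injury ICISS models reach
a higher optimism-adjusted c-statistic for mortality than multiplicative
ones, and the ordering reverses under a multiplicative process. The two
scores are highly collinear (r ≈ 0.9 on the log scale) and the systematic
difference is of order 0.001–0.002 in c. At n in the tens of thousands the
noise of estimating ~100 SRRs from ~2% mortality exceeds that difference
and happens to favour the worst variant under either process (the minimum
of noisy ratios degrades less than their product); at population scale this
noise is negligible. The comparative test therefore scores
models with the generator's true severity values — isolating the property
being claimed, the ranking of functional forms — at n = 40,000 over three
seeds per process, asserting the sign of the mean difference.

## Problem sizes and numerical choices

Recovery and calibration tests run at n = 50,000 persons with fixed seeds;
integration tests at n = 2,000–4,000; bootstrap checks use B = 8–50. These
sizes were chosen so each check has clear power while the whole suite stays
desk-scale. Probabilities are clipped at machine-safe bounds inside
likelihoods; the logit ICISS form clips scores at 1 − 1e-9 (a score of
exactly 1 is otherwise infinite); SRR lookups for codes unseen at fit time
default to 1.0 with a logged count (`missing_policy="error"` to refuse).

## Known limitations

* SRRs are raw ratios: no shrinkage or empirical-Bayes smoothing, so rare
  codes carry high variance into the worst-injury score.
* The bootstrap's blind spot for fixed-SRR optimism (above).
* Mechanism/nature category mappings cover the synthetic vocabulary's code
  ranges; a licensed classification would refine the "Other" buckets.
* Quasi-separation warnings are expected for sparse categories at small n;
  coefficients for those cells are not interpretable (fit statistics are).
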