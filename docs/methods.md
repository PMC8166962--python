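# Methods

## Data model

Spontaneous-report extracts are four relational tables keyed by an opaque
report identifier: demographics (`demo`, one row per report — its row count is
the denominator for every downstream 2×2 table), drugs (`drug`, with the
reporter-assigned role code: suspected / concomitant / interacting, and
administration start/end dates), reactions (`reac`, with MedDRA PT code, onset
date and outcome), and primary disease (`hist`, validated but unused by the
analyses). Dates are digit strings `YYYYMMDD`/`YYYYMM`/`YYYY`; precision is
carried explicitly and a partial date can never be promoted to a full one —
records with incomplete dates are *excluded and counted*, never imputed.
Role and outcome codes are canonical English tokens; source-language strings
(the real extracts are Japanese) are translated at read time through a
user-editable mapping, so no non-portable vocabulary is hard-coded.

Only suspected-drug rows enter the analysis set. Case status is defined purely
on the reaction table (any reaction whose PT code is in the configured set),
so it is invariant under the role filter. Product names map to canonical drugs
and ATC codes through a vocabulary file; the two paclitaxel products map to
distinct canonical drugs sharing ATC L01CD01 so the solvent-based and
albumin-bound formulations can be contrasted while still pooling into the
taxane class. Class-level exposure uses set semantics (a report exposed to two
members of one class counts once), keeping the 2×2 denominator a report count;
drugs without an assigned ATC code are excluded from class groups but retained
at drug level.

## Disproportionality

For each target, a = exposed case reports, b = exposed non-case reports,
c = total cases − a, d = total reports − a − b − c (denominators recomputed
from the dataset, never trusted from configuration). The reporting odds ratio
is (a·d)/(b·c) with the Woolf (logit) interval,
exp(ln ROR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)), z₀.₉₇₅ = 1.959964. The Woolf
interval is the standard SRS formula and reproduces the published screen
anchors at one decimal. A signal requires ROR > 1, CI lower bound > 1 and
a ≥ 2. Tables with a < 2 or an empty b/c/d cell are reported non-evaluable
rather than corrected; a Haldane–Anscombe 0.5-correction mode exists behind an
explicit flag and is clearly non-default. Reported values are rounded to one
decimal, half away from zero; internal values keep full precision. The ROR
indexes reporting disproportion only — it is not a risk estimate and carries
no causal weight; no multiplicity adjustment is applied across the screen.

## Time-to-onset

Latency = first complete onset date of the focal event − earliest complete
administration start date, per (report, drug), in whole days. Exclusions, each
separately counted: incomplete date on either side; negative latency; latency
beyond the analysis window (365 days, inclusive, treated as truncation —
excluded, not censored). Duplicate prescription rows of the same drug in one
report collapse to a single record and are reported in the exclusion
accounting.

Medians and quartiles use the (n+1)p plotting-position convention with linear
interpolation (numpy `method="weibull"`), the convention of the commercial
statistics package traditionally used for these analyses; the numpy method
name is configurable. The Weibull density f(t) = (β/α)(t/α)^(β−1)·exp(−(t/α)^β)
is fitted by maximum likelihood on (log α, log β) (Nelder–Mead from a
moment-style start — β₀ from the coefficient of variation via cv^−1.086, α₀
from the mean — with a small multi-start fallback); 95% CIs are Wald intervals
on the log parameters using a finite-difference observed information at the
optimum, which respects the positive support. Same-day onsets (latency 0) are
shifted to 0.5 days for the likelihood only — the log-density is undefined at
zero — and retained as 0 in the quantile summaries. Fitting refuses samples
with fewer than 10 retained latencies, mirroring the practice of analysing
only classes with enough reports. The shape CI classifies the hazard with
strict inequalities: upper bound < 1 → initial failure (decreasing hazard),
lower bound > 1 → wear-out failure (increasing), otherwise random failure —
a boundary exactly at 1 is random failure.

Because published α/β values for real extracts depend on unpublished raw
latencies and on unstated quantile/CI algorithm choices, they are treated as
qualitative references; the estimator itself is validated by parameter
recovery on synthetic data (mean relative bias of α̂ and β̂ below 5% at
n = 1,000 over 100 seeds), by agreement with an independent MLE
(`scipy.stats.weibull_min.fit(floc=0)`), scale equivariance, the exponential
special case, and a local-optimality grid check.

## Onset comparison and outcomes

In SRS data every retained record experienced the event, so all observations
are events and the Kaplan–Meier estimate coincides with 1 − ECDF (this
identity is asserted in tests); the censoring-capable implementation
(lifelines) is used for generality. The two-arm contrast uses the Mantel–Cox
log-rank test with hypergeometric variance and ties pooled at shared event
times, significant at P < 0.05. Arms below the Weibull minimum n still produce
a descriptive comparison, with a warning. Outcomes are tabulated per
drug/class over the five informative categories; unknown/blank outcomes are
excluded per drug (this per-drug convention reproduces the published combined
fractions such as 38/67 = 56.7%). Favourable (recovered + improved) and
unfavourable (death + with sequelae + not recovered) fractions are computed in
rational arithmetic so they sum to one exactly before rounding. Outcome
attribution uses the focal reaction's outcome (first occurrence on ties), not
the report's worst outcome. Mosaic geometry: column widths proportional to
per-class denominators, segment heights to within-class shares.

## Synthetic-data generator

The generator emulates report-level drug–event co-occurrence: exposures are
independent Bernoulli draws per configured drug; the focal event occurs with
background odds p₀/(1−p₀) multiplied, per exposed drug, by its
`event_odds_multiplier` — parameterising the association on the odds scale
makes the configured multiplier exactly the ROR estimand, so calibration tests
are self-calibrating. Exposed case reports draw an onset latency from the
drug's Weibull(α, β), rounded to whole days (rounded zeros are emitted as
day 0); when a report is exposed to several configured drugs the latency comes
from the first in config order (the intended scope is a single focal drug plus
background). Start dates are uniform over one configurable calendar year;
dates degrade to year-month with probability `missing_date_prob`; prescription
rows duplicate with probability `duplicate_prescription_prob`; a concomitant
"comedication" row appears with probability `concomitant_drug_prob` (default
0.2) to exercise the role filter. One focal PT per configuration. Identical
seeds give byte-identical datasets. `expected_contingency` returns the exact
expected 2×2 cells by marginalising over the exposure patterns of the other
drugs.

What the generator does **not** model: reporting-delay dynamics, correlated
co-prescription (regimens), drug–drug interactions, multi-event reports,
secular trends, or under-reporting structure. Passing calibration tests
therefore shows the estimators are correct under the assumed independence
structure, not that real-data confounding (e.g. combination chemotherapy) is
handled — the screen remains a disproportionality analysis with all its usual
caveats.

Default study conditions used in the test suite: null-calibration replicates
use 10,000 reports, background event probability 0.02, exposure 0.05 and
multiplier 1 (expected a ≈ 10) over 200 seeded replicates — the signal rule
is one-sided on a 95% CI, so the false-signal rate is expected near 2.5% and
asserted ≤ 5%; consistency uses one 200,000-report dataset (exposure 0.014,
background 0.003, multiplier 26, matching a realistic strong-signal regime)
with the estimated ROR within 10% of the multiplier; log-rank null uniformity
uses 1,000 replicates of two n = 30 arms from a common Weibull(40, 0.9).
These sizes were chosen as the smallest that leave comfortable Monte-Carlo
margins for the asserted tolerances.

## Pipeline

One master seed is split deterministically per stage (SHA-256 of
`seed:stage`, reduced below 2³¹), so full runs are reproducible byte-for-byte
under a fixed config; each stage logs its input/output row counts — exclusion
accounting is part of the science here. Stage failures preserve partial
outputs with a failure manifest and a non-zero exit.

## Known limitations

* The Weibull CIs are Wald intervals on log-parameters; profile-likelihood or
  bootstrap intervals would behave better at small n (n near the minimum of
  10), where Wald CIs for β are known to be optimistic.
* The 365-day window truncates rather than censors; with heavy late-onset
  tails this biases α̂ downward. A censoring-based variant would need the
  at-risk construction SRS data cannot support.
* Exact reproduction of published α/β/median values for real extracts is out
  of reach by design (raw latencies unpublished); only the printed-count
  quantities (RORs, CIs, outcome fractions, hazard classes from printed CIs)
  are reproduced exactly.
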