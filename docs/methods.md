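# Methods

## Model

The package scores a child with nonsystemic JIA in clinically inactive
disease (CID) on nine dichotomous criteria. The continuation utility is
a linear index,

U = β₀ + Σₖ βₖ xₖ,   β₀ = −1.61,

with coefficients (0.55, 0.57, 1.36, 0.87, 1.28, 0.75, 0.35, 1.09, 1.85)
for slow response, RF positivity, flare history, joint damage, uveitis,
spine involvement, TMJ involvement, treatment failure, and
parental/child preference to continue. These are group-average logit
estimates from a stated-preference vignette study of pediatric
rheumatologists; the model therefore predicts *peer withdrawal
behavior*, not flare risk, and the wide confidence intervals of the
original estimates are the reason the tool lets users re-weight criteria.

The withdrawal likelihood is a two-factor product:

P_withdraw(t, x) = clamp₀₁(a + b·ln t) · (1 − σ(U)),  a = −1.2861, b = 0.7557,

where t is months in CID and σ the logistic function. The first factor
is the baseline propensity to withdraw as remission lengthens; the
second down-weights it by how strongly the child's profile argues for
continuing.

### Clamping and domain

The log-linear baseline is unbounded: with the default parameters it
crosses 0 at ≈5.48 months and exceeds 1 beyond ≈20.6 months. Since a
displayed likelihood must be a probability, the baseline (and hence the
product) is clamped to [0, 1]; predictions carry a `clamped` flag and
the raw value so the unclamped curve stays inspectable. CID time is
restricted to [6, 24] months — the intake slider range, and withdrawal
is not considered under 6 months of CID — with `check_domain=False`
available to inspect the raw curve outside it. Flags are strictly 0/1;
a missing criterion is an input error, never imputed, because every
intake field is mandatory.

Because all nine coefficients are positive and the clamped baseline is
non-negative and non-decreasing in t, the model is monotone: setting any
risk factor can only lower P_withdraw, and more CID time can only raise
it. The test suite asserts both properties, plus the exact decomposition
identity, against an independently coded brute-force evaluation over all
512 flag combinations.

## Relative importance and weight adjustment

Criterion importance is the normalized coefficient share
wₖ = βₖ / Σβ (Σβ = 8.67), displayed as round-half-up integer percents:
21, 16, 15, 13, 10, 9, 7, 6, 4. Half-up rounding (not banker's) is used
because it reproduces that display list; entries are rounded
independently, so they may not sum to 100 (the defaults sum to 101, the
exact shares to 100).

User adjustment works on a 0–100 rating scale. Default ratings anchor
the top criterion (parental preference) at 100 — any positive scaling
gives identical normalized weights, so the anchor is presentational.
Adjusted ratings are renormalized to 1 (zeros preserved; all-zero
rejected) and mapped back into coefficients by βₖ′ = wₖ·Σβ, conserving
total coefficient mass. This mapping is the package's own design choice:
it reproduces the unadjusted model exactly at default ratings and keeps
the utility scale comparable across adjustments. The intercept and the
time-baseline parameters are deliberately untouched — they encode the
overall propensity to withdraw, not the balance among criteria.

## Synthetic vignette data and parameter recovery

`simulate.py` emulates the kind of data the original coefficients came
from: vignettes (flag combinations, full factorial or random subset) are
shown to simulated raters who choose continue with probability σ(U).
The default validation condition is the full 512-profile factorial with
50 raters per vignette (25,600 choices), a size at which every
coefficient's Monte-Carlo standard error is well below 0.05, so the
±0.15 recovery check is a ≳3σ band. Refitting uses maximum-likelihood
logit (statsmodels); the test suite cross-checks it against a direct
BFGS minimization of the hand-written negative log-likelihood. The time
baseline is fit separately — ordinary least squares of withdraw fraction
on ln(months) — matching the model's own two-stage structure; on
noise-free input it recovers (−1.2861, 0.7557) to 1e−9. Fractions
outside [0, 1] are fitted with a warning rather than rejected, because
the unclamped baseline itself is the natural fitting target.

What the simulation does *not* emulate: rater heterogeneity (no
mixed-logit random effects), correlated criteria in real caseloads
(generator flags are independent Bernoulli), repeated measures per
rater, or any time variation within a vignette battery. Passing
recovery tests therefore show the estimation machinery is correct under
the model's own assumptions, not that the published coefficients are
externally valid.

All randomness flows through `numpy.random.default_rng` seeded per
operation; identical seeds give identical profiles, choices, fits, and
reports.

## Numerical and interface choices

- Logistic evaluated in the two-branch stable form; non-finite utility
  is a domain error rather than a silent saturation.
- Validation collects *all* violations per record (and per CSV row)
  before raising, which suits batch clinical data entry; it is
  implemented in plain dataclasses rather than pydantic since the
  error-collection contract is ~40 lines.
- Files use lower_snake_case criterion names with the regression symbols
  (RS, RF, F, JD, U, S, TMJ, TF, PPcontinue) accepted as aliases;
  unknown keys/columns pass through as `notes` metadata.
- CLI exit codes: 0 ok, 2 input/configuration error (itemized on
  stderr), 3 estimation failure. Reports are JSON with full-precision
  numerics plus display-rounded percent fields.

## Known limitations

- Coding for a biologic response time over 12 months is undefined in the
  utility equation (only <6 and 6–12 month levels exist); profiles carry
  the dichotomous flag only.
- Whether time-in-CID counts as one of the nine criteria or as a tenth
  input is ambiguous in the original study's description; it is
  implemented as a separate time input alongside nine flags.
- The intercept is held fixed under weight adjustment; rescaling it is
  another defensible convention.
- Group-average model: no respondent heterogeneity, no per-user weight
  persistence.
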