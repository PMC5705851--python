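# Methods

This note documents the models, rules, calibrations and design choices
behind `bcellmon`, and what the synthetic cohort does and does not emulate.

## The response rule engine

BILAG-2004 grades are an ordered categorical scale A > B > C > D = E; D
(previously active) and E (never active) are stored separately for data
fidelity but are identical in all scoring and response logic. The global
score weights A=12, B=8, C=1, D/E=0 and sums over the nine fixed organ
domains (range 0–108). Weeks are counted from the first-ever rituximab
infusion; each later cycle restarts its own 6-week and 26-week clock from
its start week.

Cycle response at ~6 months is a strict partition:

* **major** — every baseline-active (A/B) domain at grade C or better, no
  newly active domain, no interim flare;
* **partial** — exactly one domain at grade B (all other baseline-active
  domains at ≤C, nothing newly active, no interim flare);
* **non-response** — everything else.

Two conventions the three-way definition leaves open are fixed here and
flagged in the output so a sensitivity analysis can re-code them:

1. A baseline-A domain found at B at 6 months has improved but not to C.
   We count it as the single permitted persistent B (partial response) and
   set `persistent_b_from_a=True`. This is the only convention under which
   the three categories partition all grade configurations.
2. A new A/B at the 6-month visit in a baseline-quiescent domain is treated
   as a flare at the endpoint and forces non-response, mirroring the
   "no A/B flare" clause applied at interim visits.

The 6-month visit is the visit closest to week 26 within [20, 32] weeks of
cycle start (3-monthly assessment schedule); cycles without one are
*unevaluable*, a distinct signal rather than a fourth category. Relapse
after a major/partial response is a new grade A anywhere or a grade B in a
domain that was ≤C at the 6-month visit; the persistent B of a partial
responder therefore does not re-trigger while it remains B. Ties (two
qualifying domains at one visit) report the first in the fixed domain
order; the event week is what matters analytically. Response duration runs
from cycle start to relapse (min 26 weeks, since relapse presupposes the
6-month response) or to censoring.

## B-cell biomarker rules

All counts are in ×10⁹ cells/L, the scale on which the thresholds are
defined, avoiding unit-conversion bugs; the ×1000 rescaling used for
regression odds ratios (per 0.001×10⁹/L) is applied only inside the
modelling layer. Comparisons are fixed as strict/inclusive exactly as used
clinically: complete depletion **<** 0.0001 (total count), repopulation
**≥** 0.0001, plasmablast relapse rule **>** 0.0008, anti-drug-antibody
positivity **>** 140 AU/mL.

The 2NDNR detector flags cycle k ≥ 2 when the severe-infusion-reaction,
CD20⁺ non-depletion and non-response criteria all hold *and* an earlier
cycle achieved CD20⁺ depletion together with response. Criterion 2 uses the
naïve+memory compartment only, because plasmablasts are CD20-negative and
cannot inform failure of an anti-CD20 agent; the 6-week depletion marker
used to predict response uses the total count. The depletion threshold's
application to total versus CD20⁺ counts is genuinely ambiguous in clinical
usage, so `BCellPanel` exposes both totals and either convention can be
run. The 6-week panel is the nearest panel in [4, 10] weeks of cycle start;
the >24 h adjudication of infusion reactions is an input flag, not
modelled.

## The synthetic cohort

The generator emulates the structure of a single-centre prospective
rituximab-in-SLE cohort: baseline covariates (age ~ N(40, 15²) truncated to
[17, 85], 93% female, ethnicity mix 68/9/17/5%, 63% concomitant
immunosuppressant, 75% antimalarial, 39% low complement, log-normal dsDNA
titres and B-cell subsets with log₁₀-SD 0.5 around medians 0.0349 / 0.0019
/ 0.0011), baseline BILAG grades drawn so that 82% have ≥1 A, 14% have no A
but ≥2 B, and ~4% are the single-B refractory minority, with A/B domains
placed by the observed marginal domain frequencies.

Cycle-1 outcomes follow a causal chain: complete depletion is Bernoulli
with logit = b₀ + ln(0.29)·[low complement] + ln(0.86)·[plasmablasts ×1000];
b₀ is found by a deterministic root-find (fixed internal quadrature sample)
so the marginal depletion probability equals its configured 58%. Response
is then drawn at 93% (complete) / 68% (incomplete), which makes the
marginal response rate (58% × 0.93 + 42% × 0.68 ≈ 82.5%) and the 50/32/18
category split emergent rather than imposed; responders are major with
probability 58/96.

Responders split 50/50 into earlier- and later-relapse classes. Their
6-month plasmablast counts come from log₁₀-normal components with fixed
log-SD 0.5 whose means are calibrated by
μ = log₁₀(0.0008) + 0.5·Φ⁻¹(p) so the exceedance probability over the rule
threshold is 0.73 (earlier) or 0.10 (later) — the rule's sensitivity and
1−specificity. Only exceedance probabilities are calibrated because the
underlying distributions are unknown; operating characteristics are the
reported quantity. Relapse times land on the 13-weekly visit grid: the
earlier class relapses within 26 weeks of the 6-month visit with
probability 0.90 (else within 52), the later class follows a per-visit
geometric hazard solved to cumulative 33% / 73% at 26 / 52 weeks. Note the
class labels are generative: because classes overlap in *time* (10% of the
earlier class relapses after 52 weeks; 33% of the later class within 26),
the observed-time operating characteristics in a full cohort analysis are
diluted relative to the class-conditional calibration — exactly the
distinction between a biomarker's calibrated performance and its apparent
performance under label noise.

Retreatment on relapse occurs with probability 77/96. In repeat cycles,
previously depleted-and-responding patients face a 2NDNR hazard with
logit = b₀ + ln(0.139)·[immunosuppressant] + 1.5·Δlog₁₀(pre-retreatment
plasmablasts); b₀ is again root-found so the marginal incidence among
retreated responders is 9/77. 2NDNR forces the full signature (reaction,
CD20⁺ non-depletion, non-response, anti-drug antibodies at 100% positivity
versus 56% in continued responders). Non-2NDNR retreated patients respond
at 61/63 — the reported cycle-2 rate of 85% counts 2NDNR patients in its
denominator, so applying the depletion-conditional split there would
contradict it; the depletion–response coupling is therefore modelled in
cycle 1 only, where the validation analysis lives. Depletion in cycles 2–3
is Bernoulli at 68% / 79%. Serious infections occur per cycle at 8/98
(complete) vs 7/73 (incomplete depletion). Follow-up is censored at 130
weeks and at most 3 cycles are generated — sizes chosen to keep a
10,000-patient cohort generable in seconds while covering every analysis.

Reproducibility: patient k draws from `default_rng([seed, k])`, so records
are invariant to cohort size; counts are rounded to 7 decimals at
generation so the in-memory dataset equals its CSV round-trip exactly and
regeneration is byte-identical.

What the simulator does **not** emulate: missing data (the real cohort
needed multiple imputation; synthetic data are complete, so complete-case
analysis is exact here and the imputation machinery is deliberately out of
scope), inter-observer grading noise, mechanistic repopulation kinetics,
within-patient correlation of grades across domains beyond the marginal
frequencies, and dosing logistics. Passing tests therefore demonstrate that
the rules and statistics are implemented correctly and that the generator
hits its configured margins — not that the generator reproduces every joint
distribution of real cohorts.

## Statistics

* **Fisher exact (2×2)**: two-sided p by the sum-of-probabilities-≤-observed
  convention (delegated to `scipy.stats.fisher_exact`, which implements it);
  this convention reproduces the reference values 0.023 and 0.789 on the
  reference tables. The reported odds ratio is the sample cross-product
  (a·d)/(b·c), with zero-margin tables reported as inf/NaN rather than
  silently dropped. Tests cross-check against an independent `math.comb`
  enumeration of all margin-preserving tables.
* **Mann-Whitney U**: exact mid-rank permutation p (all label assignments
  enumerated) for combined n ≤ 20; normal approximation with tie correction
  beyond. The exact branch is hand-written because the scipy exact method
  does not handle mid-rank ties as a permutation test; tests cross-check
  against a pairwise-count enumeration oracle.
* **Threshold metrics**: classification by strict `>` (matching the
  plasmablast rule); undefined metrics on single-class input are reported
  as missing, never zero; AUC is the rank statistic.
* **Logistic regression**: statsmodels MLE with Wald 95% CIs; pairwise
  covariate correlation > 0.8 raises a collinearity error naming the pairs
  (the caller chooses what to drop); perfect separation raises an explicit
  error suggesting a penalized fit (the fallback itself is out of scope).
  Counts are rescaled ×1000 before entering regressions.
* **Summaries**: medians/IQRs use lower-interpolation quartiles so reports
  are reproducible bit-for-bit. `run_paper_analysis` is a pure function of
  the cohort: identical inputs give identical report bytes, and every
  complete-case exclusion is counted in the report.

## Known limitations

* The simulator's relapse-time and baseline-grade models are conventions
  chosen to hit the reported margins, not mechanistic claims; quantities not
  pinned by a reported figure (e.g. the 50/50 earlier/later split, chosen
  for consistency with a 52-week median response duration) are single
  defensible defaults, stated here, and exposed as parameters.
* Multiple imputation is not implemented; analyses are complete-case with
  explicit exclusion counts.
* Time-to-event modelling (Kaplan–Meier/Cox) is out of scope; response
  durations are summarised as medians/ranges only.
* The observed-label ROC of the plasmablast rule in a full simulated cohort
  is attenuated by class overlap in time (see above); the calibrated
  class-conditional operating characteristics are the reference quantity.
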