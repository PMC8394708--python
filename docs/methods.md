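# Methods

## Scope and design

`crccea` implements a group-level (non-Markov) cost-effectiveness
comparison of two CRC screening strategies observed cross-sectionally:
two cohorts of 100 patients each, one screened by iFOBT and one by
germline genetic testing, with stage-at-diagnosis distributions,
stage-specific mean survival, stage-specific mean EQ-5D-5L utilities,
and itemized provider costs as inputs. Nothing is modelled over time:
survival means are exogenous 10-year restricted means from a national
cancer-survival registry report, utilities are single cross-sectional
measurements, and costs are annual per-patient provider costs. The
package deliberately does not estimate survival, pool diagnostic
accuracy, or build a state-transition model — those are inputs or
out of scope.

## Pipeline stages

1. **Costing** (`costing`). Per-arm profiles are sums of itemized
   components. `top_down_unit_cost` (aggregate expenditure / patients ×
   mean visits) and `activity_based_unit_cost` (sum of activity costs)
   are offered as upstream calculators, but the canonical input is the
   pre-computed component table: the raw expenditure ledgers behind it
   were never published. Currency conversion is a plain exchange-rate
   division (RM→USD at 4.14 for price year 2019); CPI adjustment is a
   user-supplied multiplicative index, defaulting to 1 because no index
   values are published. Between-arm differences carry a
   normal-approximation 95% interval (diff ± 1.96·√(se₁²+se₂²)) when
   component SEs exist. The source tables print much narrower intervals
   whose construction is unexplained; those are stored as-published in
   the fixture for display and never recomputed or imitated.
2. **Outcomes** (`outcomes`). EQ-5D-5L profiles score through a
   pluggable value set anchored at utility 1 for (1,1,1,1,1). The
   Malaysian tariff coefficients are not published, so the package
   bundles only a documented linear toy set (0.05 per level step; worst
   state 0.0) plus a loader for external coefficient files. Nothing in
   the LY/QALY chain depends on a real tariff: the chain consumes the
   published arm×stage utility *means* directly. A "problem" in a
   dimension is any level ≥ 2 — the conventional EQ-5D dichotomization.
3. **Effectiveness** (`effectiveness`). LY_k = s_k·n_k,
   QALY_k = s_k·n_k·u_k, accumulated at full precision; per-patient
   values divide by the arm's Σ n_k (100 here) rather than a hard-coded
   100. Utilities used are the arm×stage means, not the arm-level HRQoL
   summary means — the two disagree in the source and only the former
   reproduce its QALY table.
4. **CEA engine** (`cea`). Cohort management cost
   Σ_k c_k·n_k + C_screen; ICER on cohort totals at full precision;
   quadrant/dominance from the (ΔC, ΔE) sign pattern with strict
   inequalities required for dominance (axis cases are labelled
   trade-offs; the origin and the ΔE = 0, ΔC > 0 boundary report NE, the
   documented convention the tests pin down). Threshold classification
   uses GDP-per-capita multiples: < 1 highly cost-effective, 1–3
   cost-effective, > 3 not cost-effective. The source prose leaves the
   (1, 2)×GDP band unassigned ("less than one … between two and three");
   folding it into cost-effective follows the usual WHO-style bands. A
   dominant strategy is classified highly cost-effective and a dominated
   one not cost-effective regardless of the ratio, and a bare negative
   ICER is never interpreted without its quadrant.
5. **Sensitivity** (`sensitivity`). The study's discounting is a
   one-shot multiplicative reduction value × (1 − r) applied to every
   cost, LY and QALY cell — reverse-engineering its sensitivity grid
   shows each cell equals base × 0.97 or × 0.95, not 1/(1+r)^t. That
   rule (`paper_multiplicative`) is the default; standard exponential
   discounting with a 1-year default horizon is provided as the
   conventional alternative. Because the rule is linear and positive,
   dominance (ΔC < 0, ΔE > 0) and the ICER value are invariant across
   scenarios.

## Rounding policy

Internal arithmetic is never rounded; display rounding is
round-half-even at 2 dp. Two reporting-chain exceptions mirror how the
published summary tables were computed and are asserted by tests:

* Cost-per-LY/QALY ratios divide the provider cost by the
  **2-dp-rounded** per-patient effect (full-precision division gives
  71.51/159.22/108.45/196.94 instead of the published
  71.56/159.26/108.38/196.43). The full-precision ratios are also
  reported in the results manifest.
* The sensitivity grid discounts the 2-dp base-case cells, and its
  difference row discounts the as-published base difference 603.424
  (the unrounded-component difference, not 976.26 − 372.83 = 603.43).

Known source inconsistencies, recorded rather than reconciled: the
genetic-testing cost at 5% prints 927.44 although 976.26 × 0.95 =
927.447 rounds to 927.45 (the acceptance test allows 0.01 on that one
cell); the discussion section quotes cost/LY and cost/QALY figures that
contradict the summary table (the table is arithmetically consistent
with the cost and effectiveness inputs and is adopted); the published
HRQoL summary's denominators are inconsistent with the 200-patient
cohort (likely patients plus family members), so that table is carried
as-published and never recomputed.

## Synthetic cohorts

`simulate.generate_cohort` emulates the study conditions: 100 patients
per arm; stage distributions (6, 17, 54, 23)% for iFOBT and
(10, 60, 25, 5)% for genetic testing; utilities drawn truncated-normal
around the arm×stage means with sd 0.273 (the only dispersion figure
published — the overall utility SD), truncated at the full-health
ceiling of 1; VAS drawn normal (mean 73.58, sd 18.47) clipped to
[0, 100]; and an EQ-5D-5L profile whose linear-toy index approximates
the drawn utility (deficit spread over randomly ordered dimensions).
Stage assignment is multinomial by default; a deterministic
largest-remainder allocation mode produces exact expected counts so
that, with `utility_sd = 0`, the full pipeline recovers the study's
per-patient LY/QALY exactly — the parameter-recovery tests use this,
and stochastic recovery is checked at 10,000 patients per arm within
2% of the analytic expectation under the truncated-normal model (the
truncation pulls stage means slightly below their nominal values, so
the analytic target uses the truncated mean).

What the generator does **not** emulate: demographic covariate effects
on utility, utility–VAS correlation beyond shared stage, the real
respondent structure behind the published HRQoL summary, or any
clinical meaning in the synthesized profiles. Passing tests therefore
show the pipeline's arithmetic and contracts are right under the
study's aggregate structure, not that the generator reproduces real
patient-level CRC data.

## Numerical and degenerate-input choices

Totals use full-precision accumulation (summing 2-dp-rounded stage
QALYs is wrong by one cent on the iFOBT arm — kept as a negative
control in the tests). ΔE = 0 yields an undefined ICER (None) with the
quadrant set by the cost sign alone. Empty cohorts, populated stages
without a utility or treatment cost, negative amounts, rates outside
[0, 1) and malformed stage-probability vectors raise
`InvalidInputError`; unknown layouts/currency directions raise
`ConfigurationError`; corrupted packaged data fails its SHA-256
manifest check with `IntegrityError`.

## Limitations

Cross-sectional utilities stand in for longitudinal quality-of-life
streams; LY/QALY are lump sums, so the exponential discounting option
defaults to a 1-year horizon and no multi-year stream is modelled. The
provider perspective omits patient and caregiver costs. No
probabilistic sensitivity analysis (CEAC) is performed — the only
varied parameter is the discount rate, matching the scope of the
analysis the package reproduces.
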