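# Methods

## Screening model

A screening session produces, per patient: instrument totals for the
alcohol (SADD) and drug (DAST-10) screens, one probable/not-probable flag
per psychiatric disorder from an 11-module screening interview, and a
suicide-risk tier. The triage rule then maps these to a single referral
tier. The rule's premise is organisational, not diagnostic: the facility
has no specialist on site, so the algorithm's only job is to separate
(1) conditions needing immediate specialized referral, (2) probable but
non-acute disorders needing specialist assessment, and (3) everything else.

### Suicide tier

An *acute signal* is ideation, planning, an attempt, or intentionality at
or above the cut-off (default 5 on a 0–10 scale). A signal dated within the
acuity window (default 30 days) tiers as `active_emergency`; beyond it, as
`non_acute_risk`; a lifetime attempt with no current signal is also
`non_acute_risk`. An acute signal with no recency recorded is a data error,
not a default: acuity cannot be assessed, and the screen must say so.

Interpretation note: the published flow chart's yellow branch lists
"intentionality ≤ 4 … > 30 days". Here any acute signal beyond the window
tiers as non-acute risk regardless of the intentionality value; this keeps
the tier monotone in recency (moving an episode further into the past never
escalates the tier) and agrees with the branch's intent. Sub-threshold
intentionality with no other indicator does not tier at all.

The intentionality scale's range is nowhere published — only the ≥ 5 / ≤ 4
cut-offs are — so 0–10 is a configuration default, not a source fact.

### Traffic light

Evaluated strictly in order red → yellow → green, so ties are impossible:

- **red**: suicide tier `active_emergency`, or an emergency disorder
  (default set {psychosis, mania}) probable with last episode ≤ window;
- **yellow**: otherwise, if suicide tier `non_acute_risk`, or an emergency
  disorder probable with a remote episode, or any non-emergency disorder
  probable — *regardless of recency*. The published chart's "Others > 30
  days" clause is ambiguous (which others, and why recency-limited); a
  probable disorder that is not an emergency warrants specialist referral
  whether its last episode was 10 or 400 days ago, so recency is ignored
  for non-emergency disorders. This is an interpretation, recorded as such.
- **green**: the residual category.

The published green condition literally also requires SUD ≥ 3 *and*
AUD ≥ 7, which would leave a patient below both substance cut-offs with no
light at all. Totality is non-negotiable for a triage tool, and the green
recommendation text defines green by the *absence* of probable co-occurring
disorder, so substance positivity is carried on the result but never gates
the light. A fidelity mode (`assign_light(..., strict_green=True)`)
reproduces the literal conjunction and emits an explicit
`no_rule_fired=True` outcome where it is not total.

A probable emergency disorder with no episode recency is a data error
(red vs yellow is undecidable); non-emergency disorders never need recency.

### Instruments

Scoring is definition-driven. Sum instruments: reverse-keyed items are
inverted on their own scale (`x ↦ max − x`, an involution), skipped items
(skip rules may only reference earlier items) contribute nothing, and a
missing response on a non-skipped item is a hard error — a screening tool
must never impute symptom data. Positivity is `total ≥ cut-off`. Severity
bands (e.g. SADD low/medium/high dependence) are reported in the
interpretation string only and never drive triage: the triage algorithm's
cut-offs (7 and 3) are authoritative.

The dual-diagnosis interview's item content is unpublished. The shipped
definition is a structurally faithful shell — eleven disorder modules, two
generic gate items each, module positive if either gate is endorsed — whose
rules (`any_of` / `all_of` / `at_least`) are configuration. Tests drive it
exclusively through generated answer sets (`answers_for_flags` inverts a
flag matrix into responses), so nothing depends on the placeholder wording.

## Validation statistics

Per disorder: Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN); screen-positive prevalence (TP+FP)/n and reference
prevalence (TP+FN)/n as percentages. Zero-denominator metrics are flagged
`defined=False`, never silently 0. Confidence intervals: Wald (normal
approximation; clipped into [0,1] with a `ci_clipped` flag) by default
because it approximately reproduces the source study's printed intervals;
Wilson available as the statistically preferable option. α = 0.05
two-sided throughout; no multiple-testing correction, matching the source
analysis.

Group comparisons use Pearson χ² **without** continuity correction — this
choice reproduces the published statistics (sex 2.42, education 7.63,
income 4.16) exactly; Yates correction is available by flag. The smallest
expected count is reported so callers can warn below 5. Two-sample t tests
are computed from summary statistics, pooled (df = n₁+n₂−2) or Welch
(Satterthwaite df).

Missing data are handled complete-case per disorder with the exclusion
count reported (count conservation: TP+FP+FN+TN+dropped = n). The source
study mentions multiple imputation but specifies no model, so it is not
reproducible and not implemented. Prevalence may be reported over the full
cohort rather than the complete cases (`cohort_n`), which is how the source
tables print it (e.g. mania: cells sum to 211 but prevalence is 9/213 = 4.2%).

### Known irreproducibles in the source tables

Computed from the printed cells, with the printed value in parentheses:

- depression sensitivity 63/80 = 0.79 (printed 0.84); PTSD 39/80 = 0.49
  (printed 0.81) — the printed Se/Sp/PPV/NPV are mutually inconsistent with
  the printed TN/FN/TP/FP, plausibly computed on imputed data;
- impact-substance χ² = 4.37 (printed 9.22);
- age t = 1.79, df 211 (printed 4.43 with p = 0.007, which is itself
  inconsistent: |t| = 4.43 at df 211 would give p < 0.0001).

This package computes all metrics from counts and documents the
discrepancies; tests assert the computed values and their disagreement with
the printed ones. The printed Se/Sp are still used as simulator defaults,
as the screen's claimed operating characteristics.

## Simulator

Defaults are the validation cohort's margins: n = 213; reference
prevalences (TP+FN)/213 per disorder; index Se/Sp as printed; sex
202/213 male; education, marital status, income and impact-substance
distributions as printed; age ~ Normal(31.09, 11.12) truncated at 18;
days in residence uniform 7–180 (not published; any value ≥ 7 satisfies
eligibility). The three disorders without published cells (panic,
agoraphobia, specific phobia) default to prevalence 0.12 / 0.10 / 0.12 and
Se = Sp = 0.85, consistent with the screen's claimed > 80% sensitivity and
> 82% specificity. Probable flags receive an episode recency: within the
30-day window with probability `emergency_recent_fraction` (default 0.5,
unpublished), else uniform on 31–730 days. Suicide screens are active
(recent ideation, intentionality ≥ 5) at rate 0.05 and
lifetime-attempt-only at rate 0.10, both unpublished defaults.

Disorders are independent by default — the source reports no joint
distribution, so independence is the simplest defensible null. An optional
`comorbidity_factor` q ∈ [0,1] mixes each patient's per-disorder
probabilities with a patient-level severity coin
(p = π ± q·min(π, 1−π) with probability ½ each), inducing exchangeable
positive correlation while preserving every marginal prevalence exactly.
Index errors are independent across disorders given truth.

Random streams are counter-based: one generator per (seed, stream-tag,
patient, disorder), so cohorts are byte-reproducible, a patient's draws do
not depend on cohort size, and generation could be parallelised.

**What the simulator does not emulate:** real comorbidity structure beyond
the exchangeable factor, correlated index errors across disorders,
informative missingness, longitudinal symptom change, and any association
between demographics and disorder status. Passing parameter-recovery tests
therefore show the *pipeline* is unbiased under the stated sampling model,
not that the screen performs as printed in any real population.

## Numerical and scale choices

- Parameter recovery is checked on a 3×3×3 grid of (Se, Sp, π) at n = 4,000
  per point within 4 Monte-Carlo standard errors, and at n = 20,000 for the
  single headline configuration (Se 0.84, Sp 0.77, π 0.35) within ±0.02;
  the binomial 3σ bound at n = 20,000, π = 0.35 is ≈ 0.010.
- Chi-square equivalence is checked against a cell-by-cell expected-count
  oracle on 1,000 random tables (2–4 rows/columns, counts 1–29).
- Cohort CSVs are written with the `csv` module (UTF-8, `\n`, minimal
  quoting) and read back as verbatim strings, so export → import → export
  is byte-identical; empty cells are the missing-data representation.
- Eligibility bounds (age ≥ 18, ≥ 7 days in residence, 0–30 use days) are
  validated exhaustively — every violated rule is reported, not only the
  first — and validation is idempotent.

## Limitations

The interview shell's item wording is placeholder content; clinical use
requires substituting a validated item set via the definition documents.
Reports are Markdown/JSON rather than PDF (presentation, not computation).
The MINI and MoCA instruments are represented only as reference-standard
booleans and an exclusion criterion, respectively; app-quality survey
machinery (MARS) is out of scope.
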