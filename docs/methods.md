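# Methods

## Design

The analysis is a case/non-case (disproportionality) design over
spontaneous safety reports. The unit of analysis is the deduplicated
report, never the reaction row: a report with three bleeding preferred
terms contributes one case. Exposure classification uses *all* drug rows
of a report, pooling suspect and concomitant roles, because interaction
questions concern what was co-reported, not what the reporter blamed.

Pipeline order: read quarterly tables → deduplicate → normalize drug names
→ assign cohort groups → code outcomes → evaluate the signal grid.
Deduplication runs first because it is a property of the submission stream
(one case, several versions), not of the analysis.

### Deduplication

One report per CASEID is retained: the row with the most recent FDA
receipt date (FDA_DT), ties broken by the highest PRIMARYID. PRIMARYIDs
are compared numerically when they parse as integers, falling back to
lexicographic comparison, and a numeric id outranks a non-numeric one so
the ordering is total. The operation is idempotent and independent of the
input row order (property-tested).

### Cohort rules

Counting distinct ingredients per report (d = DOACs, s = study
antidepressants, o = anything else, including unmatched free text):

* d=1, s=0, o=0 → non-interaction (DOAC monotherapy);
* d=1, s=1, o=0 → interaction;
* otherwise excluded, reporting the most informative reason in the order
  multiple_doacs > multiple_antidepressants > other_concomitant > no_doac.
  Reports that would otherwise qualify but carry no coded reaction are
  excluded as no_reactions — a case/non-case design needs at least one
  coded event.

Repeated rows of one ingredient count once (FAERS repeats drugs across
dose changes). Whether non-therapeutic entries (vitamins, devices) should
count as "other concomitant" is genuinely open; this implementation counts
every drug row, which is the stricter reading.

### Drug-name normalization

Exact dictionary lookup after cleaning (uppercase, whitespace collapse,
trailing dose/formulation tokens stripped); combination products are split
on "/" and "+" before lookup. No fuzzy matching: reproducibility beats
recall, and recall gaps are closed by extending the synonym CSV. The
packaged dictionary covers the 4 DOACs and the 14 antidepressants
(6 SSRIs, 3 SNRIs, 5 others) with common brand synonyms and salt forms; it
is a practical fixture, not an exhaustive reproduction of any proprietary
name dictionary. When a drug row's free text matches nothing, the active-
ingredient column is tried before giving up.

### Outcome coding

Two configurable plain-text term lists drive coding: a haemorrhage list
(standing in for the haemorrhage SMQ) and a nervous-system haemorrhage
list (standing in for the haemorrhagic PTs under the CNS-vascular
HLGT). MedDRA is licensed and cannot be redistributed, so the packaged
lists are curated stand-ins — the nervous-system list is deliberately a
subset of the haemorrhage list, and licensed SMQ/HLGT exports (narrow or
broad scope) drop in via configuration. Matching is exact on the
casefolded, whitespace-normalized PT string; PTs are controlled
vocabulary, so substring matching would only create false positives.

### Signal statistics

ROR = (a·d)/(b·c) with SE(lnROR) = sqrt(1/a+1/b+1/c+1/d) and a Wald 95% CI
using the multiplier 1.96 exactly (not Φ⁻¹(0.975)), so results match the
conventional printed formula digit for digit; the same multiplier is used
for adjusted intervals to keep crude and adjusted CIs comparable. Signal
criterion: a ≥ 3 and CI lower bound strictly > 1. Zero cells leave the
estimate undefined rather than continuity-corrected — the a ≥ 3 rule
already guards sparsity, and an undefined estimate is more honest than a
corrected one. No multiple-testing adjustment is applied across the
grid; the criterion is a screening rule, not a hypothesis test.

Adjusted odds ratios come from maximum-likelihood logistic regression
(statsmodels, Newton iterations, tolerance 1e-8, at most 100 iterations)
of the outcome on the exposure indicator plus sex, age band (0–17, 18–59,
60–74, ≥75), reporter type and report year, each one-hot encoded with an
explicit "missing" level. Missingness is heavy in spontaneous data (the
default generator uses 48% missing age, mirroring real tables), so
complete-case deletion would discard most reports; the explicit-missing
encoding keeps them at the cost of assuming missingness is ignorable
within levels. Constant design columns are dropped with a warning; a
coefficient beyond ±15 is reported as suspected separation with
`converged=False` rather than as a usable estimate — sparse pair strata
can genuinely separate, which is why published adjusted intervals for such
strata can span orders of magnitude. By default only strata flagged by
the crude criterion are refined (`adjusted="signals"`); `"all"` and
`"none"` are available.

Pair-level strata compare against monotherapy of the *same* DOAC by
default (`same_doac_monotherapy`), isolating the antidepressant's
contribution for that anticoagulant; pooled-comparator
(`all_doac_monotherapy`) is implemented and recorded in the output
metadata, since either choice is defensible. Overall, class- and
drug-level strata always use the pooled monotherapy comparator.

### Baseline table

Age is summarized as median (Q1, Q3) and mean ± sd and compared with a
Welch t-test; sex, age band, report year and reporter type with Pearson
chi-square on non-missing counts (missing shown as its own row, excluded
from the test). A degenerate comparison with a single represented level is
reported as p = 1 (identical proportions). Top-3 reporter countries are
tallied per group.

## The synthetic generator

The generator is first-class, tested code, not a fixture. Each report is
drawn as: covariates → drugs → bleeding via a logistic model (per-DOAC
intercept + configured (DOAC, antidepressant) log odds multiplier +
covariate effects) → nested nervous-system flag → preferred terms →
missingness masks → optional duplicate submission. Because bleeding is
generated at the report level from a single logistic model, the configured
multiplier exp(θ) is exactly the conditional odds ratio the pipeline
should recover, and nesting the nervous-system flag inside bleeding
enforces the subset relation the analysis assumes.

Defaults are pinned to the published study conditions of the DOAC ×
antidepressant cohort this package models: DOAC mix 0.350 / 0.469 / 0.015 /
0.166 (rivaroxaban / apixaban / edoxaban / dabigatran, derived from the
published per-DOAC monotherapy bleeding counts and rates), per-DOAC
bleeding rates 47.7 / 16.5 / 29.2 / 36.9 %, per-DOAC nervous-system
fractions for monotherapy (11.6 / 14.7 / 9.3 / 13.8 %) and for exposed
reports (24.2 / 15.3 / 33.3 / 15.0 %), an antidepressant co-reporting
probability of 0.00255 (≈ 530 interaction reports per 207,530), class-level
interaction multipliers 1.78 (SSRI), 1.12 (SNRI), 0.67 (other), published
marginal and interaction-group covariate distributions (age bands, sex,
reporter types, report-year profile 2010–2025), and 48.2 / 15.2 / 0.5 / 2 %
missingness for age / sex / reporter / country. Values no published table
pins down were chosen once as realistic and are not tuned: duplicate rate
0.10 with a 0.25 exact-date tie fraction, other-drug probability 0.05,
covariate→bleeding log-odds centred around zero (age trend −0.45…+0.15
across bands, small positive effects for professional reporters), and a
small nuisance-PT vocabulary.

Note one deliberate asymmetry of the defaults: the published interaction
group's raw bleeding proportion (57.9% vs 31.0%) implies a crude odds
ratio near 3, which is arithmetically inconsistent with the published
overall ROR of 1.45 from the same counts. The generator is parameterized
by the *class-level odds multipliers*, not by the inconsistent marginal
proportions, so its default interaction group bleeds at ≈ 34–37%, and the
implied overall crude ROR sits near the weighted class mix (≈ 1.2–1.4
after mild confounding). The discrepancy is a property of the source
analysis (its effective unit of tabulation is ambiguous); this
implementation is strictly report-level and does not attempt to
reverse-engineer the published tabulation.

What the generator does **not** emulate: realistic marginal FAERS term
frequencies, country-specific reporting styles beyond a categorical draw,
within-report correlation of reactions, dose information, therapy dates,
or duplicate records whose content differs between versions. Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the statistics under a faithful-but-idealized reporting process — not
robustness to every FAERS data pathology.

## Experiment sizes

The packaged statistical checks use: 1,000 random 2×2 tables against an
independently coded closed form (1e-10 relative agreement); 10,000 cases
with 40% labeled duplicates (half exact-date ties) for the deduplication
rule; 1,000 null studies of 20,000 reports for type-I control of the
signal criterion (expected flag rate ≈ 2.5–4% against the 5% bound — the
default confounding makes the crude null marginally exceed 1, so the
check is slightly conservative); 100 seeds × 50,000 reports for recovery
of an injected pair odds ratio of 3 (mean |ln error| < 0.05, CI coverage
0.90–0.99, and crude ROR = covariate-free logistic OR to 1e-6 on identical
records — the recovery configuration switches covariate effects off and
equalizes covariate distributions across arms so that non-collapsibility
does not move the marginal estimand away from the configured conditional
value). The acceptance script uses a 200,000-report demonstration study,
200 null studies and 30 recovery seeds.

## Known limitations

* Exact-match name normalization misses misspellings by design; the
  synonym list is the extension point.
* The explicit-missing covariate level is a pragmatic choice of unknown
  fidelity when missingness is informative.
* Wald intervals are used everywhere, including sparse adjusted fits where
  profile-likelihood intervals would behave better; suspected separation
  is flagged instead.
* Therapy-date overlap (THER) is not checked; co-reporting is treated as
  co-exposure.
* The OUTC/THER/RPSR/INDI tables are carried through but not analyzed.
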