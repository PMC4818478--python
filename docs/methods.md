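# Methods

## The triage rule

The classifier is a fixed decision table over four categorical answers:
request type (intervention/monitoring), comorbidity (4 ordinal strata),
functionality (3 Katz-ADL strata), and intuitive prognosis (3 strata). Rules
are evaluated priority-4 first, then priority-3, then the 1-vs-2 split on
request type; the stated conditions are mutually exclusive, so the precedence
order is a safety net rather than a tie-break. The rule is a pure function:
no state, no randomness, total over the 2×4×3×3 = 72 input combinations
(partition 18/18/16/20).

Two readings of the prognosis question's reach exist in the source material's
narrative: the normative one, implemented by default, restricts its effect to
advanced disease with preserved functionality (where a prognosis of death
separates priority 4 from 3); a broader reading also upgrades severe
functional dependency from 3 to 4 under a prognosis of death. The broader
reading is available behind `discussion_variant=True` (table partition
18/18/14/22) and is never the default.

A literal reading of the rules sends "no comorbidities with severe
dependency" to priority 1/2. The combination is clinically implausible (severe
ADL dependency without any comorbidity); it is flagged
(`TriageAssessment.is_clinically_implausible`, warned about by the CLI) but
not rejected, because the questionnaire does not forbid it.

"Prognosis of survival" means either survivor category, with or without
disabilities; the question only ever distinguishes survival from death.

## Reliability statistics

**Quadratic-weighted κ.** Agreement weights `w_ij = 1 − (i−j)²/(k−1)²` with
the category count `k` fixed explicitly (default 4), so categories a pair of
raters never used still shape the weights. κ = (P_o(w) − P_e(w))/(1 − P_e(w))
with chance agreement from the marginal products. Missing positions are
dropped pairwise; at least two retained positions are required. Identical
vectors score 1 even when both raters are constant. Chance agreement of
exactly 1 can only occur when both raters are constant on the same category —
i.e. identical vectors — so the "undefined κ" branch is a defensive guard; a
distinct-constant pair has a well-defined κ of 0.

**Pairwise aggregation.** The overall value for a panel is the unweighted
mean of all r(r−1)/2 pairwise statistics, reported with the median and a
25th/75th-percentile IQR (linear interpolation). The 95% CI for the overall
value is a seeded nonparametric bootstrap (default 2000 resamples) resampling
vignettes with replacement and recomputing the mean pairwise statistic; the
percentile interval is reported. Aggregation and CI method are package
choices — the field reports "overall κ" without fixing either — and both are
configurable. Pairs with no overlapping ratings are dropped and logged.

**ICC.** Average-measures intraclass correlation from a two-way model treating
the ordinal ratings as interval-scaled; the default is the consistency-type
coefficient (ICC(C,k) ≡ ICC3k), with absolute agreement (ICC(A,k)) via
`model="agreement"`. Computed with pingouin; the F-based 95% CI comes from the
same fit. Vignettes with any missing rating are dropped listwise (κ/percent
agreement use pairwise deletion instead, since a pairwise statistic loses
nothing from other raters' gaps). Zero between-vignette variance is an error
("no subject variance") rather than a NaN.

**Interpretation bands.** Landis–Koch verbal labels with boundaries assigned
upward (0.61 is "substantial").

## Validity statistics

Appropriateness judgments are a 4-level Likert scale dichotomized 1–2 vs 3–4
(non-scarcity setting) and a yes/no last-ICU-bed question (scarcity setting);
per-priority proportions keep exact numerator/denominator counts.
Denominators are always the records actually analyzed in the stratum.
Formatted percentages round half-up to one decimal, matching clinical
reporting convention, while JSON output carries full precision.

The trend test is Cochran–Armitage with equally spaced scores 1..r and no
continuity correction: `T = Σ s_i x_i − p̄ Σ s_i n_i`,
`χ²₁ = T² / (p̄(1−p̄)(Σ n_i s_i² − (Σ n_i s_i)²/N))`. It is invariant under
affine rescaling of the scores, equals the squared pooled two-proportion z
statistic for two strata, and equals N·r² for the Pearson correlation of the
expanded per-record data — the last two identities are the independent test
oracles. Degenerate tables (all outcomes identical, or zero score variance)
return statistic 0, p 1. Empty strata are excluded from both the rates and
the trend with a warning. Pearson χ² association uses scipy without
continuity correction after dropping zero-margin rows/columns.

## The simulator

The generator emulates the two arms of a triage-instrument evaluation study.

*Vignette arm.* Each vignette's latent questionnaire is drawn uniformly from
the decision-table combinations classifying to its target priority, so the
reference standard holds by construction (default 40 vignettes, 7/13/10/10).
A rater reads each question through a noisy channel: the latent answer is
kept with probability `question_fidelity` (scalar or per-question), otherwise
an adjacent category is substituted — reflecting at scale ends, flipping for
the binary question. Adjacent-category substitution, rather than uniform
resampling, reflects that vignette misreadings plausibly confuse neighboring
severity levels and gives smoothly tunable weighted-κ levels. The rule-based
priority is always the decision table applied to the rater's answers, never
stored independently. The intuitive priority is the reference priority passed
through the same adjacent-slip kernel with probability `intuition_noise`.
Appropriateness answers (Likert, last-bed) are Bernoulli draws indexed by the
vignette's reference priority, with defaults set to the published per-priority
proportions (appropriate: 1.00/0.94/0.952/0.671; last bed:
0.837/0.612/0.452/0.168); given the dichotomy, the Likert level is uniform
within {1,2} or {3,4}.

*Cohort arm.* 583 prioritized records (265/155/102/61) plus 20 records with
missing priority reconcile the published stratum counts with the published
total of 603; the missing-priority records are excluded from stratified rates,
mirroring how incomplete records are handled in practice. Outcomes are
independent per-record Bernoulli draws at per-priority default rates taken
from the published cohort (admission 0.652/0.632/0.569/0.525, mortality
0.355/0.276/0.461/0.661, palliative consultation 0.079/0.045/0.118/0.164);
missing-priority records use the cohort-wide marginal rates.

*Free parameters.* No empirical rater error model exists for this instrument,
so `question_fidelity` (default 0.9) and `intuition_noise` (default 0.4) are
free knobs chosen once: 0.9 puts single-question agreement in the
"substantial" range reported for well-defined closed questions, and 0.4
reflects that unaided ordinal prioritization by different physicians slips to
a neighboring class roughly half the time. Published κ point values are used
only as qualitative ordering checks (the rule-based track should out-agree
the intuitive track), never as point targets — they are not reproducible
without the original rating data.

*Determinism.* One documented seed per run; named child streams (vignettes,
raters, intuition, judgments, cohort) are spawned from a `SeedSequence`, so
identical configurations give bit-identical outputs and changing one arm's
parameters does not perturb another arm's draws.

## What passing tests show — and don't

The simulator reproduces the *statistical structure* of the study design
(sizes, marginal distributions, an ordinal error process), not real clinical
text or correlated physician behavior: raters err independently, outcomes are
conditionally independent Bernoulli given priority, and appropriateness
depends only on the reference priority. Recovery tests therefore validate the
statistical machinery and the pipeline's wiring, not the instrument's clinical
performance; population-level conclusions require real rater and cohort data.

## Numerical and scale choices

Percent formatting uses decimal half-up rounding (not banker's rounding).
Bootstrap resamples default to 2000; tests use smaller resample counts and a
down-scaled study (12 vignettes × 4 raters, 80-record cohort) where only the
pipeline's wiring is at stake, and large sizes (10⁵ per stratum, 100
replicates) where a law-of-large-numbers or ordering claim is. The
rate-recovery tolerance of one percentage point at n = 10⁵ corresponds to
about six binomial standard errors at p ≈ 0.5.

## Known limitations

- The agreement module covers two-rater statistics aggregated over pairs;
  Fleiss κ, Krippendorff's α, and Bland–Altman are out of scope.
- No multivariable adjustment or survival modeling: the criterion-validity
  analysis describes marginal rate trends only and cannot estimate the
  benefit of ICU admission within a priority stratum.
- The ICC treats ordinal 1–4 ratings as interval-scaled, as is conventional
  when reporting ICCs alongside weighted κ.
- The sample-size machinery of the original study design is not implemented.
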