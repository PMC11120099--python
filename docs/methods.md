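# Methods

## Score definitions and band conventions

The CPIS assigns 0–2 points to each of six items. The published band
definitions for the continuous items leave gaps (temperature 36.0–36.5 °C
and 38.4–38.5 °C are covered by no band), so continuous inputs are mapped
with half-open bands that partition the whole axis:

- **Temperature (°C):** ≤ 36.0 or ≥ 39.0 → 2; [38.5, 39.0) → 1;
  everything else (including the residual 36.0–36.5 gap, which sits on the
  clinically normal side) → 0.
- **Leukocytes (/mm³):** 4 000–11 000 inclusive → 0; outside that range →
  1, or 2 if band forms ≥ 500/mm³. Band forms alone never score: they only
  escalate an already abnormal count.
- **Oxygenation:** PaO₂/FiO₂ > 240 or ARDS → 0; ≤ 240 without ARDS → 2
  (a worse P/F in the *presence* of ARDS is attributed to ARDS, not to
  pneumonia — hence the asymmetry).
- Secretions, radiography and microbiology are 0/1/2 categorical ladders.

PCT points are 0/1/2 at < 0.5, [0.5, 1), ≥ 1 ng/mL, following the final
published score table (an earlier description numbered the same bands
1/2/3; the published table governs, and the composite ranges and the
cpis_pct ≥ 7 default cutoff are consistent with 0/1/2).

LUS findings score: consolidation type none/subpleural/lobar → 0/1/2; size
< 15 / 15–20 / > 20 mm → 0/1/2 (a numeric 20.0 mm falls in the middle
band); laterality bilateral/unilateral → 1/2; bronchogram static/dynamic →
1/3. Without a consolidation, size, laterality and bronchogram are
structurally `none` and contribute 0.

The ultrasound composites (`cpis_lus`, `cpis_plus`) **drop the radiography
component**: the published composite table has no radiography row, and the
adult precedents explicitly substituted the chest X-ray for ultrasound.
`cpis_pct` keeps the full CPIS. The resulting attainable ranges —
CPIS 0–12, LUS 0–9, CPIS-LUS 0–19, CPIS-PCT 0–14, CPIS-PLUS 0–21 — are
verified by exhaustive enumeration in the tests (the LUS sub-score cannot
attain exactly 1, because any consolidated exam scores ≥ 2).

Missing inputs (no PCT draw, no readable radiograph, no ultrasound exam)
make every composite that needs them undefined; nothing is imputed.
Undefined scores classify as `undetermined` and are excluded per score at
evaluation time, with exclusion counts reported.

Threshold rules are data, not code: the defaults are the published
operating points (`cpis > 6` — strictly greater — and `cpis_lus ≥ 12`,
`cpis_plus ≥ 12`, `lus ≥ 7`, `cpis_pct ≥ 7`), and any `name>=k` / `name>k`
rule within the score's attainable range is accepted.

## Contingency statistics and score derivation

Odds ratios use the cross-product estimate `ad/bc` with the Wald interval
`exp(log OR ± z·SE)`, `SE = √(1/a+1/b+1/c+1/d)`. This choice is not
arbitrary: it reproduces every published ultrasound OR and interval from
the printed counts to printed precision (e.g. lobar consolidation
15.7 [1.81–136]; dynamic bronchogram 266 [22.3–3168]). Tables with a zero
cell get the Haldane–Anscombe +0.5 on every cell, flagged `corrected` in
the result — unnecessary for the published tables, necessary for small
simulated cohorts.

Association p-values switch on the classical expected-count rule: Fisher's
exact test when any expected cell is below 5, otherwise Pearson χ² without
continuity correction. For r×2 tables with small expected counts the
Freeman–Halton exact generalization is computed by direct enumeration over
first-column row counts (cheap for r×2: the table probability factorizes
into binomial coefficients). Two published p-values (bilateral laterality
0.281, static bronchogram 0.048) are not reproducible from the printed
counts under either test and are not asserted anywhere.

Point derivation follows the log-odds-ratio rule: with per-level odds
ratios against the no-finding reference, one point is worth
`max(log OR)/max_points`; each level receives its log OR divided by that
unit, rounded half away from zero, clipped to `[0, max_points]`; reference
levels and levels with OR ≤ 1 get 0. Defaults cap the bronchogram at 3
points and the other features at 2, matching the published scale. On the
exact published counts this reproduces the published points everywhere
except the subpleural level, whose OR of 1.00 yields 0 points where the
published table assigns 1 — the rule admits no positive points for a null
association, and the discrepancy is surfaced deliberately rather than
patched. The rounding convention was chosen as the realization consistent
with the published bronchogram 1/3 and type –/2 pattern; the derived table
serializes to JSON and can replace the built-in table at scoring time.

## Diagnostic-accuracy machinery

Proportions (Sn, Sp, PPV, NPV) carry **Wilson score intervals**, chosen for
their small-sample coverage (the simulated coverage for a sensitivity of
0.78 at n = 49 is ~0.945 over 10⁴ replicates). A zero denominator makes
that metric undefined without poisoning the others.

The AUC is the Mann–Whitney concordance probability, computed from ranks
with half-credit for ties; it equals the trapezoidal area under the
empirical ROC (property-tested). ROC construction uses the "positive iff
score ≥ t" convention over observed score values; the strict `cpis > 6`
rule is handled at classification time, not inside the ROC.

DeLong's placement-value estimator supplies the AUC variance
(`Var = S₁₀/n₁ + S₀₁/n₀`, sample variances of the positive and negative
placement values), normal CIs clipped to [0, 1], and the paired test
`z = (AUC_A − AUC_B)/√(Var_A + Var_B − 2 Cov)` with the covariance taken
from paired placement values on the pairwise-complete patient subset.
Perfect separation gives zero variance: the CI degenerates to the point and
the paired test returns p = 1 by convention. The implementation is checked
against a hand-computed 4-patient example, a 2 000-replicate bootstrap CI
at n = 200 (agreement within 0.03 per bound), and a 10⁵-shuffle sign-flip
permutation oracle for the paired z.

Youden cut-offs maximize J = Sn + Sp − 1 by exhaustive search over
observed score values, ties broken toward the lowest threshold.

Group descriptives dispatch as χ²/Fisher for categorical variables, Welch
t-test for normal continuous ones, and the Mann–Whitney U (asymptotic,
tie-corrected) for skewed ones.

## Synthetic cohort generator

The generator emulates the study conditions: 108-patient default size,
confirmed-VAP prevalence 51/108, ultrasound performed with probability
49/51 in the VAP group and 35/57 in the no-VAP group (marginally exactly
84/108). Findings are sampled hierarchically per group: consolidation type
(none/subpleural/lobar) first; size, laterality and bronchogram
multinomials conditional on a consolidation being present; `type = none`
forces the rest to `none`. The conditionals are the published cross-tables
restricted to consolidated patients, which makes the generator's implied
marginal odds ratios equal the published ones exactly — so contingency
analysis on a large generated cohort recovers them (the tests require
agreement within ±0.26 log-OR at n = 10⁴).

PCT is lognormal per group, with parameters inverted from the printed
median/IQR (μ = ln median, σ = (ln q₃ − ln q₁)/(2·0.6745), the
least-squares solution of the two quartile equations with μ pinned). The
printed group summaries are internally consistent with a lognormal, which
motivates the family. Secretion categories and fever frequencies come from
the published group descriptives.

Temperature, WBC, P/F ratio, microbiology and radiography distributions are
**not identifiable** from printed summaries. They use simple two-component
group mixtures (febrile/afebrile normals weighted by the group fever
frequency; a leukocytosis-centred lognormal with a small leukopenic
component; low/high P/F normals) and plausible multinomials, chosen once so
that the group-mean CPIS lands near the published 6.6 vs 5.1 and every CPIS
band is populated; all are exposed in `GeneratorConfig` for override.

Features are conditionally independent given (group, consolidation type):
only marginal tables were published, so no richer dependence structure is
identifiable. Consequences worth knowing: real joint patterns (e.g. dynamic
bronchograms concentrating in large lobar consolidations) are not
reproduced, and composite-score distributions are somewhat smoother than a
real cohort's. Passing tests therefore demonstrate that the *machinery* is
correct and that the calibrated marginal structure is recovered — not that
the synthetic cohorts are clinically realistic in their joint behaviour.
Missingness is limited to the ultrasound exam indicator and an optional
missing-PCT probability (default 0) used to exercise the missing-data
contracts; missingness is independent of the outcome within each group's
exam probability.

All randomness flows from one `numpy` `default_rng(seed)`; identical
(config, n, seed) triples give byte-identical cohorts across runs.

## Problem sizes and numerical choices

The test suite and the acceptance script use cohorts of n = 300–500 for
AUC-ordering and paired-test replicates (100 seeds), n = 10⁴ for parameter
recovery, n = 10⁵ for law-of-large-numbers calibration, and 10⁴ replicates
for interval-coverage simulation — sizes at which the checked tolerances
(±0.26 log-OR; coverage in [0.93, 0.97]; ≥ 95/100 AUC ordering) are stable
across seeds. Floating-point ties in the Youden scan are broken with an
epsilon guard toward the lower threshold; CI levels map to normal quantiles
via `scipy.stats.norm.ppf`, never hard-coded 1.96.

## Known limitations

- The published cohort's patient-level results (its exact Sn/Sp/AUC rows)
  are not reproducible without the undeposited raw data; the package
  reproduces everything that printed counts determine and replaces the rest
  with property-based checks.
- The log-OR point-assignment rule is one consistent realization of a
  procedure whose exact recipe was not published (see the subpleural
  discrepancy above).
- The per-unit PCT odds ratio printed alongside the ultrasound tables
  (0.95 with a reversed interval) is on an unstated scale and cannot be
  recomputed from printed data; it is excluded everywhere.
- B-lines, pleural effusion and pneumothorax are accepted as pass-through
  CSV columns but are not scored, mirroring the published composite table.
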