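# Methods

## Model

A categorized attribute of a medical report takes one of `k` labeled values
`A_1, ..., A_k`; a report collection induces a probability distribution
`p = (p_1, ..., p_k)` over them. Diversity is measured through the
f-entropy

    H_f(p) = Σ_i p_i² f(1/p_i) + f(0) Σ_i p_i (1 − p_i),

where `f` is convex on `[0, ∞)` with `f(1) = 0` and `f(0)` is the limit
value at zero. `H_f` is a genuine diversity (nonnegative, minimal at a
degenerate distribution, maximal at uniform, symmetric, concave) when
`g(t) = (f(t) − f(0))/t` is concave; the package checks convexity and this
admissibility condition numerically on log-spaced grids (tolerance 1e-9), no
symbolic analysis. The admissibility grid covers `t ≥ 1` only, because the
f-entropy evaluates `f` at reciprocals `1/p_i` and at 0, never strictly
inside (0, 1); the Gini-Simpson hinge generator is concave in `g` exactly on
that range and has a convex kink at `t = 1`, so a full-line check would
wrongly reject it.

Derived quantities:

- **self f-diversity** `R_{f,i}(p) = p_i f(1/p_i) + f(0)(1 − p_i)` — the
  rarity of category `i`; `H_f(p) = Σ p_i R_{f,i}(p)` (verified as a
  property test to 1e-10 over seeded random distributions).
- **marginal f-diversity** — `H_f` of the dichotomy `(p_i, 1 − p_i)`.
- **relative** versions divide by the maximum: `H_f(u)` with `u` uniform
  over the same `k` labels, or `H_f((1/2, 1/2))` for marginals.
- **order-β rarity** `(1 − p^β)/β` (β ≥ −1; `−log p` at β = 0)
  interpolates the number-of-categories (β = −1), Shannon (β = 0) and
  Gini-Simpson (β = 1) rarities. The corresponding generator family is
  `f_β(t) = (t − t^(1−β))/β`, restricted to β ≤ 1 (above that `f(0)`
  diverges); the number-of-categories generator is `f(t) = (t − 1)²` with
  `f(0) = 1`, which reproduces the `(1 − p)/p` rarity and `H_f = k − 1`.
- **f-information** `Σ p(x)p(y) f(p(x,y)/(p(x)p(y)))` over a joint
  distribution is provided for completeness (zero at independence, Shannon
  mutual information for `f = t log t`) but is not used by the estimation
  pipeline.

Conventions for degenerate inputs: `0 log 0 = 0`; a zero-probability
category contributes nothing to sums it weights, but still counts toward
`k` and toward the uniform reference — the label set, not the support,
defines the attribute. Shannon self diversity at `p_i = 0` returns `inf`
rather than raising; Gini-Simpson self diversity there is the continuity
limit 1, computed as the numerical slope of `f` at infinity (error ~1e-13).
`relative_f_diversity` of a single-category attribute resolves the 0/0 to
0, the diversity floor; for the number-of-categories generator the relative
diversity is identically 1 for every `k ≥ 2`, a degenerate but correct
normalization. Logarithms default to base e and are configurable; relative
Shannon diversities are ratios and therefore base-free.

## Estimation and inference

Probabilities are estimated by empirical frequencies among *recorded*
reports — missing observations are excluded before estimation and enter
only recording rates (`100 · recorded / total`, half-up to one decimal) and
the count summaries. The diversity estimate is the plain plug-in value with
no finite-sample (`n/(n−1)`) correction; the plug-in reproduces the
reference tables below exactly at four decimals. Shannon-type diversities
are computed but deliberately excluded from estimation and testing: no
ideal (uniformly unbiased) estimator of Shannon diversity exists, so
inference is restricted to the Gini-Simpson type.

The variance of the Gini-Simpson plug-in estimate uses the delta method for
a multinomial sample:

    Var(Ĥ_GS) = (4/n) (Σ p̂_i³ − (Σ p̂_i²)²).

This formula is validated in the test suite against a nonparametric
bootstrap (2000 resamples, 20 seeded random truths, n = 1000): agreement is
within 15% relative error, with the caveat that the leading term vanishes
at the exact uniform distribution, where the estimator's variance is
O(1/n²) and the formula degrades. Normal 95% intervals built from it cover
the true diversity in 93–97% of 500 replicates at n = 10⁴.

Two collections sharing a label set are compared with
`Z = (Ĥ_a − Ĥ_b)/√(V_a + V_b)` against the standard normal, two-sided by
default (one-sided alternatives available); the scale factor `k/(k−1)`
cancels, so testing on the absolute or relative scale is identical.
Formatted output reports p-values below 1e-5 as `< 0.00001`. No
multiple-testing correction is applied across attributes. On the packaged
study counts this test flags seven of the eight attributes significant at
the 5% level, with Allergy not significant (p = 0.255) — the published
analysis of the same counts reports the same pattern, though its printed
p-values (e.g. Smoking 0.00073 where this implementation gets Z = 3.25,
p = 0.00115) do not match any variance estimator we tried; since the
published variance formula is unknown, only the significance pattern is
treated as reproducible.

## Packaged study counts

The fixture carries the per-attribute category counts of 110 narrative and
1119 structured Czech cardiology reports over eight MDMC attributes,
checksum-guarded. Two internal inconsistencies of the published summary
are preserved as data rather than silently repaired: the structured
Dyspnoea recorded count follows the per-category table (113 + 934 = 1047,
consistent with 72 missing of 1119) rather than the summary row's 934; and
the published structured number-of-categories diversities (3,2,2,2,2,1,1,1)
disagree with `k − 1` of the category sets used by every other published
table (3,2,2,1,1,1,1,1) for Dyspnoea and Chest pain, which are dichotomies
throughout the per-category tables. Computations here always derive `k`
from the category set; the printed values are exposed separately as
`structured_noc_printed`.

Narrative surface terms were never published (only their distinct-term
counts), so narrative fixtures exist at the count level only; term-level
behavior is exercised on synthetic collections.

## Term normalization and mapping

The normalizer is a deterministic, idempotent pipeline of independently
toggleable steps: Unicode-decomposition diacritic stripping, casefolding,
whitespace collapsing, repair of the digit 0 typed for the letter O inside
alphabetic tokens, and Roman→Arabic rewriting of standalone numeral tokens
("heart sounds II" → "heart sounds 2"). Single-letter tokens are never
treated as Roman numerals: in Czech clinical text "i" and "v" are the
conjunction *and* and the preposition *in*. Numeric-range and rounding
phenomena ("70-80", "around 70") are outside the categorical pipeline and
simply fail mapping.

Mapping of narrative terms onto canonical categories is an explicit curated
dictionary applied after normalization, never string-distance matching: the
original category assignment was manual, and fuzzy matching would fabricate
semantics. Unmapped terms are surfaced (counted separately and folded into
the missing total), never guessed. Tabulation preserves zero-count
categories and satisfies `Σ counts + missing + unmapped = n reports` by
construction.

## Synthetic generator

`generate_pair` emulates the study design: two collections drawn from the
same true category distribution per attribute, the structured one recording
canonical codes, the narrative one recording surface forms drawn from
per-category synonym lists and perturbed by the lexical phenomena above.
Perturbation probabilities in the default study-like configuration are
0.5 (diacritic dropping), 0.2 (abbreviation truncation), 0.05 (typo
injection — adjacent-character swap), 0.25 (case drift): plausible
free-text noise levels chosen once as defaults. Typos are deliberately the
one perturbation the generated mapping does not cover, so they exercise the
unmapped path; because the typo rate is category-independent, their
exclusion thins the sample without biasing the diversity estimate. The
default configuration uses the study's sample sizes (110/1119), true
probabilities equal to the structured plug-in frequencies, per-attribute
missingness rates from the study counts, and small invented Czech-flavored
synonym sets (synthetic — the study's own terms are unavailable).

Missingness is independent per attribute per report; an optional
informative mode makes reports of the modal category twice as likely to go
unrecorded (emulating unrecorded negative findings). Whether the study's
narrative missingness was informative cannot be determined from the
published information, so neither mode claims to match it. Both collections
read a common category stream by default (`share_draws`), so a degenerate
configuration — no perturbation, no missingness, equal sizes — yields
literally identical collections; independent draws are available by flag.
A single seeded generator drives each call; identical seed and
configuration give byte-identical serialized output.

What passing tests on synthetic data do *not* show: real narrative reports
have correlated attributes, informative missingness of unknown form,
richer synonym inventories, and free-text context the generator does not
attempt (no sentence structure, negation, or prose).

## Problem sizes and numerics

Property suites run on 200 seeded random distributions (k ≤ 8) at
tolerance 1e-10–1e-12; Monte-Carlo checks use 500 replicates at
n ∈ {10², 10³, 10⁴} and 100 generator seeds at n = 5000 per collection —
sizes at which the whole suite completes in well under a minute while
leaving the stochastic bands (93–97% coverage, 15% bootstrap agreement,
≥ 99% three-standard-error recovery) comfortably testable. Reported table
values round half-up to 4 decimals (percentages to 1); internal computation
is full double precision.

## Known limitations

- The asymptotic variance (and hence the Z test) is unreliable when a
  collection is nearly uniform over its categories or very small
  (n ≲ 30); the smallest study cell (Palpitations narrative, n = 17) is at
  the edge of normal-approximation comfort.
- The order-β generator family is implemented for β ∈ [−1, 1]; rarities
  are available for all β ≥ −1.
- Admissibility checking is numerical, on a finite grid; a generator
  violating convexity only between grid points would pass.
- The CLI exposes only the categorical pipeline; continuous attributes and
  free-text extraction are out of scope.
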