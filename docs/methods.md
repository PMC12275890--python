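# Methods

This note documents the statistical model behind `ddri`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical choices that affect results.

## Data model and preprocessing

One record is a laboratory result: analyte value, age in whole years, sex
(two-level, as the stratification requires), an administrative case id, and
up to five 3-character ICD-10 category codes (pattern letter + two digits).
Preprocessing keeps the first result per case (file order, or timestamp
order when available, with a stable tie-break), then removes records with
unknown sex, age outside 20–89, missing values, and values that are
non-positive or outside configurable analyte plausibility bounds (potassium
default 0.5–12 mmol/L — beyond any survivable physiology, so only unit or
entry errors are caught). Every removal is counted by reason and the counts
always sum to input minus output.

Malformed codes are dropped from a record's code list while the record
itself is kept: the measurement is still a valid data point for the Global
Distribution, only its diagnosis grouping is affected. A
`strict_code_filter` switch removes whole records instead, for sensitivity
analysis. De-duplication runs before the validity filters; the reverse
order would let an invalid first result resurrect a later duplicate.

Strata are sex × 10-year inclusive age bands (20–29 … 80–89; 14 strata).
The band width is configurable but must divide the 70-year span evenly.

## Per-code testing and FDR control

Each code group with more than 5 members is tested two-sidedly against the
full GD of its stratum. The GD deliberately *contains* the group — that is
the method's definition and is conservative (self-inclusion pulls the two
samples together); a `compare_to_complement` switch tests against GD minus
the group instead. All codes are tested against the original GD in a single
pass; removal is not sequential, so results are order-independent.

Test selection: Shapiro–Wilk at `normality_alpha` = 0.05 on the group and
on the GD (subsampled to 5 000 with a seeded generator when larger, which
bounds cost and keeps the test's p-value meaningful at huge n). Both pass →
Welch's t-test (unequal variances — a small diagnosis group against a whole
stratum makes the equal-variance assumption indefensible); otherwise
Mann–Whitney-U. Zero-variance groups are untestable for normality and fall
back to Mann–Whitney. The Mann–Whitney p is computed by exact enumeration
of all C(n₁+n₂, n₁) rank assignments when n₁+n₂ ≤ 16, using midranks, with
the two-sided p defined as the permutation probability of a U statistic at
least as far from n₁n₂/2 as observed (this coincides with the classical
exact two-sided p in the tie-free case and handles ties coherently); larger
samples use the tie-corrected normal approximation.

Q-values follow Storey–Tibshirani: π̂₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ = 0.05, 0.10, …, 0.90, smoothed by a cubic least-squares polynomial
evaluated at λ = 0.90, clamped to (0, 1]; q is the step-up transform
q(p₍ᵢ₎) = min_{j≥i} π̂₀ · m · p₍ⱼ₎/j. With fewer than 20 p-values the
smoother is unstable, so π̂₀ falls back to 1 with a logged warning — the
result is then exactly Benjamini–Hochberg, which is the conservative limit.
Removal significance is judged on q < α (default 0.05); a raw-p switch
exists for comparison.

The Differential Distribution removes a result if **any** of its codes is
significant; uncoded results always survive. Lowering α can only shrink the
removed set (monotonicity), and the removed/surviving partition is exactly
characterized by carrying/not carrying a significant code.

## Code clustering

Co-coded diagnoses on one result form a sentence (1–5 codes). A skip-gram
word2vec model with 5 negative samples embeds the codes; since gensim-style
training is not needed for such tiny vocabularies, the trainer is a compact
vectorized numpy implementation: mini-batches of 1024 (center, context)
pairs, batch-averaged gradients (stable even when a small vocabulary makes
the same rows recur many times per batch), linearly decaying learning rate
from 2.0, single-threaded and fully deterministic under its seed. Defaults:
dimension 100, window 5 (≥ 4 guarantees all pairs within a 5-code sentence
co-occur), 20 epochs, min_count 6 (aligned with the n > 5 testing filter),
noise distribution ∝ frequency^0.75.

Cosine similarity is converted to a distance as 1 − s (clamped at 0);
"inverting" a similarity matrix in the matrix-algebra sense does not yield
a metric and fails for singular matrices, so complementation is the
default, with arccos(s)/π available as `distance_mode="angular"`. Bottom-up
agglomerative clustering with average linkage on the distance matrix, cut
at k clusters (default 800, capped at vocabulary size), is the default;
k-means on the embedding vectors is the alternative. Codes too rare to be
embedded become singleton pseudo-clusters, so rare codes keep their
per-code behavior instead of silently escaping testing. A result belongs
to a cluster's value group if any of its codes is a member; testing,
q-values and removal then mirror the per-code pipeline exactly — with
k = vocabulary size the clustered pipeline reproduces the per-code removed
set identically. Clustering is fit per stratum, consistent with the slice
being tested; `k` has no automatic selection — it encodes how coarse a
comorbidity grouping the user considers clinically meaningful.

## Reference-interval estimation

The parametric estimator targets the main Gaussian mode of a (possibly
still contaminated) distribution. Iteration: compute the mean m and SD s of
the currently retained set, rescale s by the SD of a standard normal
truncated at ±trim_z (0.8712 at trim_z = 1.96) — skipped until something
has actually been trimmed — and retain values in [m − trim_z·s,
m + trim_z·s]. Windows are nested (values once trimmed are never
re-admitted), so n is non-increasing and convergence is monotone; the loop
stops when both endpoints move less than `tol` = 1e-4 or after `max_iter` =
50 iterations. The in-loop rescaling is what makes the procedure a fixed
point at the truth: trimming a clean N(μ, σ²) at μ ± 1.96 σ leaves a
truncated sample whose rescaled SD is again σ, so the window reproduces
itself. Rescaling only the final SD, with raw-SD windows during iteration,
would instead contract to a ±1.35 σ window and underestimate σ by ~21 % —
that variant is not offered. Limits are m ± z₀.₉₇₅·s with 90 % CIs from the
normal-theory quantile standard error s·√(1/n + z²/(2n)).

Known bias: under heavy one-sided contamination the equilibrium window
still retains the contaminant's lower tail. At 20 % contamination shifted
+3.4 σ with doubled SD, the recovered mode mean is biased upward by
≈ 0.08 σ (0.03 mmol/L at σ = 0.35). In the full pipeline the DDM removes
most contaminated results *before* RI estimation, which is why the
end-to-end recovery of healthy limits is an order of magnitude tighter than
the estimator alone under raw contamination.

The nonparametric mode takes the empirical 2.5th/97.5th percentiles of the
distribution itself. Quantiles use the Weibull (n+1)p plotting position
(the convention recommended for nonparametric reference limits; the choice
matters at small n and is fixed and documented for that reason). The 90 %
CI of a percentile is distribution-free: order statistics at ranks
n·p ± z₀.₉₅·√(n·p·(1−p)), rounded outward — slightly conservative
(measured coverage ≈ 91 % at n = 2 000 for p = 0.975). Sample-size floors:
a hard error below 120 values (the classical direct-method minimum) and a
logged warning below 5 000, the size at which indirect estimation from
mixed patient strata becomes reliable.

Verdicts compare each DD bound with its GD counterpart: disjoint 90 % CIs
→ `adjusted`; DD point estimate inside the GD CI → `not_different`;
otherwise `overlap`. The definition is deliberately asymmetric in the
point-containment clause (it asks whether the *new* estimate is
distinguishable from the *reference* one).

## Synthetic cohorts

The generator emulates a mixed inpatient population per stratum: a healthy
Gaussian core (potassium-like default: mean 4.0 mmol/L, SD rising linearly
0.35 → 0.45 across the age bands, echoing the variance growth seen in
older inpatients) plus disease components, each with a prevalence, a mean
shift, an SD scale factor, an optional lognormal shape (to exercise the
Mann–Whitney branch) and an optional comorbidity block. The default
contaminated mix assigns 25 % of results to eight disease codes in three
blocks (renal, cardio, metabolic) with shifts +0.4 to +1.2 mmol/L and
doubled SD — magnitudes patterned on what renal/cardiac/metabolic
subgroups do to potassium in practice. Block members are co-coded on the
same result with probability 0.35, giving the clustering step real
structure to find. Null "background" codes are attached to results
independently of health status, so their groups mirror the GD and must not
be flagged. Ground truth (healthy μ ± 1.96 σ per stratum, per-code
moments) is emitted alongside the data.

What the generator does **not** emulate: longitudinal within-patient
correlation, preanalytical artifacts (e.g. hemolysis), coding-practice
drift, age trends *within* a band, and realistic ICD frequency
distributions (codes are either disease markers or uniform background).
Passing tests therefore demonstrate the statistical machinery under the
stated mixture model, not performance on any particular hospital's data.

## Problem sizes and determinism

The validation suite exercises the pipeline at n = 20 000 per stratum for
contaminated-recovery checks (the scale at which a 25 % contaminated
stratum yields stable per-code groups), 200 strata for null FDR behavior,
2 000 replicates for CI coverage, and 10 seeds for clustering recovery —
sizes chosen so every property is measured with useful Monte-Carlo
precision while a full run stays in the minutes range on one core. All
randomness flows through explicit integer seeds: the generator, the GD
normality subsample, embedding training and k-means are all reproducible,
and identical config + seed reproduces pipeline output byte-for-byte.

## Known limitations

- Analytes whose healthy distribution is strongly non-Gaussian violate the
  mode-trimming model; only the test-selection step adapts to
  non-normality, the RI step does not (no Box–Cox family is offered).
- Codes present on fewer than 6 results are never tested individually;
  without clustering their results always survive into the DD.
- The q-value smoother needs ≥ 20 testable codes per slice; below that the
  procedure is BH, i.e. somewhat conservative.
- Verdicts inherit the usual caveats of CI-overlap reasoning; `overlap` is
  intentionally reported as "evaluate further", not as a decision.
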