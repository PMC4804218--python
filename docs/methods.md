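# Methods

## Scores and profiles

The TM-score of a domain pair for a fixed residue correspondence is

    TM = max over rigid superpositions of (1/L_norm) Σ_{i=1..L_ali} 1/(1 + (d_i/d0)²)

where `L_ali` is the number of aligned CA pairs, `d_i` the distance of
pair *i* after superposition, and `d0(L_norm) = max(1.24 (L_norm−15)^⅓ −
1.8, 0.5)` Å, the canonical size normalization. `L_norm` is the shorter
chain length in **local** mode and the mean length in **global** mode
(rounded half-up before `d0` is evaluated; the definition is on integer
lengths and half-up matches common practice). Local mode measures
substructure similarity; global mode penalizes length mismatch, which is
why "Russian-doll" pairs — one domain resembling a substructure of a
longer one — show local ≫ global scores.

Alignment search is deliberately out of scope: correspondences come from
input files or the synthetic generator, so the score is exactly
reproducible for given pairs. The maximization over superpositions is
deterministic: Kabsch superposition on every contiguous alignment
fragment (lengths `L_ali`, `L_ali/2`, `L_ali/4`, minimum 4, all offsets),
then up to 20 rounds of re-superposing on pairs closer than a cutoff
that starts at `d0` and grows by 0.5 Å whenever fewer than 3 pairs
qualify, until the included set is stable. Each refined candidate is then
polished by a majorize–minimize ascent on the score itself: `1/(1+u)` is
convex in `u = (d/d0)²`, so a weighted Kabsch step with weights
`1/(1+(d_i/d0)²)²` maximizes a tangent minorant and monotonically
increases the score to a stationary point. On small structures the result
matches an independent 6-dof numerical maximization to 1e-6 (tested).
Reflections are excluded in the Kabsch step by sign-correcting the
smallest singular value.

A fold's profile is the vector **x** of within-fold TM_max-scores (each
member's best score to any other member, self-matches excluded by
identifier). Folds with fewer than 25 members are excluded from
classification targets — below that the empirical distribution of x is
too sparse to characterize. Summaries use the sample (N−1) standard
deviation; the choice is immaterial at N ≥ 25 but fixed for
reproducibility. When a member is used as a query it is removed and the
profile rebuilt from the remainder. A tie for the partner domain
achieving the query–fold maximum is broken lexicographically.

## CEP

`CEP(s) = #{x_i ≤ s}/N` (inclusive). The query is assigned to the fold
with the highest CEP; ties are broken by higher query–fold TM_max, then
lexicographic fold id. The tie-break is a documented package choice —
nothing forces a particular rule, but one must be fixed for determinism.
Queries are classified independently; there is no joint reassignment and
no open-set option (every query is forced into some profiled fold).

## C3P: Bayesian mixture and posterior predictive

Within-fold TM_max-scores are modelled as a k-component Gaussian mixture
with unknown k under the Richardson–Green hierarchical priors:

| parameter | prior | default | role |
|---|---|---|---|
| k | Poisson(λ=1), truncated to 1..k_max (k_max=30) | — | number of components |
| π | Dirichlet(γ,...,γ), γ=1 | flat | mixture proportions |
| μ_j | Normal(ξ, κ⁻¹), ξ=median(x), κ=1/R² | data-scaled | component means |
| σ_j⁻² | Gamma(α, β), α=2 | — | component precisions |
| β | Gamma(g, h), g=0.2, h=10/R² | data-scaled | shared precision-prior rate |

R = max(x) − min(x) (floored at 1e-3 for degenerate constant data). The
mixture is untruncated: predictive draws outside (0, 1] simply count as
below or above a query score. k=0 is meaningless and the truncation at
k_max makes the Poisson prior proper; both bounds are required for a
well-defined reversible-jump sampler.

One sweep performs: Gibbs updates of π (Dirichlet full conditional), of
each (μ_j, σ_j²) (Normal and Gamma full conditionals; a μ draw that
breaks the mean ordering is rejected, keeping the ordered
parameterization), of the allocations z, and of β; then one split/combine
attempt and one birth/death attempt. Split proposals use the
moment-matching construction with u₁,u₂ ~ Beta(2,2), u₃ ~ Uniform;
combines merge only components adjacent in mean order. Acceptance ratios
are computed as log-joint differences plus proposal and Jacobian terms;
because components are kept mean-sorted, the ordering factor (k+1)
enters the trans-dimensional ratios explicitly. Birth draws an empty
component from the priors with weight ~ Beta(1, k) and weight-rescale
Jacobian (1−w*)^(k−1); death removes a uniformly chosen empty component.
Defaults are 30,000 iterations, 5,000 burn-in, thinning 5; everything is
reproducible from a single integer seed.

The posterior predictive of an unobserved score is estimated by Monte
Carlo: per retained draw θ, pick a component by π and sample its
Gaussian (one draw per retained sample by default; configurable).
`C3P(s)` is the fraction of predictive draws ≤ s. The variance-reduced
alternative `c3p_analytic` averages the mixture CDF `Σ_j π_j Φ((s−μ_j)/σ_j)`
over draws; both estimators agree within binomial Monte-Carlo error
(tested), and the analytic form is used by default in classification.
C3P is label-switching invariant by construction (a predictive quantity),
so no relabeling step is needed. Folds with fewer than 5 observations
cannot be fitted; callers fall back to the empirical CEP. Per-fold fits
are cached and reused across queries: the profile, not the query,
determines the posterior. In leave-one-out classification the mixture
fitted on the full profile is reused for each held-out member — refitting
per member would change nothing material (one of ≥25 points) at 25× the
cost; the repeated hold-out protocol, which removes whole query sets,
does refit per repeat.

## Hold-out protocol

Per repeat and per large fold, `max(1, floor(0.10·N))` members are
sampled without replacement as queries (rounding down per fold; at least
one per fold), profiles are rebuilt from the remainder, and each query
is classified by each method. Disagreement with the original
classification is summarized as mean ± SD over repeats. A fold that
would fall below 2 members is excluded from sampling with a warning.

## Synthetic universes

The generator produces classification tables and local/global score
matrices directly — the classifiers consume only scores, and direct
generation gives exact control over within/between score supports. The
within-fold TM_max distribution is then an order statistic of the
pairwise draws (the maximum of N−1 per member) and is *emergent*: its
mean sits roughly 2.3 pairwise-SDs above the pairwise mean and its
spread is proportional to (and several times smaller than) the pairwise
spread. Scores are clipped to (0.01, 1] — open below, as TM-scores are.

Two presets define the study conditions used by the tests and the
acceptance script:

* **discrete** — 8 folds × 30 members, within-fold pairwise scores in
  [0.80, 0.98] (Normal(0.88, 0.03) clipped), cross-fold scores in
  [0.15, 0.40]. Every fold-pair closeness is below every within-fold
  TM_max, so all classifiers must agree with the truth; the hold-out
  disagreement is exactly zero for TM_max, CEP and C3P.
* **continuum** — 10 folds × 40 members with anti-correlated mean/spread
  gradients (pairwise means 0.95→0.72 across the background folds with
  spreads 0.008→0.03, plus two markedly heterogeneous folds at means
  0.62/0.55 with spreads 0.095/0.13), and ten bridge domains from the
  two tightest folds aimed unevenly (6/4) at the two heterogeneous folds.
  Each bridge scores ~Normal(0.89, 0.005) to a single *anchor* member of
  its target fold — the member with the highest within-fold TM_max — and
  ~Normal(0.65, 0.01) to the rest. The anchor construction mirrors how
  continuity appears in real score data (a query's similarity to a fold
  is carried by one partner domain) and keeps the pull one-directional:
  the bridge's query–fold TM_max lands in the upper tail of the wide
  target distribution (high CEP) while no target member sees a score to
  the source fold above that fold's own tight support. The uneven 6/4
  split keeps fold-attraction counts untied so the rank correlation
  between fold heterogeneity (sd of x) and attraction count has a
  well-defined, small permutation p-value at 10 folds.

The numeric levels above were set from the order-statistics of the
emergent TM_max distributions so that the designed mechanism (bridges
reclassified into heterogeneous folds, nothing else moving) is realized
across seeds. What the presets do **not** emulate: real folds share
domains' evolutionary structure (scores are correlated through actual
geometry, not i.i.d. draws), fold sizes are heavy-tailed rather than
uniform, and alignment noise is score-dependent. Passing tests on these
universes therefore demonstrate correctness of the *classifiers and
protocol* under controlled continuity, not the empirical reclassification
rates of any real hierarchy, which depend on full database-scale score
matrices.

Toy structures for the geometry code are ideal α-helical CA traces
(rise 1.5 Å, radius 2.3 Å, 100° twist per residue) with i.i.d. Gaussian
coordinate noise and optional truncation to nested substructures.

## Evaluation

Reclassification counts queries whose assignment differs from the
original fold; the attracting fold is credited once per such query.
The heterogeneity–attraction rank correlation is Spearman's ρ between a
fold property (mean_x, sd_x or size) and attraction count, with folds
attracting zero queries included as zeros (excluding them changes ρ;
this is the documented choice), and a two-sided permutation p-value from
10,000 seeded label shuffles — exact asymptotics are unreliable at the
small fold counts of synthetic universes. Group-location comparisons
(Mann–Whitney/Wilcoxon) are thin conveniences over scipy.

## Numerical choices and limitations

* Score-table import keeps the maximum of asymmetric duplicate pairs
  (alignment programs are not perfectly symmetric; TM_max statistics
  consume the higher score) and warns.
* Mixture weights are floored at 1e-300 and precisions capped away from
  zero to keep log-densities finite; split proposals that violate the
  mean-order adjacency condition or produce non-invertible auxiliary
  variables are rejected outright.
* The sampler's split/combine acceptance rate is low (1–4%) on
  well-separated data — expected for Richardson–Green moves when the
  posterior on k is concentrated — but strictly positive; k mixing is
  verified by the recovery tests.
* Problem sizes in the test suite and acceptance script (universes of
  240–400 domains, 5 hold-out repeats, per-fold chains of 3,000–30,000
  iterations) were chosen so a full run completes on a single CPU in a
  few minutes while leaving Monte-Carlo error well inside the asserted
  tolerances; the mixture-recovery checks use the full default chain
  length.
* The package classifies against fixed fold profiles; it does not create
  new folds, detect outliers, or re-run structure alignment.
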