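# Methods

## Model and assumptions

`scbulk` models one gene at a time. A sample's cells belong to one of two
subsets: subset + (component distribution with mean μ₊) and subset −
(mean μ₋), with subset-+ proportion r. The single-cell value is the mixture
`y ~ r·f₊(y) + (1−r)·f₋(y)`, and the bulk measurement is
`Y = k·E[y] + e` — i.e. the bulk value is proportional to the mean of the
sample's single-cell distribution plus an additive, independent measurement
error with variance `v_err`. Across donors, μ₊, μ₋ and r are mutually
independent random variables with means (E₊, E₋, E_r) and variances
(V₊, V₋, V_r).

These assumptions matter and are enforced rather than implied:

- **Independence of (μ₊, μ₋, r).** No covariance terms are modelled; the
  closed-form variance is exact only under independence, which is also how
  the simulator draws donors.
- **Mean-proportionality of bulk.** Y carries no information about the shape
  of the cell distribution beyond its mean; this is why cell-to-cell
  variability (Vy₊, Vy₋) is absent from the closed-form bulk variance. At a
  finite number of cells n per sample it enters only through the sampling
  noise of the cell mean (see *Finite-cell correction*).
- **k = 1 in all closed forms.** The proportionality constant is kept in the
  simulator (`SimulationConfig.k`); comparisons against the closed forms
  rescale analytically (mean × k, biological variance × k²; the measurement
  error is added after k and is not rescaled).

Closed forms (module `model`):

- bulk mean `E[Y] = E_r·E₊ + (1−E_r)·E₋`;
- bulk variance `V[Y] = (E₊−E₋)²V_r + E_r²V₊ + (1−E_r)²V₋ + (V₊+V₋)V_r + v_err`,
  exposed term-by-term (`variance_bulk_terms`) because the first three terms
  are the distinct biological levers of differential variability;
- group shifts: group D has `E₊ + d₊(E₊−E₋)`, `E₋ + d₋(E₊−E₋)`, `α_r·E_r`.
  `ShiftParams` stores the *normalised* d±; `ShiftParams.from_absolute`
  converts from absolute expression shifts. The two conventions coincide
  whenever E₊−E₋ = 1, which holds in all bundled presets;
- mean difference
  `E[Y_D]−E[Y_C] = (E₊−E₋)(E_r(α_r−1) + α_r·E_r·d₊ + (1−α_r·E_r)d₋)` and its
  zero `α_r* = (1 − d₋/E_r)/(1 + d₊ − d₋)` (requires E₊ > E₋, E_r > 0,
  1 + d₊ − d₋ > 0; violations raise a `DomainError` naming the condition).
  The factored form and the bound are verified against the plain two-call
  difference of bulk means as an oracle identity in the tests, not trusted
  from transcription.

Validation is strict everywhere: proportions outside [0, 1], negative
variances, or α_r·E_r outside [0, 1] raise, never clamp. Silent clamping
would decouple the closed forms from the simulator and invalidate the
moment-matching tests.

## Simulator

Per group, N donors are drawn as μ₊ ~ Normal(E₊, V₊), μ₋ ~ Normal(E₋, V₋),
r ~ Uniform with mean E_r and variance V_r (bounds `mean ∓ √(3·variance)` —
the unique uniform with those moments; a support leaving [0, 1] is rejected
up front). The second parameter of every Normal is a **variance**, not an
SD; the SD convention would not reproduce the closed-form bulk variance.
Each donor contributes n cells from `r·Normal(μ₊, Vy₊) + (1−r)·Normal(μ₋, Vy₋)`
with the component chosen Bernoulli(r) **per cell** (not a fixed r·n split),
so finite-cell noise correctly carries the binomial term. The bulk value is
`Y = k·ȳ + e`, `e ~ Normal(0, v_err)`, drawn once per sample.

RNG design: one `SeedSequence` per `simulate_bulk` call, with separate
spawned streams for group-C donors, group-D donors, each donor's cells, and
the measurement errors. Changing `n_cells` therefore does not reshuffle
donor-level parameters, which the tests rely on.

**Finite-cell correction.** The sample variance of simulated Y exceeds the
closed form by `k²·E[V[y|donor]]/n`, where
`E[V[y|donor]] = E_r·Vy₊ + (1−E_r)·Vy₋ + (E_r−E_r²−V_r)((E₊−E₋)² + V₊+V₋)`.
`expected_bulk_moments` returns the corrected moments; at the preset sizes
(n = 10⁴) the correction is ~10⁻⁴ of the total, but at small n it dominates
and the tests verify it explicitly.

**Presets.** Preset 1 (proportion mechanism): E₊=2, E₋=1, E_r=0.9, V₊=1,
V₋=0.1, V_r=0.001, Vy±=1, v_err=0.1, d₊=d₋=0.5, N=1000 donors per group,
n=10⁴ cells — bulk variance falls 0.9131 → 0.2981 at equal means. Preset 2
(gap mechanism): same but V₊=V₋=0.01, d₊=10, d₋=0.1 — variance rises
0.1092 → 0.2275 (ratio ≈ 2.08). In both, α_r is *computed* from the
cancellation bound at preset construction (4/9 and ≈ 0.08155 respectively)
rather than hard-coded, so the equal-means construction holds to machine
precision.

A deterministic-limit subtlety: with all donor-level and cell-level
variances zero but 0 < r < 1, Y is not a constant at finite n — the per-cell
Bernoulli subset choice leaves the binomial lattice of cell means. The limit
is exactly deterministic only for r ∈ {0, 1} or n → ∞; the tests check both
facets.

## Parameter-space sweep

`sweep_grid` evaluates the closed-form mean and variance differences over
d₊, d₋ ∈ {0, 0.1, …, 1} × α_r ∈ {0.2, 0.5, 0.8} on the baseline E₊=2, E₋=1,
E_r=0.5, V₊=0.3, V₋=0.1, V_r=0.05. Measurement noise defaults to zero for
the sweep: it is additive and group-invariant, so it cancels in the variance
difference. Sign labels use a 1e−12 tolerance with exact zeros labelled
`boundary` instead of being forced into a side; grid points whose shifted
proportion leaves [0, 1] are recorded as `invalid` cells and the sweep
continues. The sweep calls the same `model` functions the rest of the
package uses — there is no reimplementation to drift.

## Estimation pipeline

1. **Normalisation** (`normalize_cells`): log(1+count) per entry, then each
   cell row rescaled to sum to 10⁶. All-zero cells are left at zero and
   flagged. This step targets count data; for data already on a continuous
   expression scale (e.g. the synthetic mixtures, which can be negative) the
   pipeline is run with `normalize=False`.
2. **Pseudobulk** (`pseudobulk`): per-sample mean over cells, one row per
   sample. Samples with no cells are an error, not an empty row.
3. **Filter** (`filter_genes`): keep genes with grand-mean pseudobulk
   strictly > 20 (default). The mean-proportionality assumption is
   technically unstable for lowly expressed genes, so filtering precedes
   testing, and BH correction is applied only to tested genes.
4. **Tests** (`de_dv_test`): per gene, Welch's unequal-variance t-test (DE)
   and a variance-ratio F-test (DV), both two-sided; BH correction applied
   separately to the t and F p-value vectors; flags at adjusted p < 0.05.
   The F-test is two-sided (`p = 2·min(P(F≤f), P(F≥f))`, capped at 1)
   because variability can move in either direction — the proportion
   mechanism above *lowers* it. Zero-variance edge cases are deterministic
   conventions, flagged as degenerate: both groups constant and equal → both
   p = 1; both constant but unequal → t p = 0; variance zero in exactly one
   group → F p = 0.
5. **Decomposition** (`decompose_sample`): for a chosen gene (by default the
   top DE and top DV genes by raw p-value), each sample's cell values are
   split into two clusters by 2-means in one dimension. Because optimal 1-D
   k-means clusters are intervals, the global optimum is the best of the
   n−1 threshold splits of the sorted values, found exactly with prefix sums
   in O(n log n). This replaces iterative Lloyd refinement entirely: the
   result is the certified global optimum, deterministic, with no
   initialisation or restart policy to document (the `seed` argument is
   accepted for interface stability and unused). The higher-centroid cluster
   is subset +; r̂ is its cell fraction. Samples with fewer than two distinct
   values degenerate to r̂ = 0 with both means at the common value, matching
   the convention that the zero/low-expression population is subset −. WSS
   ties between equivalent splits resolve to the smallest split index
   (largest subset-+ cluster).

**Decomposition accuracy.** Hard-threshold clustering misassigns the cells
that cross the midpoint between components, biasing μ̂₊ down, μ̂₋ up and r̂
toward the larger cluster. The contaminating fraction decays like the normal
tail of half the separation |μ₊−μ₋|/√Vy: recovery error is ≳ 0.08 at 5σ
separation and small r, < 0.02 from ~6σ, and negligible at 10σ. The tests
document this with a monotone three-point separation ladder and verify
per-sample recovery within 0.05 at 6σ and 10σ with n = 10⁴ cells.

## Synthetic data generator

`generate_dataset` assembles a cells × genes matrix gene-by-gene from
independent draws of the simulator's generative scheme, sharing sample/cell
indices, and returns per-(gene, sample) ground truth (realised μ₊, μ₋, r,
archetype label, closed-form group deltas). Each archetype's label is
validated against the closed-form mean/variance differences before any
sampling, so a mislabeled configuration fails loudly.

The default 20-gene panel is the package's reference condition: 16 null
genes plus one gene each of `de`, `dv_proportion`, `dv_shift` and `cancel`,
at 100 samples per group × 500 cells per sample. Expression baselines
(component means 22–35) are set so every archetype clears the > 20 filter;
the two DV genes transplant the preset-1/preset-2 mechanisms onto a 30/31
baseline (variance ratios ≈ 0.24 and ≈ 13 at the panel's pseudobulk level);
the cancel gene uses a 10-unit component gap (10σ at Vy=1) with d₊=0.3,
d₋=0 and α_r at the cancellation bound, so it is invisible to DE while the
decomposition cleanly shows μ̂₊ rising 35 → 38 and r̂ falling 0.6 → 0.46.

Values are continuous normal mixtures, matching the generative model, not
counts; `mode="truncate"` and `mode="counts"` provide nonnegative/integer
variants for I/O realism, with the altered fraction recorded in the ground
truth. These modes perturb the moments and are excluded from closed-form
comparisons.

**What passing tests show — and what they do not.** The generator emulates
the model's assumed structure: two normal components, independent donor
parameters, independent genes, no library-size variation, no dropout/
zero-inflation beyond what truncation induces, no correlation structure.
Pipeline results on these fixtures validate the statistical machinery and
the model-implied phenomena (DV without DE, cancellation); they do not
certify performance on real scRNA-seq data, where subset number, count
noise, and normalisation interact with all of the above.

## Numerical choices

- Tolerances: oracle identities asserted at 1e−10 relative; sign
  classification at 1e−12; Monte-Carlo checks at 4 standard errors with the
  SE of a sample variance computed from the sample's fourth moment
  (distribution-free asymptotic form).
- Problem sizes: tests run the presets at N = 1000 donors × n = 10⁴ cells
  (the preset definition) and the panel at 100 × 500; smaller sizes are used
  where the quantity under test does not need preset scale.
- The BH step-up convention relied on is pinned by a worked example
  ((0.01, 0.02, 0.03) → (0.03, 0.03, 0.03)) and the F-test against frozen
  `var.test` reference values computed in R.

## Known limitations

- Two subsets only; no covariance between donor parameters; no non-normal
  component distributions in the simulator (the closed forms themselves are
  distribution-free in the component shapes).
- The decomposition inherits hard-clustering bias at weak separation (see
  above) and always reports two clusters for ≥ 2 distinct values, even when
  one subset is truly absent.
- The pipeline's normalisation couples genes through the per-cell sum; on
  few-gene synthetic panels this distorts per-gene signals, which is why the
  reference panel is analysed unnormalised.
- Dense in-memory matrices: datasets are densified on load, appropriate for
  the fixture scale this package targets, not for atlas-scale matrices.
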