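# scbulk

A two-subset mixture model linking single-cell expression distributions to
bulk differential expression (DE) and differential variability (DV) analysis.

## The problem

Bulk RNA-seq measures, for each gene and sample, something close to the
*mean* of that sample's single-cell expression distribution. When a tissue
contains two cellular subsets — a subset "+" expressing a gene highly and a
subset "−" expressing it at a low level — group differences in bulk data mix
together two very different single-cell phenomena: *expression shifts within
each subset* and *changes in the subset proportions*. `scbulk` implements a
probabilistic model that makes this mixing explicit, and the analysis tools
that follow from it, for anyone interpreting DE/DV results on heterogeneous
tissue (or designing a single-cell study to disambiguate them).

## The model

Single-cell expression for one gene follows the mixture
`y ~ r·f₊(y) + (1−r)·f₋(y)` with component means μ₊, μ₋ and subset-+
proportion `r`. A sample's bulk value is `Y = k·E[y] + e = k(rμ₊ + (1−r)μ₋) + e`
with measurement error `e`. Across donors, (μ₊, μ₋, r) are independent random
variables with moments (E₊, V₊), (E₋, V₋), (E_r, V_r). With k = 1:

```
E[Y] = E_r·E₊ + (1−E_r)·E₋
V[Y] = (E₊−E₋)²·V_r + E_r²·V₊ + (1−E_r)²·V₋ + (V₊+V₋)·V_r + V[e]
```

A disease group shifts the component means by d₊, d₋ (normalised by E₊−E₋)
and scales the expected proportion by α_r, giving the closed-form bulk mean
difference

```
E[Y_D] − E[Y_C] = (E₊−E₋)·( E_r(α_r−1) + α_r·E_r·d₊ + (1−α_r·E_r)·d₋ )
```

which is zero exactly at `α_r* = (1 − d₋/E_r) / (1 + d₊ − d₋)`: a positive
expression shift at the single-cell level can be perfectly cancelled by a
proportion decrease and become invisible to DE analysis — while still moving
the bulk *variance*, which is what DV analysis detects. Notably, cell-to-cell
variability within a subset does not appear in `V[Y]` at all.

## What the package provides

- `scbulk.model` — the closed forms above, with the variance itemised into
  its five additive terms and strict parameter validation.
- `scbulk.simulate` — the two-group generative simulator (donor-level
  Normal/Uniform draws, per-cell mixture draws, bulk = cell mean + error),
  with two presets producing DV without DE: a proportion change that
  *lowers* the bulk variance (ratio ≈ 0.33) and a gap widening that *raises*
  it (ratio ≈ 2.08), both at exactly equal group means.
- `scbulk.grid` — the 11×11×3 sweep over (d₊, d₋, α_r) producing the paired
  sign maps of the mean and variance differences.
- `scbulk.estimation` — the analysis pipeline: log1p + per-cell sum
  normalisation to 10⁶, pseudobulk (per-sample cell mean), a strict > 20
  grand-mean expression filter, Welch's t-test (DE) and a two-sided
  variance-ratio F-test (DV) with Benjamini–Hochberg correction at 5% FDR,
  and an exact 1-D 2-means decomposition of each sample's cell values into
  (μ̂₊, μ̂₋, r̂).
- `scbulk.fixtures` — multi-gene synthetic datasets with per-donor ground
  truth, built from labelled gene archetypes (null / de / dv_proportion /
  dv_shift / cancel) that are validated against the closed forms.
- `scbulk` CLI — `simulate`, `grid`, `test`, `decompose`, `fixtures`
  subcommands over Matrix Market + CSV inputs, each writing a JSON run log.

## Worked example

```python
import scbulk as sb

gp = sb.GroupParams(e_plus=2.0, e_minus=1.0, e_r=0.9,
                    v_plus=1.0, v_minus=0.1, v_r=0.001)
noise = sb.MeasurementNoise(0.1)
print("E[Y] control:", sb.expected_bulk(gp))           # 1.9
print("V[Y] control:", sb.variance_bulk(gp, noise))    # 0.9131

alpha = sb.cancellation_alpha_bound(gp, 0.5, 0.5)
print("cancellation alpha_r:", alpha)                  # 0.4444...
shift = sb.ShiftParams(0.5, 0.5, alpha)
gp_d = sb.apply_shift(gp, shift)
print("E[Y] disease:", sb.expected_bulk(gp_d))         # 1.9  (equal means)
print("V[Y] disease:", sb.variance_bulk(gp_d, noise))  # 0.2981

gp1, shift1, cfg1 = sb.preset_example(1, seed=7, n_samples=500, n_cells=2000)
data = sb.simulate_bulk(gp1, shift1, cfg1)
yc, yd = data.values("C"), data.values("D")
print(f"empirical mean C/D: {yc.mean():.3f} / {yd.mean():.3f}")
print(f"empirical var  C/D: {yc.var(ddof=1):.3f} / {yd.var(ddof=1):.3f}")
```

prints

```
E[Y] control: 1.9
V[Y] control: 0.9131
cancellation alpha_r: 0.4444444444444444
E[Y] disease: 1.9
V[Y] disease: 0.2981
empirical mean C/D: 1.859 / 1.920
empirical var  C/D: 0.898 / 0.314
```

Both groups have the same expected bulk mean (1.9), yet the disease group's
bulk variance drops from 0.9131 to 0.2981 because the high-variance subset's
proportion fell from 0.9 to 0.4 — a pure DV signal with the single-cell
expression of both subsets *increased* by 0.5. The simulated samples
reproduce both moments within Monte-Carlo error.

The same from the shell:

```
scbulk simulate --preset 1 --seed 7 --out bulk.tsv
scbulk grid --out grid.tsv
scbulk fixtures --seed 1 --out fix/
scbulk test --matrix fix/matrix.mtx --genes fix/genes.tsv --cells fix/cells.csv \
            --no-normalize --out results/
```

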