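# dermabs

Derivation of **default dermal-absorption values** for plant-protection
products from in vitro human skin studies.

When an applicant submits no substance-specific dermal-absorption study,
risk assessors fall back on default values: regulatory percentages of the
applied dose assumed to reach systemic circulation. `dermabs` implements
the two statistical routes used to derive such defaults from a collection
of in vitro absorption experiments:

1. **Empirical route** — per category, the sample 95th percentile of the
   observed absorption fractions and its distribution-free upper 95%
   confidence limit, taken as the *k*-th order statistic with *k* the
   smallest integer satisfying `BinomialCDF(k; n, 0.95) ≥ 0.95`.
2. **Model route** — a Bayesian Gaussian linear mixed model on the
   logit-transformed fraction absorbed,

   ```
   logit(f_i) = α + β_C·C_i + β_O·O_i + β_S·S_i + β_W·W_i
                + b_{substance(i), status(i)} + u_{study(i)} + w_{group(i)} + ε_i

   (b_dilution, b_concentrate)' ~ N₂(0, G),   u ~ N(0, σ²_study),
   w ~ N(0, σ²_within),                        ε ~ N(0, σ²_e)
   ```

   with dilution and organic-solvent as reference categories, a random
   slope for substance within concentration status (status-specific
   between-substance variances `σ²_{S:D}`, `σ²_{S:C}` and their
   correlation ρ), a study intercept and a within-study group intercept
   (replicates of the same applied concentration of the same substance in
   the same formulation type within the same study). The default-value
   candidate for a cell is the upper 95% limit of the 90% prediction
   interval, per posterior draw

   ```
   100 · inv_logit( lp + Φ⁻¹(0.95) · √V ),   V = σ²_{S:status} [+ σ²_study] [+ σ²_within]
   ```

   summarised by its posterior median and, most conservatively, its 95th
   percentile. Inference is a fully conjugate blocked Gibbs sampler (joint
   multivariate-normal location update; inverse-Wishart for `G`; scaled
   inverse-χ² for the scalar variances), bit-reproducible given a seed.

Records are classified into eight cells — four formulation-type categories
(organic solvent, water-based, solid, other) × concentrate/dilution — under
either the *commercial* definition (undiluted product) or the *SCoPAFF*
cut-off definition (> 50 g/L, or g/kg for solids), and the package
tabulates how the derived defaults change between the two.

Preprocessing follows the harmonised evaluation rules: experiments with
mean mass-balance recovery outside [90%, 110%] are excluded; absorption is
*potential* absorption (receptor fluid + chamber wash + whole skin + tape
strips, where all strips are excluded if ≥ 75% of material was absorbed by
half the sampling duration, and only strips 1–2 otherwise).

## Worked example

Plug-in evaluation at the published posterior-mean estimates for the
BfR2024 dataset:

```python
>>> from dermabs import BFR2024_POSTERIOR_MEANS, mean_prediction, pi_upper
>>> draw = BFR2024_POSTERIOR_MEANS.pseudo_draw()
>>> float(mean_prediction(draw, status="dilution")[0])
8.786391482930126          # mean absorption of dilutions, % (reference cell)
>>> float(pi_upper(draw, "dilution", "organic_solvent", "substance+study+within")[0])
48.18265738810758          # upper 90%-PI limit, all three variance levels, %
```

So an average dilution in an organic-solvent formulation absorbs ≈ 8.8% of
the applied dose, while the default-value candidate covering new
substances, new studies and new concentration groups is ≈ 48%.

Full pipeline on synthetic data with known truth (reduced scale, balanced
categories):

```python
>>> from dermabs import SyntheticTruth, generate_logit_dataset, DermalAbsorptionLMM
>>> truth = SyntheticTruth.reduced(n_substances=25, seed=7,
...     cell_weights={c: 1.0 for c in SyntheticTruth().cell_weights})
>>> prepared, effects = generate_logit_dataset(truth)   # 1162 replicates
>>> res = DermalAbsorptionLMM(prepared).fit(draws=600, burnin=250, seed=42)
>>> print(res.summary().round(2))
                           mean  hpdi_2.5  hpdi_97.5     ess
parameter
alpha                     -2.60     -3.33      -1.88  505.51
beta_concentrate          -1.83     -2.39      -1.19  598.31
beta_other                 0.16     -0.72       1.04  326.19
beta_solid                -0.93     -1.67      -0.01  600.00
beta_water_based          -1.53     -2.50      -0.53  473.43
var_substance_dilution     0.61      0.07       1.28   94.70
var_substance_concentrate  0.48      0.10       1.05  123.58
var_study                  0.64      0.28       0.97  145.95
var_within                 0.68      0.44       0.97  118.59
rho_substance             -0.21     -0.76       0.41   73.62
```

The generating values (`alpha = -2.34`, `var_study = 0.67`, …) sit inside
every 95% HPDI. `res.prediction_table()` then yields the 8 × 3-level
default-value table in percent, and
`dermabs.empirical_table(prepared)` the order-statistic route.

A command-line interface mirrors the stages:

```sh
dermabs simulate --n-substances 40 --seed 1 --out records.csv
dermabs preprocess records.csv --definition commercial --out prepared.csv
dermabs empirical prepared.csv --out empirical.csv
dermabs fit prepared.csv --seed 1 --out draws.csv --summary-out params.json
dermabs predict draws.csv --out defaults.csv
dermabs report --out results_dir        # everything incl. SCoPAFF comparison
```

## Layout

- `dermabs.dataset` — record schema, formulation categorisation,
  concentrate definitions, plausibility checks
- `dermabs.preprocessing` — recovery filter, tape-strip rule, potential
  absorption, logit table
- `dermabs.empirical` — percentiles and order-statistic confidence limits
- `dermabs.model` / `dermabs.prediction` — the mixed model, Gibbs sampler,
  prediction intervals and summaries
- `dermabs.simulate` — synthetic-data generator with known ground truth
- `dermabs.report` / `dermabs.cli` — pipeline orchestration and CLI

See `docs/methods.md` for modelling assumptions, priors, numerical choices
and known limitations.
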