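# Methods

## Data model and curation

A measurement couples a monoatomic cation (element symbol + charge >= +1),
a ligand (SMILES, canonicalized with RDKit before any keying, plus its
molecular charge in aqueous solution), a coordination count n >= 1, the
overall stability constant beta_n on the log10 scale, and the conditions
(temperature in °C, ionic strength in mol/L). Polyatomic cations such as
NH4+ or UO2+ are out of scope.

Curation applies two fixed rules:

* **Exclusions.** Records are dropped when the cation is one of the heavy
  actinides Am, Cm, Cf, Bk, Es, Fm, Md, or when the ligand contains any of
  Te, Se, As, Mn, Co, Fe, W, Mo, Cr, Re — elements for which reliable
  molecular descriptors cannot be built. Every dropped record carries a
  machine-readable reason, and kept + dropped is an exact partition of the
  input.
* **Duplicate resolution.** For each (cation, canonical ligand, n) key one
  record survives, chosen by condition priority: (1) 25 °C and
  I = 0.1 mol/L, (2) 25 °C and any I, (3) any temperature and
  I = 0.1 mol/L, (4) everything else; within the winning tier the largest
  beta wins, and an exact tie keeps the first-seen record so the result is
  deterministic in input order. Because reported conditions are rounded,
  tier membership uses |T − 25| <= 0.5 °C and |I − 0.1| <= 0.005 mol/L.

## Descriptors

The beta_1 descriptor concatenates three blocks per record:

* **Cation (12 features):** charge, atomic number, melting point (K),
  molar specific heat capacity (J/mol·K), ionic radius (pm, Shannon, for
  the given charge), polarizability (Å^3), electron affinity (eV), Pauling
  electronegativity, and the number of unfilled electrons in the s, p, d
  and f frontier subshells of the ion. A curated reference table for 36
  common cations ships with the package; any table with these columns can
  be substituted (the synthetic generator provides its own).
* **Ligand:** RDKit's 2-D descriptor set (~210 compositional and
  topological descriptors; no 3-D geometry) plus the molecular charge in
  aqueous solution. Descriptor failures become missing values.
* **Conditions:** temperature and ionic strength.

Ligand features pass a fixed three-stage pruning pipeline before
assembly, in this order:

1. `drop_degenerate` removes any column that is constant or contains a
   missing value. A missing value removes the column, not the row,
   because descriptor failures are molecule-specific and silently
   shrinking the dataset would be worse than losing one feature.
2. `correlation_filter` scans ordered column pairs (i before j) and drops
   j whenever |Pearson r(i, j)| > 0.7 with both still present — the
   earlier column wins. The comparison carries a 1e-12 guard so a pair at
   exactly the threshold is kept (the rule is a strict inequality).
3. `vif_filter` iteratively removes the column with the largest variance
   inflation factor, VIF_k = 1/(1 − R²_k) with R²_k from an
   intercept-included regression of column k on the survivors, until all
   VIF < 4. Perfect collinearity is treated as infinite VIF and removed
   first.

All descriptors are z-scored with statistics from the fit rows only; the
metadata (per-column mean and scale) travels with the table so held-out
rows, new predictions and inverse transforms always use fit-set
statistics.

## Gaussian-process regression

Both stages use exact GP regression with the ARD Matérn-3/2 kernel

    k(x_i, x_j) = sigma^2 (1 + sqrt(3) r_ARD) exp(-sqrt(3) r_ARD),
    r_ARD = sqrt( sum_m (x_im - x_jm)^2 / l_m^2 ),

zero prior mean on internally standardized targets, a *learned* Gaussian
observation-noise variance, and a fixed diagonal jitter of 1e-8
(escalated tenfold on factorization failure, erroring past 1e-2 with the
eigenvalue range reported). A noise term is essential: stability
constants carry real experimental scatter of a few tenths of a log unit,
and exact interpolation of noisy targets would be wrong and numerically
fragile. The noise variance can be pinned (e.g. to zero for
interpolation checks).

Hyperparameters (sigma^2, l_1..l_d, noise) maximize the log marginal
likelihood by L-BFGS in log-parameters with analytic gradients;
`n_restarts` (default 5) starts are used, the first from a fixed default
(sigma^2 = 1, l_m = sqrt(d), noise = 0.1) and the rest drawn
log-uniformly (sigma^2 in [0.1, 10], l_m in [0.3, 30], noise in
[1e-4, 1]) from a generator seeded by the run seed, so fits are exactly
reproducible. Dense Cholesky factorization puts the practical ceiling
near 10^4 rows; a `max_rows` switch takes a seeded uniform subsample for
larger inputs, and the reference experiments below state the sizes they
use.

Predictions are de-standardized posterior means; reported standard
deviations include the noise variance by default (the error bar of a new
*observation*), with `include_noise=False` giving the latent-function
uncertainty.

## KL-divergence sensitivity analysis

Relevance of feature m is measured by perturbing column m of the
evaluation rows (default: the training rows) by +delta = 0.001 in
standardized units and averaging, over rows, the divergence
KL(unperturbed || perturbed) between the univariate predictive Gaussians.
Raw scores are normalized to sum to 1 ("standardized relevance") and
ranked descending. Choices the measure leaves open and how they are
fixed here: forward KL from the unperturbed distribution, a positive
one-sided delta, arithmetic mean over rows. Delta acts in standardized
units — in raw units a fixed 0.001 would mean different things for
different descriptors. A summed KL below d·1e-16 raises "model
insensitive to all features" (floating-point KL is never exactly zero).

## Validation-ligand selection and feature-count optimization

Cross-validation over records would leak ligands between training and
validation, overstating generalization to new molecules. Instead whole
ligands are held out, biased toward the *edge of the applicability
domain*: per ligand, the mean ARD distance to all other ligands is
computed in the standardized ligand-feature space, ligands are split
into five quantile strata of that distance, and the requested count
(default 20) is sampled near-uniformly across strata with the top
(most distant) stratum guaranteed at least 4 picks and the single most
distant ligand always included. The selection is seeded and
deterministic.

Feature-count optimization refits the GP on the top-k ranked features
for each k in a grid (default: every k up to min(d, 20) plus multiples
of 5 up to d) and picks the k minimizing validation MAE, ties toward
smaller k; failed fits are recorded and skipped.

## The cascade

The beta_n (n >= 2) descriptor starts with four cascade features —
predicted beta_1 of the record's M–L pair at the record's conditions,
the 1-sigma uncertainty of that prediction, the complex charge
(cation charge + ligand molecular charge) and n − 1 — followed by the
ligand features the final beta_1 model does not use. Predicted beta_1 is
always a model output, never a lookup: many multi-order pairs have no
measured beta_1 at all.

During training, beta_1 features for the stage-two records are generated
*out of fold*: the n = 1 records are split into 5 folds, each fold's
posterior is recomputed (at the full model's hyperparameters, without
re-optimizing) on the other folds, and a stage-two record whose pair has
an n = 1 record in fold f receives the fold-f-excluded prediction. This
prevents the stage-two model from learning on optimistically in-sample
beta_1 fits while keeping the step a single extra factorization per
fold. At inference the full beta_1 model is used.

Stage-one relevance-based feature selection is part of the fit
(`CascadeConfig.select_features`, on by default): a probe GP on the
training ligands ranks features by KL sensitivity and the count is
optimized on the held-out validation ligands, with the probe and the
per-k refits running on a seeded subsample (default 500 rows) to keep
the selection loop tractable. Runs that only compare the cascade to its
ablation disable selection so both arms see identical descriptors.

The universal thermodynamic inequality beta_{n−1} < beta_n < n·beta_1
(a consequence of K_1 > K_2 > ... > K_n) is implemented as a QC check
over (cation, ligand, conditions) families, flagging monotonicity and
upper-bound violations separately.

## Synthetic data

The generator emulates the statistical shape of a large curated
stability-constant compilation while planting known structure:

* **Cations:** ion labels are sampled from a pool of 64 real
  (element, charge) combinations, none excluded; charge and atomic
  number are real, the other ten features are drawn from realistic
  element ranges. Defaults: 57 cations.
* **Ligands:** a deterministic template grammar — donor heads/tails
  (amine, hydroxyl, carboxyl) joined by alkyl linkers with optional
  ether/secondary-amine mid-chain donors — yields ~4,900 distinct
  canonical SMILES, so fragment counts such as −NH− and −O− vary
  meaningfully. Aqueous molecular charge is −1 per carboxylic-acid
  group. Defaults: 2,706 ligands, each paired with 5 cations, which puts
  the record counts at the scale of the real compilations (~13.5k n = 1,
  ~7k n >= 2).
* **Constants:** log K_1 = 2.5·chi(M) + 1.2·q(M) + 0.8·donors(L) −
  1.5·charge(L) − 2 (+ a mild chi×charge interaction when `nonlinear`)
  + N(0, noise_sd), shifted/clipped at 0.1 so it is positive;
  noise_sd defaults to 0.5 log units, typical of experimental scatter.
  Stepwise constants decay geometrically, log K_i = rho^{i−1} log K_1
  with rho ~ U(0.3, 0.8) per pair, so every family satisfies
  beta_{n−1} < beta_n < n·beta_1 *by construction*. The maximum n per
  pair follows (0.60, 0.18, 0.10, 0.07, 0.03, 0.02) for n_max = 1..6,
  mirroring the rapid decay of multi-order data in real compilations.
* **Duplicates:** with probability 0.1 a pair also emits a complete
  off-condition family (shifted K_1, same rho), internally consistent
  and guaranteed to lose the tier-1 priority contest, exercising
  duplicate resolution.

What the generator does *not* emulate: negative beta_1 values (real
compilations contain some; positivity is required for the geometric
construction), the real beta_n distribution shape beyond order of
magnitude, condition-dependent systematic shifts, and real descriptor
noise — the planted signal lives in entity-level quantities (donor
counts, charges, electronegativity) that the RDKit descriptors can
represent. Passing tests on this data therefore demonstrate pipeline
correctness and the recoverability of planted structure, not predictive
accuracy on laboratory measurements.

## Reference experiment sizes

The standing experiments (`stabgp.benchmarks`, also run by
`scripts/acceptance.py`) use sizes chosen to be informative on a single
CPU: posterior-vs-direct-solve checks at n = 50, d = 5 over 10 seeds;
planted-relevance recovery at n = 300, d = 10 with 3 active features
over 10 seeds; and the cascade-vs-ablation comparison on datasets of 30
cations × 400 ligands (≈1,600 multi-order records, 30 % of ligands held
out) over 5 seeds, with GP fits subsampled to 500 rows, 2 restarts and
100 optimizer iterations. The ablation refits the stage-two GP on the
same descriptor minus the predicted-beta_1 value and uncertainty
columns.

## Known limitations

* Exact GPs scale cubically; beyond ~10^4 rows only the subsampling
  switch is offered (no inducing-point approximations).
* The applicability-domain selection rule (quantile strata over mean ARD
  distance) is one defensible reading of "near the edge of the
  applicability domain"; other rules would select different validation
  sets.
* The bundled cation table covers 36 common ions; records with other
  cations need a user-supplied table.
* No Bayesian-optimization ligand search is included; the uncertainty
  outputs are designed to support one.
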