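# Methods

## Scope and model

`nanoqstr` models cell viability (%, A549 human lung epithelial cells)
as a function of metal-oxide nanomaterial composition and exposure: a
tabular regression problem with one row per (ENM, concentration)
condition. The learners are CART-family tree ensembles — a single
decision tree (DT), a random forest (RF) and extra-trees (ET) — because
the relationship is dominated by categorical composition attributes and
their interactions with dose, and tree models capture those without a
specified functional form while staying interpretable. Tree induction
is delegated to scikit-learn; the package owns the pipeline around it:
descriptor engineering, train-frozen pre-processing, selection, the
QSAR validation metric suite, the applicability domain and the
leak-free orchestration.

Assumptions worth stating explicitly:

* each row is one independent observation (replicate wells, if any
  underlie a viability value, are not modelled);
* viability is a percent of control, bounded below by 0 and unbounded
  above (values > 100 % are genuine hormetic/stimulation readings);
* composition labels are parseable chemical formulas plus controlled
  doping/coating vocabularies with explicit sentinels (`ND`, `NSC`).

## Pre-processing

The stage order is fixed and validated: diameter filter → one-hot
encoding → descriptor build → z-score → Yeo-Johnson. Two deliberate
choices:

* **Variance filter before standardization.** A variance threshold is
  meaningless after z-scoring (every column has unit variance), and
  z-scoring is undefined on constants; the low-variance drop therefore
  runs on the raw training matrix, before Eq. X′ = (X − µ)/σ.
* **Train-frozen parameters.** One-hot level maps, µ/σ, Yeo-Johnson λ,
  filter decisions, importances and models are all fitted on the
  training rows only and applied frozen elsewhere. Fitting transforms
  on all rows before splitting would leak test/unseen statistics into
  the fitted state; a `fit_subset` tag on every `TransformState` records
  what the state saw. z-scores use the population SD (ddof = 0, the
  classic z-score convention; configurable).

One-hot indicator columns are excluded from z-scoring and Yeo-Johnson
by default — Gaussianizing a binary indicator is not meaningful.

The Yeo-Johnson λ is the per-column maximum-likelihood estimate
(scipy); tests verify it against a brute-force λ-grid (step 0.001)
oracle to within 0.05.

## Split protocol

From the filtered dataset, `n_unseen` = 33 rows are withheld first to
simulate prospective data; the remainder is split 70/30 into training
and test with `test = round(test_frac · n_remaining)` (documented
because 30 % of 300 is exact but other sizes round). At study scale:
333 → 33 unseen / 210 train / 90 test.

## Descriptor families

* **raw** — diameter (nm), concentration (µg/mL);
* **onehot** — `core_*`, `dop_*`, `coat_*` indicators;
* **elemental** — constants of the core's *active metal*, defined as
  the metallic element of the formula (largest stoichiometric count,
  ties to the higher atomic number; semimetals such as Si never
  qualify, so SiO₂ has no active metal and zero-valued metal
  constants): electron count (= atomic number for a neutral atom),
  Pauling electronegativity, first ionization energy (eV), van der
  Waals radius (pm); plus the count of metallic elements (core +
  dopant), oxygen/total atom counts and the parsed doping percent. The
  element constants ship as a versioned CSV resource whose SHA-256 is
  pinned by a test.
* **combined** — arithmetic combinations of existing columns; the
  defaults are the two dose-interaction terms that drive the response:
  `Concentration_ug_mL*coat_PMAA` and `Concentration_ug_mL/Diameter_nm`.
  Combinations are built from raw (untransformed) parents by default;
  the concentration/diameter orientation is the ratio c/d, matching its
  negative association with viability (small particles at high dose are
  the toxic corner). Both choices are configurable.

## Selection

Three projections, each idempotent and audited in a `SelectionReport`:
variance ≤ 0 dropped (constants; threshold configurable), then a greedy
scan over column pairs with |Pearson r| > 0.95 keeping the member
better correlated with the response (without a response, the earlier
column), then permutation importance — baseline R² minus the mean R²
over shuffles of one column at a time (10 repeats, seeded) under the
fitted reference model. The final model-retraining set is the top 12
columns: the selection narrative identifies both the negatively and the
positively correlated descriptor groups (about six of each), and
retraining on only the top six loses the doping effects. SHAP-style
explainers can be layered on externally; permutation importance is the
implemented, tested selector.

## Validation metrics

All formulas live in `validation.py` and are tested to 1e-12 against an
independent plain-loop implementation:

* R² (observed-mean denominator), RMSE, MAE (and MSE = RMSE², reported
  alongside to remove ambiguity);
* Q²_F1 = 1 − SS_res/Σ(y − ȳ_train)², Q²_F2 = 1 − SS_res/Σ(y − ȳ_test)²
  — the two external-predictivity conventions; Q²_F1 ≥ Q²_F2 on every
  input, with equality when the means coincide;
* CCC, Lin's concordance correlation with population moments; CCC ≤ |r|
  always, with equality only on the identity line;
* Q²_LOO = 1 − PRESS/SS_tot by actual refitting (seeded, deterministic);
* 5-fold CV: the headline "validation" figures are computed on the
  pooled out-of-fold predictions (per-fold reports and their mean are
  also emitted; folds of size < 2 carry no per-fold R²-type metrics).

## Applicability domain

Standardization approach: against training references,
S_ki = |x_ki − µ_i|/σ_i, and per sample S_new = S̄ + 1.28·σ_S
(population SD across that sample's descriptors; 1.28 is the one-sided
90th-percentile normal quantile). S_new ≤ 3 ⇒ inside the domain (for
training rows: not an outlier). Absolute deviations are used because a
mean of signed z-scores can cancel to zero for a sample that is extreme
in opposite directions. The published variant's preliminary
max(S_ki) ≤ 3 shortcut is available as `strict=True`; the default is
the score-only rule. The domain is assessed on the matrix that enters
the model (post z-score/Yeo-Johnson), and the choice is recorded in the
report.

## Synthetic data generator

The generator emulates the exposure table the workflow assumes, so
every stage and the recovery tests run without downloads. Deterministic
surface per ENM, with u = log10(c/c₀) the dose in decades above the
series anchor c₀ (so the lowest dose sits at exactly 100 % before
noise):

```
viability = 100
          + u · (β_PEG·PEG + β_Fe3O4·Fe3O4 + β_Fe·Fe-dop + β_PMAA·PMAA + β_Cl·Cl-dop)
          + β_ratio · (c − c₀)/d
          + noise,   truncated below at 0.
```

Signs follow the expected feature–viability directions: PEG coating,
Fe₃O₄ core and Fe doping protective; the PMAA × concentration
interaction, Cl doping and concentration/diameter toxic. Coating and
core effects scale with dose (a coating matters at high exposure, not
at the anchor dose), which is what the interaction features encode.

**Study-scale roster.** `study_config()` fixes a 16-ENM panel: 11 ENMs
under 200 nm carrying 333 observations (three 31-dose and eight 30-dose
geometric ladders from 0.01 to 25 µg/mL) and 5 coarse ENMs (≥ 200 nm)
carrying 44, i.e. 377 rows in total. The PEG-coated Fe₃O₄ ENMs sit at
mid diameters (45/80 nm); placing the protective coatings on the
smallest particles would flip the marginal sign of the
concentration/diameter feature.

**Calibration.** The default effect sizes and noise SD are calibrated
once so that the modelling subset's marginal viability distribution has
mean 96 % and SD 23 %: the effect profile was scaled so the
deterministic surface has mean exactly 96 and variance 529 − σ_noise²,
with σ_noise = 7 %. Noise is Gaussian and *moment-matched per ENM
series* — each series' noise vector is centred, projected orthogonal to
that series' deterministic profile and rescaled to exactly σ_noise — so
the marginal mean/SD of any union of whole series is a design constant
rather than a property of one lucky seed. The draws remain i.i.d.
Gaussian up to this rank-2 projection (two effective degrees of freedom
per 30-dose series are spent).

An optional hormesis mode adds a low-dose stimulation bump (peak ≈ 2.2
decades above anchor) and a final-half-decade crash, mimicking the
rise-then-collapse dose profiles seen for ZnO; it is off by default so
the surface is monotone and recovery tests are clean.

**What the generator does not emulate:** replicate-well structure and
assay-specific error models, ion-release kinetics and dosimetry
(delivered vs nominal dose), correlations between diameter and
composition beyond the fixed roster, and batch effects. Passing
recovery tests therefore demonstrates that the pipeline recovers the
structure this generator encodes — not that the biology of any real
dataset is this clean.

## Numerical and reproducibility choices

* One top-level seed fans out per stage via `numpy.random.SeedSequence`
  (split / model / permutation / CV streams); identical configs give
  byte-identical JSON reports.
* Hyperparameters default to the scikit-learn defaults (fully grown
  trees, 100 estimators); every resolved value is echoed in the run
  report. With interpolating ensembles the training R² is ≈ 1 by
  construction — the meaningful figures are the validation/test/unseen
  ones.
* Tie-breaks are deterministic everywhere: selection ties by
  lexicographic column name; the correlation filter scans pairs in
  column order.
* Degenerate inputs fail loudly: constant columns at z-score or AD
  reference time, constant responses for R²-type metrics, schema
  mismatches at predict time (missing/extra columns are named).
* Problem sizes in the shipped analyses: 377-row tables, 20-seed
  sweeps, 50-seed recovery checks — chosen so a complete run of the
  test suite and drivers stays in the minutes range on one CPU.

## Known limitations

* Elemental descriptors cover a documented subset (~10) of the larger
  descriptor sets used with closed-source calculators; a full external
  descriptor matrix can be passed through as extra CSV columns.
* The greedy correlation filter is order-dependent and not guaranteed
  to find the *maximum* decorrelated subset (tests compare it against
  brute force on small instances: it always returns a valid subset, not
  always the largest).
* Q²_LOO refits the full ensemble n times; at 210 training rows and
  default ensembles this is seconds-to-minutes, and it is the slowest
  part of a full run (`compute_loo=False` skips it).
* The unseen-subset metrics rest on 33 rows; their seed-to-seed spread
  is large (±0.1 in R² is normal), which is why the seed sweep, not any
  single run, is the right summary.
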