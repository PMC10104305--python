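# Methods

## The estimation problem

*Raphia laurentii* is a cespitose ("trunkless") palm: its short stems
are buried inside a clump of up to twenty-metre fronds, so the diameter
measurements that drive conventional tree and tree-palm allometries are
not obtainable in the field. AGB must instead be predicted from what can
be measured on a standing clump: petiole diameters (per-frond stalk
diameter at ~1.3 m, summarised per individual as the mean `MDp` and the
sum `SDp`), total height `H`, the live frond count `Npf`, and — from a
small number of destructively sampled individuals — tissue density `TD`
and the stem base diameter `D`.

## Tissue processing

Each lab sample carries a fresh mass, an oven-dry mass and (for stem,
sheath, petiole and rachis) a hydrostatic displaced volume. Tissue
density is dry mass over volume (g cm⁻³); the dry/fresh ratio of each
component converts field fresh masses to dry mass; a palm's AGB is the
sum of its five component dry masses (stem, sheath, petiole, rachis,
leaflet), and its frond mass is the non-stem remainder.

Two conventions needed fixing where the procedure is underdetermined:

* **Per-individual tissue density** is the equally weighted mean of the
  four component densities (leaflets have no volume). Equal weighting is
  adopted because the published overall density mean (0.24 g cm⁻³)
  equals the plain mean of the four component means; mass-weighting
  would be a defensible alternative and would shift `TD` slightly
  toward the stem/petiole values.
* **Partition percentages** are means of per-individual fractions
  ("individual-first"), not ratios of mean masses. The two disagree
  whenever size and allocation covary; the individual-first convention
  matches the published component shares (e.g. petiole 30.17%), which
  are not reproducible as ratios of the published mean masses.

Group comparisons use the tie-corrected Kruskal–Wallis H (delegated to
`scipy.stats.kruskal`; an all-tied input returns H = 0 rather than 0/0)
and a hand-implemented Dunn post hoc test,
`z = (R̄ᵢ − R̄ⱼ) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ))`,
with two-sided normal p-values and optional Bonferroni or Šidák
adjustment (default none, matching the common default of the post hoc
tooling this field uses).

## Allometric fitting

Models are linear in natural logarithms,
`ln AGB = a + b ln P1 [+ c ln P2 [+ d ln P3]]`, fitted by OLS
(statsmodels behind the module surface). Conventions:

* **Degrees of freedom**: `df = n − (p + 1)` counting the intercept, the
  standard least-squares convention; `RSE = sqrt(RSS/df)`.
* **AIC** uses the full Gaussian log-likelihood including the constant,
  with `p + 2` free parameters (coefficients, intercept, error SD) —
  the convention of mainstream statistical software, consistent with
  the negative AIC values reported for well-fitting log-scale models.
* **Correction factor** `CF = exp(RSE²/2)` (Baskerville). Predictions on
  the kg scale are `CF · exp(fitted log value)`; `CF(0) = 1` and CF is
  strictly increasing in RSE.
* **RMSE and Bias%** are computed on the back-transformed kg scale with
  CF applied; Bias% is the mean signed relative error × 100. Whether
  the published table applied CF before computing these is not
  documented; applying it is the internally consistent choice since the
  corrected predictions are the ones a user would deploy.

The candidate set is staged. Predictors are grouped into coarseness
(`D`, `MDp`, `SDp`), height (`H`) and intrinsic (`TD`, `Npf`)
parameters. Stage 1 fits all six singles; stage 2 combines the stage-1
winner with each predictor of the other two groups; stage 3 extends the
stage-2 winner by each predictor of the remaining group. "Winner" at
every stage, and the final ranking, use the same lexicographic order:
adjusted R² (desc), then AIC, RSE, RMSE, |Bias%| (asc), ties broken
toward fewer predictors. A nested partial F-test
`F = ((RSS_red − RSS_full)/q) / (RSS_full/df_full)` annotates each
stage-2/3 candidate against its parent at α = 0.05; it annotates rather
than vetoes promotion, since the selection criteria above are the
deciding ones. Fitting is run separately on the full sample
(`MDp ≥ 2 cm`) and on the `≥ 5 cm` subset, mirroring the question of
whether excluding juveniles improves the equations.

## Application and upscaling

Hardwood trees (DBH ≥ 10 cm) use the pantropical moist-forest equation
`AGB = 0.0673 (ρ D² H)^0.976` (ρ in g cm⁻³, D in cm, H in m, AGB in
kg); the height-free environmental-stress variant is out of scope since
no stress parameter is available for these plots. Palms use a packaged
or fitted log-linear model; the frond-count-only model m16 serves
inventories where only `Npf` was recorded, applied plot-wide even below
its fitted range (with a logged extrapolation note) rather than
dropping stems. Plot totals are per-hectare; the palm contribution is
`100·palm/total` and the cost of excluding palms is `100·palm/tree`.
Carbon conversion uses a configurable fraction (default 0.47 of dry
mass, a standard tropical-forest value; the source analysis does not
state its factor). Regional stock is
`Pg C = (Mg C ha⁻¹) × km² × 100 / 10⁹`; at 30.4 Mg C ha⁻¹ over
66,300 km² this gives 0.20 Pg C. (The prose figure "2 million tonnes"
printed alongside 0.2 Pg C elsewhere is internally inconsistent —
0.2 Pg is 200 million tonnes; the arithmetic here reproduces the
0.2 Pg value.)

## The synthetic-data generator

The generator emulates the study design, not any particular dataset:

* six mean-petiole-diameter classes, `(2,4], (4,5], (5,6], (6,7],
  (7,8], (8,12.6]` cm (the open top class is closed just above the
  largest observed mean petiole diameter), 15 palms per class;
* per palm, a target mean petiole diameter uniform in its class; a
  frond count `Npf = clip(round(1.5 + 0.7·MDp + N(0,1)), 3, 11)`
  (larger palms carry more fronds; every sampled palm had ≥ 3); `Npf`
  petiole diameters `N(MDp, 0.15·MDp)` — the within-palm dispersion is
  unreported, so a 15% coefficient of variation is assumed — whose sum
  is `SDp` and whose mean is the recorded `MDp`;
* stem base diameter `3.5·MDp + N(0,2)` clipped to the observed
  8.2–35.4 cm; height log-linear in `SDp`,
  `H = exp(0.956 + 0.45 ln SDp + N(0, 0.18))` clipped to 5.13–21.20 m;
  tissue density truncated-normal around 0.24 (SD 0.036) within
  0.15–0.38 g cm⁻³. The link strengths are calibrated so the
  single-predictor fits land in the published R² band (~0.79–0.97, with
  TD near zero) and height carries genuine information beyond `SDp`,
  as it does in the published two-predictor step;
* `AGB = exp(a + Σ slope·ln predictor + N(0, σ))` from a configurable
  true model (default: the published m11 coefficients) with σ = 0.18 on
  the log scale — the residual SD of the published best models;
* component masses from a Dirichlet split (concentration 100) with mean
  shares stem 14.83%, sheath 13.83%, petiole 30.17%, rachis 16.00%,
  leaflet 25.17% — the published pooled partitioning;
* 19 lab samples per palm (3 stem discs, 3 fronds × 5 pieces, 1 leaflet
  bulk sample) with per-sample dry/fresh ratios around the published
  component means and volumes consistent with the palm's density.

What it does **not** emulate: measurement error on the predictors,
within-clump correlation between stems of one clump, heteroscedastic or
size-dependent allocation shifts (the published rachis share rises and
the leaflet share falls with size; the Dirichlet split holds shares
constant), and any spatial structure. Tests passing on this generator
therefore validate the estimation machinery — unbiased coefficient
recovery, correct metric arithmetic, selection behaviour — not the
field accuracy of the published coefficients, which cannot be re-derived
without the undeposited raw data.

Plot inventories are generated with trees (D = 10 + Exp(15) cm clipped
at 150, density U(0.25, 0.85), height log-linear in D) and palms
carrying only a frond count, matching the data actually available in
the application plots.

## Numerical and interface choices

* Natural logarithms throughout; predictors and AGB must be strictly
  positive to enter a fit; rank-deficient designs and `df = 0` fits are
  rejected with explicit errors rather than returning NaNs.
* Exact invariants are enforced on ingest: component masses sum to the
  recorded AGB within 10⁻⁹ kg, `SDp/Npf` agrees with `MDp` within 10⁻⁶,
  dry mass never exceeds fresh mass. Files violating them abort by
  default; a skip-invalid mode drops rows with logged counts.
* CSV tables are UTF-8, comma-separated, with unit-suffixed column
  names; floats are written at 17 significant digits and parsed with
  pandas' round-trip parser so write-then-read is bit-exact.
* The packaged coefficient table is checksum-verified on load, and
  every CF it contains is checked against `exp(RSE²/2)` within the
  0.005 tolerance of two-decimal printing. The symbol `TDp`, used in
  places for the summed petiole diameter, is canonicalised to `SDp`.
* Simulation problem sizes used in the test-suite checks: 200
  replicates of n = 90 for coefficient recovery, single fits at
  n ≈ 5000 for consistency checks, 1000 replicates at n = 30 for the
  partial-F null calibration.

## Known limitations

Belowground biomass, necromass and peat carbon are out of scope, as is
uncertainty propagation beyond the correction factor (no prediction
intervals on plot totals). The published coefficients themselves are
taken as given; only their internal arithmetic (CF, ranking, component
sums, upscaling) and the behaviour of the estimation procedure on data
of the same structure are verifiable.
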