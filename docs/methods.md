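# Methods

This note documents the models implemented in `thermotree`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
choices that affect results.

## Assay model and community summaries

A ramping assay holds an insect at a 28 °C baseline and changes the
temperature by 1 °C every 2 min (0.5 °C min⁻¹) until mobility is lost.
Because mobility is checked once per step, the recorded CT is
grid-discretized: `synthdata.discretize_ct` records the smallest grid
temperature at or above the true threshold for CT_max (the first check at
which the insect is immobile) and the largest grid temperature at or
below it for CT_min. The recording bias is therefore in [0, 1) °C for
CT_max and (−1, 0] for CT_min; with between-individual spread well above
the 1 °C step the bias is close to +0.5 / −0.5 °C and cancels exactly in
two-group contrasts such as the shock effect.

Plot summaries report mean, median, and the 10% / 25% quantiles per plot
and assay direction. All quantiles in the package use linear
interpolation between order statistics (numpy's default, the common
"type 7" rule); the rule is fixed package-wide so assay and proteome
summaries are comparable.

Elevational trends come in two modes: ordinary least squares (slope,
intercept, overall F) and a penalized cubic regression spline with basis
dimension 5. The spline penalty weight is selected by generalized
cross-validation over a log-spaced grid; because a straight line lies in
the penalty null space, noiseless linear data are reproduced exactly at
any penalty. Trends can be fitted at the record level (with plot-level
predictors) or at the plot level — both are exposed because community
datasets are analysed both ways in practice; the functions are agnostic
to which aggregation the caller passes.

Shock (hardening) effects are oriented so that positive always means
increased tolerance: shocked − control group means for CT_max, control −
shocked for CT_min. Elevation bands are half-open: lowland < 600 masl,
mid [600, 1200), high ≥ 1200. The reported `se` is the standard error of
the difference in group means.

## Phylogenies

`simulate_tree` draws a pure-birth (Yule) tree conditioned on the tip
count: lineages split at unit rate, the reconstructed tree starts at the
root split, and all node times are rescaled so every root-to-tip path
equals the configured depth (1.0 by default — branch lengths are
relative time throughout). Families and orders are assigned by cutting
the tree at the height where the lineage count first equals the requested
number of groups, so they are monophyletic by construction.

Supertree assembly mirrors the barcode-community workflow:

* **Grafting** replaces each family tip of an ultrametric backbone with
  the root of that family's subtree, keeping the backbone terminal branch
  as the subtending edge. A single-OTU family becomes one pendant branch;
  its length defaults to half the family's backbone terminal branch (a
  fixed length is required but no canonical value exists; half the
  terminal branch keeps the tip inside the family's time slice and is
  overridable).
* **Age calibration** assigns every unconstrained internal node the age
  obtained by spacing nodes evenly — by node count — between its nearest
  constrained ancestor and nearest constrained descendant (tips are
  constrained at age 0, the root age must be given). Nodes are processed
  root-to-tip and previously interpolated ages act as constraints for
  deeper nodes; this sequential form guarantees parent ≥ child ages on
  chains and matches the even-placement behaviour of the classic
  "bladj" algorithm. Branch lengths are recomputed from ages; an
  interpolation conflict that would produce a negative branch is clamped
  to zero with a warning, while inconsistent *fixed* ages raise an error.
* **Tip-height equalization** stretches terminal branches so all tips
  reach the maximum depth. The result looks ultrametric but branch
  lengths remain relative, not absolute, time.

Signal statistics default to operating on whichever tree the caller
passes; for assembled supertrees the equalized tree is the natural
input, and both equalized and raw trees are accepted.

## Trait evolution and comparative statistics

The trait generator writes tip values as
`beta0 + beta_elev · elevation + u`, with `u` a zero-mean OU deviation
simulated branch-by-branch with the exact transition
`u → u e^{−αt} + N(0, σ²(1 − e^{−2αt})/(2α))` and a stationary root draw
`N(0, σ²/(2α))`. With α = 0 the recursion is the exact BM transition, so
the BM limit is available without a separate code path. `beta0` is the
optimum θ at elevation 0. The stationary start was chosen so that the
generator's tip covariance, `σ²/(2α)·e^{−α d_ij}`, is exactly the
covariance the OU estimators assume.

All comparative methods work on dense tip covariance matrices built from
the tree (C_ij = depth of the MRCA of tips i and j):

* **Ancestral states** are ML states under BM in GLS form: the root is
  the GLS mean `(1'C⁻¹y)/(1'C⁻¹1)`, internal nodes are best linear
  unbiased predictions about that mean, and reported variances include
  the uncertainty in the mean.
* **Pagel's λ** multiplies the off-diagonal of C; λ is estimated by
  bounded scalar ML on [0, 1] (mean and scale profiled out analytically)
  with the endpoints checked explicitly, and tested against λ = 0 with a
  χ²₁ likelihood-ratio test.
* **Blomberg's K** uses the standard ratio of mean squares about the
  phylogenetically corrected mean, normalized by its BM expectation; the
  significance test permutes tip labels, one-tailed for large K, with
  (b+1)/(m+1) smoothing and a recorded seed.
* **The correlogram** computes Moran's I with 1/patristic-distance
  weights inside equal-frequency distance classes, with one-tailed
  permutation p-values per class.
* **PGLS** supports three covariance models: star (= OLS), BM
  (C as-is), and stationary OU (`exp(−α d_ij)` correlation; the
  non-stationary fixed-root form is available behind a flag because the
  two differ and published fits rarely state which was used). α is found
  on a 25-point log-spaced grid spanning α·depth ∈ [10⁻⁴, 5·10³],
  refined by bounded scalar search between the bracketing grid points
  (tolerance 1e-8); hits at the grid edge set a boundary flag and a
  warning. AIC counts coefficients + σ² (+ α for OU); AIC ties are
  broken alphabetically by model name for deterministic rankings.
* **The OU optimum θ** is the intercept of the intercept-only OU fit,
  i.e. the GLS mean under the fitted OU covariance; a constant trait
  short-circuits to θ = that constant with σ² = 0.
* **Variance partitioning** uses likelihood-based partial r²,
  `1 − exp(−(2/n)(logL_full − logL_reduced))`: predictors are dropped one
  at a time (covariance kept, α refit), and the phylogeny component
  replaces the covariance with the star model while keeping all
  predictors. This form was chosen because it is well defined for
  correlated-error models and reduces to the classical partial r² for
  independent observations (verified in the tests to 0.02).

Covariance matrices are checked for symmetry and passed through a
Cholesky factorization before any solve; failures raise a dedicated
degeneracy error rather than propagating NaNs.

## Thermal-death-time model

The TDT law is `log10 t_coma = (T_L − T)/z + log10 t_ref` with t_ref =
1 min. The reference time is a convention, not an estimate — every
downstream threshold is expressed through the closed form, so changing
t_ref rescales T_L without changing any classification.

`fit_z` is least squares of log10(time) on temperature; z = −1/slope, and
a non-negative slope raises an implausible-sensitivity error. z defaults
to 3 °C per decade wherever a value is needed and none is estimated — a
conservative middle of the 1–5 range observed across insects (higher z
gives shorter coma times).

Dynamic-to-static conversion assumes injury accumulates memorylessly at
rate 1/t_coma(T) with no repair, and coma at accumulated injury 1. For a
linear ramp of rate r from `start_temp` this integral has the closed-form
inverse implemented in `dynamic_to_static`; the default keeps the
sub-start term, and an `approx=True` flag drops it (the familiar
`T_L = ct_dyn − z log10(r t_ref ln10 / z)`), accurate to < 0.05 °C when
the start is at least 3z below the knockdown temperature. A forward
quadrature simulator (`simulate_ramp_knockdown`) provides the independent
check: round trips agree within 0.01 °C across z ∈ [1, 5] and
r ∈ [0.06, 1] °C min⁻¹.

A temperature value is *critical* when its predicted coma time is at or
below the exposure threshold (≤, not <; the boundary case is counted),
i.e. when `T ≥ T_L − z·log10(threshold/t_ref)`; the default threshold is
480 min (8 h). Fractions are computed over **all** retained values,
night temperatures included. Community sensitivity converts the 10%,
25%, and 50% CT_max quantiles of the lowland sample into three tolerance
landscapes applied gradient-wide — a conservative convention assuming
upslope communities can reach lowland tolerance by turnover or
acclimatization.

Climate projection is anomaly addition: every value is shifted by
Δ = bio5_future − bio5_current for the plot, preserving the sub-daily
variance structure. Surface series receive the same air-derived Δ, a
conservative choice since surface temperatures are expected to warm
faster than air in open habitats.

## Microclimate and proteome generators

Microclimate series are 15-min cadence:
`sea_level_mean − lapse·elevation + A_d sin(diurnal) + A_s sin(annual) +
AR(1) noise`. The diurnal phase peaks at 14:00 and troughs at 02:00 on
exact sample points so the noiseless daily range is exactly 2·A_d; the
seasonal period is exactly 365 days so multi-year means telescope to the
configured level; AR(1) innovations are scaled to a fixed marginal sd.
Defaults (24.3 °C at sea level, 4.9 °C km⁻¹ lapse, 5 °C diurnal
half-amplitude, weak 1 °C seasonality, ρ = 0.8, sd 1 °C) emulate a wet
tropical lowland-to-montane gradient. The generator does **not** emulate
cloud-cover autocorrelation, rain events, canopy buffering, or
surface–air offsets, so passing tests demonstrate correct model
arithmetic and estimator calibration — not realism of any particular
site's weather.

Protein melting temperatures are generated as
`grand_mean + order + family + species + protein noise` (defaults 46.9 °C
grand mean with ~3 °C protein-level spread, matching the scale of
predicted insect proteomes). The heat-sensitive proteome statistic is the
per-species mean of proteins at or below the species' 25% T_m quantile;
family statistics average species first (species are the exchangeable
unit), and the order/family variance tests are sequential fixed-effect F
tests on species means — a deliberate simplification of a mixed model
with random protein identity, adequate for balanced synthetic tables and
noted as an extension point for unbalanced real data.

Within-species assay spread is a free parameter (default sd 1 °C) since
community surveys rarely report it.

## Reproducibility and problem sizes

All generators draw from named substreams of one root seed (a CRC32 hash
of the substream name enters the seed sequence), so identical
configurations reproduce outputs byte-identically and adding a new
generator never perturbs existing streams. Output CSVs carry a header
comment with package version, seed, and a configuration hash.

The recovery studies use 50 replicates of 300-tip trees for θ, 50
replicates of 500-tip datasets for λ, 200 replicates of 60+60-individual
experiments for the shock effect, and 200 BM replicates on 80-tip trees
for the K calibration — sizes at which Monte-Carlo standard errors are
a few hundredths of the quantities of interest while a full run stays
under a minute per study on one CPU.

## Known limitations

* The λ ML estimator has a small downward finite-sample bias (~0.01 at
  500 tips), visible but well inside the recovery tolerance.
* OU parameters α and σ² are individually weakly identified when
  α·depth ≫ 1 (only their ratio, the stationary variance, is); θ remains
  well estimated, which is why recovery is asserted for θ.
* The sequential even-interpolation calibrator can, on pathological
  constraint patterns, clamp a branch to zero rather than fail; the
  warning should be treated as a signal to add calibration points.
* Mixed-effects versions of the trend and T_m models, survival analysis
  of assay mortality, and behavioural thermoregulation are out of scope.
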