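# Methods

## Designs and coding

A factor is specified by natural low/center/high levels; the coding map
is the affine transform `x = (natural - center) / ((high - low)/2)`, so
the three levels land on -1/0/+1. The center is required to be the
midpoint of low and high — otherwise the three anchors cannot share one
linear map. Values outside `[-1, 1]` are allowed (they arise when
coding reported optima) but warned about as extrapolation.

`make_bbd` builds Box-Behnken designs for 3–7 factors: for every
unordered factor pair the four `(±1, ±1)` sign combinations with all
other factors at 0, plus `n_center` all-zero replicates — `2k(k-1) +
n_center` runs. Pairs are enumerated lexicographically and centers
appended, so run order is deterministic; an optional seed shuffles rows
reproducibly. Run order is irrelevant to OLS fitting, so the packaged
study table keeps its published order. The packaged design stores
natural factor values and recodes them from the level table at load
time, because the published coded labels contain typos while the
natural values are internally consistent. The solvent ratio "1 : N
g/mL" is represented by the scalar N (mL of solvent per g of material).

## Assay responses

All five responses are ratios scaled to percent: extraction yield
`W1/W2·100`, total polyphenol content `C1/C2·100` (gallic-acid
equivalents over total sample concentration), enzyme inhibition
`(control - sample)/control·100`, and radical scavenging
`(blank - sample)/blank·100`. The radical formula follows the standard
scavenging convention (fractional loss of radical absorbance); the
alternative reading `sample/blank·100` would invert the meaning of
inhibition and is not used. Blank correction is deliberately left to
the caller: plate layouts mix per-well and per-plate blanks, and the
response functions should not guess. Negative rates (apparent
activation) and yields above 100% are returned as computed but warned
about rather than clipped.

## Model fitting and ANOVA

Fitting is always the *full* second-order polynomial in coded units —
`1 + 2k + k(k-1)/2` terms, no term dropping — estimated by OLS
(delegated to `statsmodels`; the term construction, replicate grouping
and lack-of-fit partition are this package's own). Coded units make the
intercept the center-run mean and put all effects on comparable scales;
natural-unit equations are derived views. Per-term standard errors use
the unscaled covariance matrix times residual MS; p values are
two-sided t on residual df, with significance at α = 0.05 by default
(equivalent to the partial F test for single terms).

The ANOVA partitions `SS_total = SS_model + SS_residual` and splits the
residual over replicate groups: pure error is the pooled within-group
SS of runs with identical coded settings (for a BBD, the center
replicates, df = n_center − 1), lack of fit is the remainder. `F_model
= MS_model/MS_residual` and `F_LOF = MS_LOF/MS_PE` take p values from
the exact F upper tail. Degenerate inputs are handled explicitly: a
design with no replicates omits the pure-error/lack-of-fit rows with a
warning, and exact replicates (zero pure error, e.g. noiseless
simulations) report the lack-of-fit row without an F ratio rather than
dividing by zero. Factor influence is ranked by |coded linear
coefficient|, with ties kept in input order and flagged.

## Surface optimization

The unconstrained stationary point solves `H x = -b` with
`H = 2 diag(b_ii) + [b_ij]` and is classified by the eigenvalue signs
of `H`; a Hessian with condition number above 1e10 is reported
degenerate instead of inverted. Box optima use a deterministic
multi-start scheme: bounded L-BFGS-B (analytic gradient) from every
point of the 3^k lattice of box corners/edge-midpoints/center, plus the
stationary point when interior, keeping the best result and never
reporting below the best start value. For quadratics over a box this
reliably finds the global optimum (verified against dense-lattice
search in the tests) while staying fully reproducible — the scheme is
the package's own definition, since point-and-click optimizers do not
document theirs.

Joint optimization maximizes Derringer–Suich desirability: each
response maps to `d ∈ [0, 1]` by a power-weighted ramp between two
anchors (one-sided for maximize/minimize goals, tent-shaped for target
goals), combined by geometric mean, maximized by the same multi-start
scheme (numerical gradient; D is piecewise-smooth). Default anchors are
each surface's own (min, max) over the box with weight 1, i.e. "do as
well as possible on every response, traded off evenly". On the packaged
study this default reproduces the published joint condition to within a
few percent in every factor. The published per-response "optimal
settings" all cluster at that single joint condition rather than at the
individual surface maxima (two of which sit on the cube boundary far
from it), so the reproduction tests compare them against the joint
optimum; published predicted values are treated as approximate
cross-checks because they are not exactly consistent with the published
equations either.

## Chromatography

Calibration lines are plain least squares on (concentration, area)
pairs with R² = 1 − SS_res/SS_tot (defined 0 for constant areas) and a
validity range defaulting to the standard span. Contents use the
one-point external-standard method — `conc = sample_area/standard_area
· standard_conc`, converted to percent w/w through solution volume,
dilution and extract mass, which are explicit arguments because they
are bookkeeping the instrument does not know — with the calibration
curve used only to flag out-of-range concentrations, matching the
stated laboratory procedure. System suitability computes, per peak, the
RSD (sample sd, n−1, pharmacopoeial convention) of relative retention
time and relative peak area across injections; the reference peak's
rows are forced to exact zeros since its ratios are identically 1.

## Synthetic data

The generators emulate exactly the error structure the analysis
assumes, with mandatory seeds and no global state:

- **BBD experiments**: response = true quadratic surface + iid
  N(0, σ²), so center replicates share one mean and pure-error MS is an
  unbiased σ² estimate (verified over seeds in the tests).
- **Assay plates**: sample absorbance = control·(1 − IR/100) + Gaussian
  noise, clipped at zero.
- **Injections**: template areas times iid lognormal factors with unit
  mean and given percent CV (areas stay positive; a peak's relative
  area is then a ratio of lognormals with CV ≈ √2·CV), retention times
  jittered with a Gaussian sd.
- **Calibration series**: a true line sampled on an even grid plus
  Gaussian area noise.

What this does *not* emulate: heteroscedastic or correlated assay
noise, plate-position effects, drifting retention over long sequences,
peak overlap/integration error, or any mechanistic extraction kinetics.
Passing recovery tests therefore demonstrate correctness of the
statistics under their own assumptions, not robustness to real-data
pathologies.

Default simulation conditions mirror the packaged study: 4 factors, 5
center replicates (29 runs), response noise sd 0.8 (the residual scale
of the best-behaved study response), 12-peak chromatograms at 1–2% area
CV with 6 replicate injections. Recovery checks use 100 simulated
experiments; distributional checks (pure-error expectation, RSD bands)
use 300–400 replicates — sizes chosen so Monte-Carlo error is well
below the asserted tolerances.

## Numerical choices

- Model-matrix column order: intercept, linear, pairwise interactions
  (lexicographic), pure quadratics; coefficient vectors and JSON
  serializations follow it.
- Rank deficiency raises before fitting (`rank < p` on the model
  matrix); responses of wrong length raise.
- Coded values produced by recoding natural columns are snapped to
  exact design levels when within 1e-9, so structural invariants
  (column sums, orthogonality) hold exactly.
- Reports print coefficients to 2 decimals and R² to 4 decimals; JSON
  keeps full precision with sorted keys, so identical inputs give
  byte-identical artifacts.
- Desirability returns exactly 0 when any component is 0 (geometric
  mean annihilation) without evaluating logs.

## Known limitations

- The published run table rounds responses to 2 decimals, and its
  ABTS column contains at least one datum inconsistent with the
  published ABTS ANOVA panel; refits therefore reproduce published
  sums of squares exactly for some responses and only to ~0.1–12
  absolute for others, while R², coefficients and F ratios reproduce
  throughout. The package reports what the shipped data imply and does
  not attempt to "correct" the published values.
- Lack of fit needs replicated runs; designs without them get no
  adequacy test.
- Optimization is over a box in coded units; general nonlinear
  constraints and ridge analysis are out of scope, as are
  central-composite/Plackett-Burman designs, IC50 fitting, and peak
  detection from raw chromatographic signal.
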