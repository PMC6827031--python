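# Methods

## Grid and raster conventions

All modeling happens on one aligned north-up grid of square cells.  Cell
(r, c) covers the half-open square
[x₀ + c·s, x₀ + (c+1)·s) × (y₀ − (r+1)·s, y₀ − r·s], row 0 at the north
edge; points exactly on the east/south outer boundary are clamped inward.
Nodata (NaN internally) propagates: a cell is valid for modeling only if
every layer is defined there — this is what makes "fraction of land area"
well defined when a lake masks part of the grid.  Two grids are aligned iff
all geometry fields agree (the CRS tag is carried opaquely; reprojection is
out of scope).  Continuous layers resample bilinearly between cell centers,
categorical layers by nearest neighbor only; bilinear on categorical codes
is rejected.

## Covariate derivation

* **Slope/aspect** — Horn 3×3 finite differences with replicated edge
  padding; slope in [0°, 90°], aspect in degrees clockwise from north with
  −1 as the flat sentinel.
* **TWI** — ln(a / tan β) with a = (D8 accumulation count + 1)·cell_size
  and β the Horn slope.  The flow router is single-direction D8; steepest
  drop is measured per unit distance and ties break to the first direction
  clockwise from north, which makes accumulation deterministic and
  hand-traceable.  tan β is floored at 0.001 so flats stay finite.  D8 and
  the ε-floor are this package's choices; a wetness-index definition alone
  pins down neither.
* **Distance maps** — minimum Euclidean distance from each cell center to
  the true vector geometry (shapely), not to a rasterization: this removes
  any rasterization-order dependence and is testable against an analytic
  oracle.  The 10-km road buffer (`buffer_mask`) thresholds this distance
  and composes with background sampling as a bias-correction zone.
* **Time-series statistics** — Savitzky–Golay smoothing along time
  (scipy, `mode="interp"`: a polynomial fit on the truncated terminal
  window handles the edges; coefficients come from local least squares, so
  any window/order pair works), then per-cell mean/max/min/std.  The
  standard deviation uses the population divisor n: the statistics
  summarize one fixed year, not a sample from a longer record.

## The maxent model

Features of continuous variables are scaled to [0, 1] by their background
min/max; hinge (forward/reverse) and threshold knots sit at background
quantiles (50 per variable by default).  Categorical variables contribute
one indicator per background-observed code; unseen codes score zero with a
warning.  Which classes are active follows the conventional sample-size
rule — m < 10 linear; < 15 +quadratic; < 80 +hinge; ≥ 80 all — because
"default settings" in the tools practitioners use are only reproducible by
codifying that rule; it is configurable.

The penalty is β_j = β·s_j/√m with s_j the background standard deviation
of feature j and β a single global multiplier (default 1.0) — an explicit
approximation of the published default behavior without importing tuned
per-class tables.

Fitting maximizes the penalized presence log-likelihood with FISTA:
backtracking line search on the smooth part, soft-thresholding for the L1
term, gradient-scheme adaptive restart, deterministic start at λ = 0.
Convergence requires both an objective change below `tol` (default 1e-6)
and a sup-norm parameter step below √tol; exceeding `max_iter` (default
5,000) raises an error carrying the final gradient norm.  The problem is
convex, so the `seed` argument exists only for interface symmetry.

**Samples in the background.**  By default the evaluation layer folds the
training presences into the fitting background (the convention of the
standard maxent tool).  Without it the penalized likelihood is unbounded
whenever the presence feature mean leaves the convex hull of the background
features — which genuinely happens when presences fall outside a
bias-correction zone.  `fit()` itself never augments, so closed-form
fixtures remain exact.

**Logistic output.**  L(x) = σ(H + ln raw(x)) with H the entropy of the
fitted raw distribution — the entropy calibration equivalent to a default
prevalence of 0.5.  The transform is strictly monotone in the raw output,
so AUC is identical on either scale; TSS thresholds are applied to the
logistic scale, where the decile grid {0.0, …, 1.0} (11 thresholds) lives.

## Validation protocol

Replicated subsample validation: each replicate splits the presences
50/50 (38 train / 39 test at m = 77) by a permutation derived only from
(seed, replicate), fits on the training half against the full background,
and records training AUC, test AUC (rank-based Mann–Whitney with midrank
ties) and the max-TSS threshold against a pseudo-absence set redrawn from
the background under the replicate seed (whether the original protocol
redrew or fixed that set is not decidable; redrawing is the conservative
choice).  Ties in the TSS arg-max break toward the smaller threshold,
favoring sensitivity.  Because split plans depend only on (seed,
replicate), two scenario runs sharing a seed are paired by construction,
and per-replicate metric differences are pure model effects.

Jackknife importance refits with each variable alone and omitted and
reports training gains; "percent contribution" is implemented as
permutation importance (drop in training gain when a variable is permuted
jointly across presence + background, mean of 10 permutations, floored at
0, normalized to 100) because the path-attribution of the original tool is
solver-specific; the 0.5 exclusion cut is read as 0.5 percent.  Variable
selection removes, while any continuous pair exceeds |r| > 0.75 over the
background, the member with the lower with-only gain; categorical layers
are exempt (Pearson r is undefined for codes).

The Wilcoxon signed-rank test drops zero differences, midranks ties, and
is exact for n ≤ 25 via the full null distribution of W⁺ over all 2ⁿ sign
assignments (dynamic programming over doubled midranks, so tied ranks stay
integral); above that, a normal approximation with tie-aware variance
Var(W⁺) = Σrᵢ²/4 and continuity correction.  Scenario significance is read
at p < 0.01.

## Scenario comparison

Each scenario gets its own max-TSS threshold (from its replicate-mean TSS
curve) and binary map — mirroring the per-model thresholding procedure —
and the "area where probability increases with human factors" counts valid
cells where the full model's replicate-mean probability exceeds the
reduced model's by more than δ (default 0), restricted by default to cells
suitable under the full model.  Both the δ and the restriction are
reported in the output metadata because no unique counting rule exists;
the computation uses replicate-mean maps (per-replicate maps are the noted
alternative).

## The synthetic generator

`generate_study` emulates the study structure: a 100×100 grid of nominal
1-km cells; five zero-mean unit-variance Gaussian random fields
(squared-exponential correlation, lengths 8–20 km) standing in for
climate/vegetation/altitude; a soil-type layer from quantile-binning a
sixth field into 4 coherent classes; 2 roads and 2 rivers as random-walk
polylines crossing the grid and 12 resident sites clustered near roads;
their three distance maps; an elliptical lake of nodata (500 cells); and
77 presences.  True suitability is logistic in min-max-scaled variables
with road distance dominant (coefficient −15 on the scaled variable, i.e.
an e-folding of a few km — chosen so that, as in the real basin, high
suitability hugs the road network and roughly a fifth of the land clears
0.5), soil-type effects ±0.9/±0.45, and one humped climate response
(+2 linear, −2.5 quadratic); intercept 1.0.  Presences are drawn cell-wise
∝ suitability × e^(−d_road/10 km) (roadside detection bias), sequentially
without replacement with greedy earlier-point-wins thinning at 2 km —
sequential rejection rather than draw-then-thin, so the requested count is
met deterministically.  Everything is a pure function of (config, seed);
seeds for sub-stages derive hierarchically and stay below 2³¹.

The background sample (3,000 cells ≈ a third of the ~9,500 valid cells,
proportional to 10,000 over a ~29,700-cell basin) is drawn uniformly from
the whole valid area, matching the protocol of drawing background from the
entire study region; restricting it to the 10-km road zone is supported
(`background_bias_radius`, `bias_zone` in the run config) but off by
default — with both presences and background confined to the road
corridor, road-driven suitability is nearly unidentifiable, which the
basin-wide accuracy of the original study indicates was not its design.

What the generator does **not** emulate: burrow-count observation error
(presence is binary), climate realism of any particular bioclim variable,
anisotropy or trends in the random fields, and real road-network topology.
Passing recovery tests therefore show the pipeline recovers truth under
its own generating assumptions, not that any real landscape satisfies
them.

## Problem sizes and experiment profile

The canned experiments (`pikasdm.experiments`, the analysis scripts and
the acceptance script) use 8 hinge knots per variable instead of the
library default 50: at 3,000 background cells the hinge response curves
are saturated well below 50 knots, and replicate fits stay sub-second.
The recovery experiment runs 20 seeds with with-only jackknife fits (the
ranked quantity); validation uses 20 replicates; the scenario contrast
uses 100 paired replicates; the determinism check re-runs the
simulate → fit-evaluate pipeline twice at 5 replicates and compares every
written artifact bit-for-bit.

## Known limitations

* No reprojection: all inputs must already share one CRS.
* The regularization multiplier approximates, not reproduces, the original
  tool's per-class tuned tables; absolute gain values are therefore not
  comparable across implementations, though rankings are stable.
* Percent contribution is permutation-based and will split credit between
  strongly correlated variables (visible in the road/resident pair).
* The exact Wilcoxon branch is O(n·Σ2rᵢ) in memory/time and is capped at
  n = 25, beyond which the corrected normal approximation is used.
* D8 routes all flow to a single neighbor; dispersal-type routers (MFD,
  D∞) would change TWI in flat terrain.
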