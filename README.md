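# pikasdm

Presence-only species-distribution modeling pipeline for the plateau pika
(*Ochotona curzoniae*), built around a from-scratch maximum-entropy (maxent)
model and exercised end-to-end on synthetic landscapes with known truth.

## The problem

Plateau pika is a keystone burrowing lagomorph of the Qinghai–Tibetan
plateau whose distribution is surveyed only where field crews can reach —
mostly along roads.  Mapping its suitable habitat over a whole basin from
77 presence plots therefore needs a presence-only model (no confirmed
absences exist), careful handling of roadside sampling bias, and a way to
ask how much of the predicted range is attributable to anthropogenic
factors (distance to road, distance to resident site) versus environment
(climate, soil, vegetation, terrain, water).

Because the original field occurrences and GIS layers are not deposited,
this package ships a first-class synthetic-landscape generator that
reproduces the statistical structure of such a study — spatially
autocorrelated covariates, a categorical soil layer, road/river/resident
features with distance maps, a lake-shaped nodata region, presences drawn
from a known logistic suitability surface with roadside detection bias and
2-km thinning — so every stage of the pipeline can be validated against a
known truth.

## The model

Maxent fits a Gibbs density over the background cells x with feature
expansion f(x) (linear, quadratic, product, threshold, hinge and
categorical-indicator features of the covariates):

    q_λ(x) = exp(λ·f(x)) / Z(λ),   Z(λ) = Σ_background exp(λ·f(x))

choosing λ to maximize the L1-penalized log-likelihood of the m presences:

    J(λ) = (1/m) Σ_i λ·f(x_i) − ln Z(λ) − Σ_j β_j |λ_j|

J is concave; at the optimum with β = 0 the background expectation of every
feature equals its presence mean (exponential-family moment matching).  The
solver is a deterministic accelerated proximal-gradient method
(FISTA with backtracking and adaptive restart, soft-thresholding for the L1
term).  Outputs: the **raw** density (sums to 1 over background) and the
entropy-calibrated **logistic** suitability L(x) = e^H·raw/(1 + e^H·raw)
with H the entropy of q.

Around the model, the pipeline implements the full study protocol:
replicated 50/50 subsample validation (training/test AUC; TSS over a
decile threshold grid with max-TSS threshold selection), jackknife variable
importance (training gain with each variable alone / omitted), permutation
percent contributions, |r| > 0.75 correlation screening, max-TSS
binarization with suitable-area accounting, and paired with/without-human-
factors scenario comparison via the exact Wilcoxon signed-rank test.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic landscape (100×100 grid of 1-km cells, 9 covariate layers, 77
presences, 3,000 background cells):

```sh
python analysis/01_simulate_landscape.py   # writes the study bundle
python analysis/02_fit_and_validate.py     # replicated validation + maps
python analysis/03_variable_importance.py  # jackknife + selection
python analysis/04_human_factor_scenarios.py
```

`02_fit_and_validate.py` prints (seed 1):

```
20 replicates, seed 1
training AUC 0.8748 (SD 0.0125)
test AUC     0.8423 (SD 0.0146) -> good
max TSS      0.5622 (SD 0.0327) -> fair
max-TSS threshold 0.3000
suitable area 2744 km^2 (28.9% of valid land)
```

i.e. the model discriminates presences from background well ("good" on the
standard AUC grading), and thresholding the replicate-mean probability map
at the max-TSS point classifies 2,744 km² of the basin as suitable.
`03_variable_importance.py` shows the jackknife recovering the generating
truth — distance to road carries the highest with-only gain (0.65 nats) in
100% of 20 independently simulated studies, with soil type secondary —
and `04_human_factor_scenarios.py` quantifies the anthropogenic
contribution:

```
metric        with human     without    Wilcoxon p
train AUC         0.8705      0.7856      3.96e-18
test AUC          0.8477      0.7244      3.96e-18
max TSS           0.5658      0.3545      3.96e-18
dropping human factors moves test AUC from 'good' to 'fair'
suitable area: full 2900 km^2, reduced 2335 km^2 (extension 24.2%)
presence probability increases with human factors over 1669 km^2
```

All 100 paired replicates favor the full model, so the Wilcoxon p-values
saturate at the normal-approximation floor — the same qualitative verdict
as the real study: anthropogenic distance layers carry predictive
information that the environmental layers cannot replace.

The same pipeline is scriptable over real data through the `pikasdm` CLI
(`simulate`, `fit-evaluate`, `jackknife`, `map`, `compare`) with a YAML
config; see `pikasdm --help`.

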