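# Methods

This note records the modeling choices, parameter conventions, and known
limitations of the package, in the order the pipeline runs.

## Scales and panels

All marker intensities are analyzed on the arcsinh scale,
`asinh(raw / 5)`. The functional panel comprises 13 intracellular
phospho/total markers (pSTAT1/3/4/5/6, pMAPKAPK2, pCREB, pPLCγ2, pS6,
pERK1/2, pP38, pNFκB, IκB) shared with baseline-only clinical panels — the
space the transport maps operate in — plus 7 surface functional markers
(PD-1, PD-L1, CD25, CD36, CD44, GLUT1, HLA-DR) measured in the screen only.
With the full gating of 28 populations and 7 stimulations this yields
28 × 20 × (1 + 7) = 4,480 screen features per treatment arm, 364
overlap-panel baseline features, and 2,548 candidate response features.
Population medians use the midpoint convention for even cell counts.
A stimulation response is *strong* when its signed arcsinh difference to
unstimulated exceeds 0.1 (0.01 for IL-33, whose responses are small); an
absolute-value variant is available by flag since magnitude-based displays
are common.

## Combinatorial debarcoding

Samples carry 4-of-9 metal-channel barcodes (126 codes; the 96 of highest
purity are assigned to samples, the remaining 30 monitor misassignment).
Code purity is the product of its channels' isotopic purities — impurities
act multiplicatively — with lexicographic tie-breaks; shipped default
purities are placeholders (real values are lot-specific) and tests use
constructed ones. Assignment rescales each channel by its 95th-percentile
intensity over the stream, normalizes each event by its brightest rescaled
channel, and requires the gap between the 4th and 5th brightest channels to
strictly exceed the separation threshold (default 0.1). The per-event
normalization makes assignment invariant to common positive rescaling of an
event. Whether the original analyses threshold raw or rescaled separations
is ambiguous; we state and implement the rescaled reading. Doublets of
distinct codes have ≥ 5 near-equal top channels, hence separation ≈ 0 and
rejection — verified exhaustively over all 7,875 code pairs. No
Mahalanobis-distance or intensity-based secondary filtering is applied.

## Drug-screen statistics

Plates are 8 stimulation rows × 12 treatment columns with vehicle (DMSO)
in columns 1, 6, 12. Acquisition-time drift is modeled per donor per
feature by a smoothing spline across the 12 columns (order k = 2,
smoothing factor 1.5, vehicle columns at weight 2, drug columns at
weight 1), and the drug effect is the treated value minus the spline's
fitted value at the treated column. Two conventions follow the fitting
library (scipy's FITPACK wrapper): the smoothing factor bounds the weighted
residual sum of squares, and weights multiply residuals *inside* the
square, so vehicle residuals count 4× in that sum. With this budget the
fit typically reduces to the weighted least-squares parabola: a constant
row is returned exactly, an exact linear drift is reproduced, and a drug's
own effect leaks slightly into the control estimate (attenuation equal to
the hat value of its column, ≈ 15–20%). The fit intentionally includes
drug columns at weight 1 even when drugs have real effects; this mirrors
the screen design and the leakage is noted, not corrected.

Significance is a paired t test of per-donor effects against zero with
Benjamini–Hochberg correction at FDR 0.05, applied across all drug-feature
tests of a cohort analysis (per-drug correction by flag); zero-variance
effects report undefined p and are never significant. Effects are
categorized as stimulatory/amplifying vs inhibitory/neutralizing ×
{baseline, strong response, weak response}: amplifying means moving the
readout further from the unstimulated reference in the response's own
direction (or raising baseline activity for unstimulated features).
Cohort restriction is the specificity index |ΔP − ΔNP| / (|ΔP| + |ΔNP|)
(0 equal, 1 single-cohort, undefined when both vanish). Synergy of a
combination vs the sum of its components is classified with a tolerance
defaulting to the vehicle-triplicate SD of the feature — vehicle noise
defines "additive". Cumulative drug effects sum absolute significant
effect sizes (signed sums would cancel opposing effects). Pregnant vs
non-pregnant profile comparisons use Mann–Whitney U with BH correction,
prefiltered to features with group difference > 0.05 arcsinh.

## Transport maps

Each map's potentials are input-convex networks: hidden passthrough
weights are clamped non-negative after every optimizer step, activations
are leaky ReLU (slope 0.2), and the output adds a linear skip and a
learnable non-negative quadratic term α/2‖x‖² (initialized at α = 1 so the
map starts near the identity; α can shrink below 1 to represent
contractive maps). Training alternates `inner_iters` Adam updates of g per
update of f on resampled minibatches. Gradients are analytic, including
the second-order term of the g-objective (differentiating through ∇g):
with piecewise-linear activations the activation-curvature contributions
vanish almost everywhere, so a forward tangent pass plus one backward pass
reproduces what reverse-mode autodiff would compute; both first- and
second-order gradients are finite-difference-checked in the test suite.
The dual loss E[f(target)] − E[f(∇g(source))] is traced and must stay
finite; a non-finite value aborts with diagnostics.

Architecture and iteration conventions: the reference formulation exposes
both a four-layer bottleneck (128, 128, 64, 32) and a single latent-width
knob (42); we expose both, with `hidden_units=None` meaning four hidden
layers of `latent_dim` width — they are alternative parameterizations, not
composed. "Iterations" count outer iterations (each = inner g-updates + one
f-update). Profiles: `paper` (bottleneck widths, 50,000 iterations, inner
ratio 10, batch 256), `test` ((64, 64), 2,000 iterations, inner 5, batch
128) and `tiny` ((32, 32), 400 iterations) for synthetic work and the test
suite; on the synthetic generator's conditions the tiny profile already
recovers planted shifts to ≈ 0.01–0.05 arcsinh. Cells enter on the arcsinh
scale without standardization, keeping medians comparable across modules.
One master seed expands deterministically to per-map seeds keyed by
(cell type, perturbation); training is deterministic per seed.

Stimulation maps are trained from pooled unstimulated vehicle cells to
pooled stimulated vehicle cells, only for (cell type, stimulation)
combinations with ≥ 1 strong response; drug maps from vehicle to
drug-treated cells within each stimulation context plus the unstimulated
baseline context. Pooling subsamples to a configurable cap (default 5,000
cells per side). Missing conditions are skipped and logged, or raised under
`hard_fail`.

## Evaluation

Maps are scored under donor-grouped 4-fold cross-validation (folds are a
seeded permutation; no donor appears on both sides). Metrics per
(cell type, perturbation, held-out donor): MAE between predicted and
observed population medians; MMD between predicted and observed cell
distributions using a sum of Gaussian kernels at bandwidths 0.5×, 1×, 2×
the median-heuristic scale (biased estimator by default, unbiased by flag;
samples capped at a seeded subsample, default 2,000); and R², by default
the coefficient of determination of observed vs predicted medians across
markers (squared-Pearson mode available — the aggregation across 13
markers per cell type and donor vs across a stimulation's full feature set
is exportable either way). Controls: the *identity baseline* returns the
held-out donor's unperturbed cells (no effect learned); the *training
baseline* returns the training donors' perturbed cells (no
individualization). With donor heterogeneity (τ > 0) the learned map
preserves each donor's offset while the training baseline cannot, which is
the ordering the evaluation is designed to expose.

## Twin expansion

Baseline features of a twin are observed unstimulated medians; response
features are median(transported) − median(baseline). Treated twins use the
drug-at-baseline map for baseline features and compose the
drug-within-stimulation map *on the simulated stimulated cells* — matching
how those maps were trained (contextually per stimulation); composing on
baseline cells instead is a plausible alternative reading, flagged here.
The weak-response filter removes response features whose cross-sample
median is below 0.1 arcsinh, computed on untreated twins only (so the
filter cannot depend on the intervention) and applied identically to
treated matrices — treated and untreated feature indices are always
identical, which the treated-minus-untreated contrast requires. With
identity maps the entire downstream treatment effect is exactly zero.

## Outcome model

Stability selection augments the feature matrix with artificial noise
features built by permuting real columns (Gaussian noise by flag), two per
real feature — the larger pool stabilizes the false-discovery surrogate.
Over 50 subsamples of half the samples, a Lasso path is fitted at
penalties (0.05…0.5) × the data-derived maximal penalty; a feature's
selection frequency is its maximum over the path. The reliability
threshold minimizes (1 + #noise ≥ t) / max(1, #real ≥ t) over t ∈
[0.5, 1], ties to the larger t. Like knockoff-style rules, the +1 in the
numerator means a single true feature cannot be certified; on tiny feature
sets the selector may return empty, in which case the model falls back to
all features with a warning, and a fixed threshold can be passed instead.
Under an independent-outcome null, selections stay at the noise level (a
couple out of 200, usually zero).

The regressor is an XGBoost tree ensemble; its grid is searched under
patient-grouped K-fold CV with RMSE as the default criterion, or the AUROC
of the derived preterm classification (expected length = gestational day
at sampling + predicted time to labor, preterm below 259 days = 37 weeks)
when labels are supplied — the two-stage RMSE-then-AUROC flow the study
design describes. Fold models are refit per fold and kept: each held-out
sample's treatment effect is computed under its own fold model (refitting
per fold gives honest held-out deltas; a once-fitted global model would
not). Attributions are exact tree-path additive contributions
(per-sample contributions + expectation = prediction), summarized as mean
absolute attribution.

Treatment effects per sample are treated-minus-untreated predictions in
days; the time course is a 30-day left-closed rolling average anchored on
gestational day (edges use available data); per-patient aggregation sums
the patient's sample deltas (mean by flag) as a proxy for repeated dosing,
and the fraction of patients with positive aggregate is reported per drug.

## Synthetic immunome

The generator emulates the structure the pipeline needs, on the arcsinh
scale directly: per-marker cell values are Gaussian around
baseline + donor offset + stimulation shift + drug shift (+ optional
interaction terms for planting synergy, + optional linear plate-column
drift), with spread `cell_sd` (default 0.2, a typical arcsinh-scale
population width) times planted scale factors. Donor random effects are
additive offsets per (donor, cell type, marker), shared across all of that
donor's conditions — the heterogeneity transport maps must preserve. The
study did not characterize donor variance components, so the default
τ = 0.3 used in tests is a free parameter chosen as a realistic
between-donor spread relative to `cell_sd`; it is documented as such, not
estimated. An optional heavy-tail contamination flag (5% of values at 4×
spread) supports robustness checks. The clinical generator gives each
patient 1–3 unstimulated samples across gestational days 160–270 and sets
time to labor = Σ w·(true feature value) + Gaussian noise, clipped at 0,
with term/preterm labels from the 259-day cutoff on day + time-to-labor.
Defaults are deliberately modest (6 reduced cell types, 13 overlap
markers; the full 28-type gating is available by config) so tests run
quickly.

What the generator does **not** emulate: raw ion counts and their
Poisson-like noise, spillover, bead drift, acquisition-time effects beyond
the linear column drift, correlated marker programs, or cell-abundance
differences. Passing tests therefore demonstrate the correctness of the
computations and the recoverability of planted structure under idealized
Gaussian mixtures — not performance on real cytometry data.

## Problem sizes

The test suite and the reproduction script run everything at reduced
scale: transport oracles at (64, 64) widths, 2,000 iterations, 5,000
cells; atlas cross-validation and sign recovery at (32, 32) widths, 400
iterations, 4 donors, 500 cells per condition, 60 synthetic patients.
These sizes were chosen so the full pipeline demonstrates each property in
minutes on one CPU; the `paper` profile (full widths, 50,000 iterations)
is the intended setting for real screens.

## Known limitations

- The dual OT training is a saddle-point problem; very long runs can
  oscillate mildly around the optimum. The quadratic skip keeps the map
  well-behaved but adds a parameterization not present in the reference
  formulation.
- Per-feature, per-donor spline drift correction absorbs part of a real
  drug effect (hat-value attenuation); this is inherent to fitting drug
  columns at weight 1.
- Tree-ensemble outcome models saturate outside the training feature
  range, so very large simulated shifts produce conservative deltas.
- No uncertainty propagation from map estimation into treatment effects.
- FCS ingestion is not provided; data enter via the documented CSV schema.
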