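# immunotwin

Single-cell digital twins of the immunome for in silico drug screening.

Mass-cytometry perturbation screens measure how every circulating immune
cell type responds to ex vivo stimulation (LPS, IFNα, IL-33, GM-CSF, TNFα,
IL-2/4/6, PMA/ionomycin) in the presence or absence of candidate drugs. This
package turns such a screen into a predictive instrument: it learns
cell-type-specific **optimal-transport maps** of each perturbation, applies
them to *baseline-only* blood samples of unseen individuals to create
treated and untreated **digital twins**, and reads out the simulated drug
effect on a clinical outcome — here, time to spontaneous labor in pregnancy,
where immunomodulatory prevention of spontaneous preterm labor (sPTL) cannot
be screened by conventional trials. It also implements the screen's
supporting machinery: the choose-4-of-9 doublet-removing mass-tag barcoding
scheme, plate-drift-corrected drug-effect statistics, and a noise-augmented
sparse outcome model.

## The model

**Transport maps.** A perturbation response for one cell type is modeled as
a Monge map `T` pushing the unperturbed single-cell marker distribution `μ`
onto the perturbed distribution `ν` in the 13-dimensional space of
functional markers (arcsinh scale, cofactor 5). `T = ∇g` for a convex
potential `g`, learned with its conjugate partner `f` from *unpaired*
samples through the dual formulation of the squared-Wasserstein problem:

    min_g  E_{x∼μ} [ f(∇g(x)) − ⟨x, ∇g(x)⟩ ],
    min_f  E_{y∼ν} [ f(y) ] − E_{x∼μ} [ f(∇g(x)) ],

with alternating inner/outer updates. Both potentials are input-convex
neural networks (non-negative passthrough weights, leaky-ReLU activations,
a learnable non-negative quadratic skip), so convexity — and hence a valid
transport map — holds by construction. For Gaussians with shared covariance
the optimal map is the mean shift, which gives a closed-form training
oracle. One map is trained per (cell type, stimulation) with at least one
strong response (arcsinh difference > 0.1; 0.01 for IL-33) and per
(cell type, drug, stimulation context), including drug-at-baseline maps.

**Digital twins.** A clinical sample arrives as gated unstimulated cells.
Stimulation maps simulate its responses, producing a feature row over
`p × (s + 1)` features (baseline medians + simulated response medians);
drug maps then produce one treated row per drug on the identical feature
index. Weak simulated responses (cross-sample median < 0.1 arcsinh) are
removed from both matrices.

**Outcome model.** Time to labor is predicted from untreated twins by
noise-augmented stability selection (artificial permuted-column features, a
Lasso path over subsamples, a threshold minimizing a false-discovery
surrogate) followed by a gradient-boosted tree ensemble under
patient-grouped cross-validation. The simulated effect of a drug for a
held-out patient is `prediction(treated twin) − prediction(untreated twin)`
under that patient's fold model, in days; per-patient effects sum over the
patient's samples as a proxy for repeated dosing.

## Worked example

A small synthetic screen (2 cell types, LPS stimulation, one drug "THF"
planted to raise pSTAT1 in classical monocytes by 0.5 arcsinh — a feature
the outcome depends on positively):

```python
import numpy as np
from immunotwin import (
    GroundTruth, StabilitySelector, SyntheticConfig, TimeToLaborModel,
    ICNNConfig, feature_name, generate_atlas, generate_clinical_cohort,
    train_atlas_models, treatment_effect,
)
from immunotwin.twin import expand_cohort

cfg = SyntheticConfig(
    n_donors=4, n_cells=500, cell_types=("cMC", "NK"), stimulations=("LPS",),
    treatments=("THF",), markers=("pSTAT1", "pSTAT3"), seed=0,
)
truth = GroundTruth.from_effects(
    cfg,
    stim_effects={(ct, m, "LPS"): 0.5 for ct in cfg.cell_types for m in cfg.markers},
    drug_effects={("cMC", "pSTAT1", "THF"): 0.5},
    tau=0.3, outcome_noise=1.0,
)
truth.outcome_weights = {feature_name("cMC", "pSTAT1", "unstimulated", "baseline"): 40.0}

atlas = generate_atlas(cfg, truth)
registry = train_atlas_models(
    atlas,
    ICNNConfig(hidden_units=(32, 32), n_iters=400, inner_iters=3,
               batch_size=128, seed=0),
    markers=cfg.markers,
)

cohort, outcomes, _ = generate_clinical_cohort(
    cfg, truth, n_patients=60, samples_per_patient=(1, 2, 3), seed=2)
twins = expand_cohort(cohort, registry, ["THF"], ["LPS"]).penalized()
meta = outcomes.loc[twins.untreated.index]

model = TimeToLaborModel(selector=StabilitySelector(threshold=0.6, random_state=0),
                         random_state=0)
model.fit(twins.untreated, meta["time_to_labor"], groups=meta["patient_id"])
report = treatment_effect(model, twins.untreated, twins.treated,
                          meta["patient_id"], gestational_day=meta["gestational_day"])
```

Output:

```
trained 6 transport maps
selected features: ['cMC|pSTAT1|unstimulated|baseline']
held-out Pearson R: 0.99
median per-patient effect of THF: +37.4 days
patients predicted to benefit: 98.3%
```

The stability selector finds exactly the planted outcome feature; the model
predicts held-out patients' time to labor from it; and because the drug's
transport map shifts that feature upward, almost every patient's treated
twin is predicted to labor later — with the magnitude (≈ +37 days ≈ 40 × 2
samples × 0.5 shift, attenuated by tree-model saturation) following directly
from the planted link.

Every stage is also reachable from the command line (`immunotwin
simulate-atlas | simulate-cohort | simulate-barcodes | debarcode |
screen-effects | train-ot | evaluate | expand-twin | fit-outcome`).

## Data formats

Cell tables are long-format CSV with metadata columns `donor, cohort,
cell_type, stimulation, treatment, replicate` followed by one column per
marker (arcsinh scale), plus a JSON manifest; feature matrices use compound
column names `celltype|marker|stimulation|stat` with
`stat ∈ {baseline, response}`. Barcode schemes and synthetic configurations
are YAML.

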