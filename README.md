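# gnnr — group + nuclear norm regularized regression for longitudinal omics

Longitudinal two-class omics studies (e.g. nontargeted LC-MS metabolomics
sampled at several time points after an intervention) are usually analyzed
cross-sectionally: one PLS-DA model per time point, variables selected by
VIP score, and the per-time selections compared afterwards. That discards
the temporal structure — a marker of the underlying physiological process
should discriminate over a *period*, not at one isolated time point, and
sets selected cross-sectionally overlap poorly across time points.

`gnnr` implements a multitask alternative. Given a cube
χ = {X₁, …, X_T} ∈ ℝ^(d×n×T) of d variables, n samples tracked over T time
points, and labels y ∈ {−1, +1}ⁿ, it fits one linear model per time point
with a shared coefficient matrix B = [β₁, …, β_T] ∈ ℝ^(d×T):

    min_B  ½ Σ_t ‖y_t − X_tᵀ β_t‖²  +  γ₁ Σ_j ‖βʲ‖₂  +  γ₂ ‖B‖*

* the **l2,1 group norm** Σ_j ‖βʲ‖₂ (sum over variable rows) drives entire
  rows toward zero, selecting a common compact variable set across time
  points (setting γ₂ = 0 gives the LFS baseline);
* the **nuclear norm** ‖B‖* = Σᵢ σᵢ(B) pulls the per-time models toward a
  shared low-rank structure, encoding the similarity of association
  patterns at consecutive time points.

The solver is the method's iteratively reweighted least-squares scheme:
D(j,j) = ½(Σ_t b_tj² + ε)^(−1/2), D̃ = ½(BBᵀ + εI)^(−1/2), and per-time
updates β_t = (X_tX_tᵀ + γ₁D + γ₂D̃)⁻¹X_t y_t, repeated to convergence.

The package also provides

* **PLS-DA with VIP scores** (the cross-sectional baseline),
* **validation statistics**: leave-one-pair-out CV with the conditional
  expected AUC, discriminant Q² (DQ², which ignores prediction error
  beyond the class label), accuracy/NMC, stratified k-fold splitting,
* **minimax-regret hyperparameter selection** over the decade grid
  {10⁻⁶, …, 1, …, 10³},
* a **synthetic longitudinal generator** with ground-truth marker groups
  (profile means {2.1, 1.7, 1.2, −1.3}, SD 1.5; 1500 variables × 100
  samples × 4 time points by default) and recovery-ratio scoring,
* a thin CLI (`gnnr simulate|fit|select|evaluate|tune`).

## Worked example

```python
import numpy as np
from gnnr import (GeneratorConfig, RegularizationConfig, generate_dataset,
                  fit_gnnr, select_top_n, recovery_ratios, evaluate_longitudinal)

dataset, truth = generate_dataset(
    config=GeneratorConfig(n_per_class=15, n_background=200, seed=7))
fit = fit_gnnr(dataset, RegularizationConfig(gamma1=1.0, gamma2=0.1))
ratios = recovery_ratios(select_top_n(fit.B, [40, 50, 50, 50]), truth)
print("persistent marker group 5 recovery:", np.round(ratios[4], 2))
print("background false recovery:        ", np.round(ratios[-1], 3))

rep = evaluate_longitudinal(
    dataset,
    lambda d: fit_gnnr(d, RegularizationConfig(gamma1=1.0, gamma2=0.1,
                                               max_iter=50, tol=1e-5)),
    cv="stratified:5", seed=1)
print("CE_AUC per time point:", np.round(rep.ce_auc, 3))
print("DQ2 per time point:   ", np.round(rep.dq2, 3))
```

prints

```
persistent marker group 5 recovery: [0.98 1.   1.   1.  ]
background false recovery:         [0. 0. 0. 0.]
CE_AUC per time point: [1. 1. 1. 1.]
DQ2 per time point:    [0.982 0.985 0.984 0.985]
```

The persistent marker group (class means 2.1 vs −1.3 at every time point)
is essentially fully recovered by the top-ranked coefficients, no
uninformative background variable is selected, and the cross-validated
statistics confirm near-perfect out-of-sample separation (CE_AUC = 1) with
predictions close to the ±1 label targets (DQ² ≈ 0.98).

The scripts in `examples/` walk through each capability: loading CSV cubes
(`load_and_fit.py`, with a 3×2×2 toy dataset in `examples/data/`),
simulation + recovery scoring (`simulate_and_recover.py`), cross-sectional
PLS-DA/VIP with Venn-overlap counting (`plsda_vip.py`), and grid search
with minimax-regret selection (`tune_minimax.py`).

## Data formats

A dataset on disk is one CSV matrix per time point (`X_<time>.csv`,
d rows × n columns, first column `variable_id`, header = sample ids —
variables in rows to match X_t ∈ ℝ^(d×n)), plus `labels.csv`
(`sample_id,label` with labels in {−1, +1}). A single long-format table
(`sample_id,time_id,variable_id,value,label`) is also accepted. Ground
truth for simulated data is `groups.csv` (`variable_id,group_id`) plus a
JSON sidecar of each group's discriminative time points. Missing values
are rejected at load time.

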