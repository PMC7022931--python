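"""Tune regularization by cross-validated DQ2 and minimax regret.

Runs the grid search on a small simulated dataset, prints the DQ2 of each
candidate at each time point, and selects the parameter point whose worst
distance-from-optimum across time points is smallest.
"""

import warnings

import numpy as np

from gnnr import GeneratorConfig, generate_dataset, grid_search, minimax_regret
from gnnr.regression import RegularizationConfig

warnings.simplefilter("ignore", RuntimeWarning)

dataset, _ = generate_dataset(config=GeneratorConfig(n_per_class=15, n_background=100, seed=5))
grid = [0.01, 0.1, 1.0, 10.0]
result = grid_search(
    dataset,
    method="gnnr",
    grid=grid,
    cv="stratified:5",
    seed=5,
    config=RegularizationConfig(max_iter=50, tol=1e-5),
)

dq2 = result.values("dq2")
print("cross-validated DQ2 per (gamma1, gamma2) and time point:")
for point, row in zip(result.params, dq2):
    print(f"  g1={point['gamma1']:<5g} g2={point['gamma2']:<5g}  "
          + " ".join(f"{v:.3f}" for v in row))

best = minimax_regret(result, metric="dq2")
print(f"\nminimax-regret selection: gamma1={best['gamma1']}, gamma2={best['gamma2']}")
print("(the point whose worst shortfall from each time point's optimum is smallest;"
      "\n ties go to the stronger, more parsimonious regularization)")
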