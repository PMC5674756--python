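"""Fit zero-inflated data with the Hurdle noise model and impute dropouts.

Dropout zeroes roughly half the entries (detection-limit thresholding at 0).
The Hurdle model treats zeros through a logistic zero process on the latent
expression instead of as real measurements, so factor recovery survives,
and residual/imputed matrices replace zeros by the posterior latent value.
"""

import numpy as np

from pathfa import (
    DropoutConfig,
    FitConfig,
    SimulationConfig,
    residual_expression,
    simulate_dataset,
)
from pathfa.pipeline import fit_simulated, score_replicate

cfg = SimulationConfig(
    n_cells=80, n_genes=800, n_active_pathways=3, n_negative_pathways=5,
    set_size_range=(20, 50), noise_sd=0.1,
    dropout=DropoutConfig(mechanism="threshold", threshold=0.0), seed=9,
)
sim = simulate_dataset(cfg)
zero_frac = (sim.Y.values == 0).mean()
print(f"dropout zeroed {zero_frac:.0%} of entries")

fitted = fit_simulated(sim, n_dense=1, noise="hurdle",
                       fit_config=FitConfig(max_iter=150, tol=1e-5), seed=9)
print(f"driver-recovery AUC under dropout: "
      f"{score_replicate(fitted, sim)['auc_driver']:.3f}")

imputed = residual_expression(fitted, sim.Y, [])
zeros = sim.Y.values == 0
latent_truth = (sim.X_true @ sim.W_true.T)[zeros]
corr = np.corrcoef(imputed.values[zeros], latent_truth)[0, 1]
print(f"corr(imputed values at dropout sites, true latent expression): "
      f"{corr:.3f}")
print("High AUC and a strong imputation correlation show the zero process")
print("recovers structure the Gaussian model would treat as real zeros.")
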