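"""Replicate-level benchmark: how reliably are true drivers recovered?

Runs the simulate -> fit -> score loop over independent replicates of one
simulation setting (with annotation corruption) and summarizes the ROC AUC
for ranking true driver pathways by relevance, plus the annotation-repair
AUCs.
"""

from pathfa import FitConfig, SimulationConfig
from pathfa.pipeline import run_benchmark

cfg = SimulationConfig(
    n_cells=60, n_genes=800, n_active_pathways=5, n_negative_pathways=10,
    set_size_range=(20, 50), noise_sd=0.1, fnr_sim=0.10, fpr_sim=0.05, seed=4,
)
per_rep, summary = run_benchmark(
    cfg, n_reps=5, n_sparse=0, n_dense=0,
    fit_config=FitConfig(max_iter=150, tol=1e-5),
    setting_label="corrupted_10_5",
)
print(per_rep.to_string(index=False))
print()
print(summary.to_string(index=False))
print("\nauc_driver: ranking true drivers above negative-control sets;")
print("auc_added / auc_removed: repairing deleted / inserted annotations.")
print("The reference protocol uses 50 replicates; 5 keep this example quick.")
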