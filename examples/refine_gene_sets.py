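"""Repair a corrupted gene-set annotation from the indicator posterior.

The simulation deletes 10% of each active set's genes and inserts 5%
foreign genes before the model sees the annotation. Genes with posterior
inclusion probability above 0.5 that were not annotated are 'added';
annotated genes falling below 0.5 are 'removed'. Against the recorded
corruption we can score how well the edits undo the damage.
"""

from pathfa import FitConfig, SimulationConfig, refine_gene_sets, simulate_dataset
from pathfa.pipeline import fit_simulated, score_replicate

cfg = SimulationConfig(
    n_cells=100, n_genes=1000, n_active_pathways=5, n_negative_pathways=15,
    set_size_range=(20, 60), noise_sd=0.1, fnr_sim=0.10, fpr_sim=0.05, seed=2,
)
sim = simulate_dataset(cfg)
print(f"corruption: {len(sim.corruption.deleted)} genes deleted, "
      f"{len(sim.corruption.inserted)} inserted")

fitted = fit_simulated(sim, n_sparse=0, n_dense=0,
                       fit_config=FitConfig(max_iter=200, tol=1e-5), seed=2)

refinement = refine_gene_sets(fitted)
deleted = set(map(tuple, sim.corruption.deleted))
for name in sorted(refinement.per_factor):
    if not name.startswith("active"):
        continue
    added = refinement.added(name)
    hits = sum((name, g) in deleted for g, _ in added)
    print(f"{name}: {len(added)} genes added ({hits} were true deletions), "
          f"{len(refinement.removed(name))} removed")

scores = score_replicate(fitted, sim)
print(f"\nAUC re-including deleted genes: {scores['auc_added']:.3f}")
print(f"AUC expelling inserted genes:   {scores['auc_removed']:.3f}")
print("Both near 1 means the posterior cleanly separates wrongly-annotated")
print("genes from correct ones.")
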