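import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pathfa import (
    AnnotationMatrix,
    ExpressionMatrix,
    FitConfig,
    SimulationConfig,
    simulate_dataset,
)
from pathfa.inference import fit
from pathfa.model_core import assemble_model, initialize_state

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_annotation(G, sets, gene_prefix="g"):
    """Annotation from {name: [gene indices]} over G genes."""
    gene_ids = np.array([f"{gene_prefix}{i}" for i in range(G)], dtype=object)
    names = np.array(list(sets.keys()), dtype=object)
    inc = np.zeros((G, len(sets)), dtype=np.int8)
    for a, idx in enumerate(sets.values()):
        inc[np.asarray(idx, dtype=int), a] = 1
    return AnnotationMatrix(inc, gene_ids, names)


def make_expression(values, scale="log_counts", gene_ids=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    cells = np.array([f"c{i}" for i in range(n)], dtype=object)
    genes = (
        np.asarray(gene_ids, dtype=object)
        if gene_ids is not None
        else np.array([f"g{i}" for i in range(g)], dtype=object)
    )
    return ExpressionMatrix(values, cells, genes, scale)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with one confounder and mild corruption."""
    cfg = SimulationConfig(
        n_cells=60, n_genes=400, n_active_pathways=3, n_negative_pathways=5,
        set_size_range=(20, 40), n_confounders=1,
        confounder_gene_range=(80, 150), noise_sd=0.1,
        fnr_sim=0.1, fpr_sim=0.05, seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fitted(small_sim):
    state = assemble_model(
        small_sim.Y, small_sim.corrupted_annotation, n_sparse=0, n_dense=1
    )
    state = initialize_state(state, small_sim.Y, seed=0)
    return fit(state, small_sim.Y, FitConfig(max_iter=120, tol=1e-6))
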