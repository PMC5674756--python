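"""Generative model: factor taxonomy, priors, and the full variational state.

The model decomposes a cells x genes expression matrix as

    Y = X W^T + psi,

where the K = C + A + H columns of X are known covariates, annotated
(pathway) factors, and unannotated factors, and psi is noise whose form
depends on the chosen model (Gaussian, Hurdle, Poisson). Weights carry a
spike-and-slab prior: w_gk ~ N(0, 1/alpha_k) when the regulatory link
z_gk = 1 and a point mass at zero otherwise. Pathway membership enters as
Bernoulli evidence on z_gk with assumed annotation error rates FPR and FNR,
contributing fixed prior odds of +-log((1-FPR)/FNR) to each indicator — a
nudge the data can overrule for genes with strong (mis)fit, which is what
drives gene-set refinement. A Gamma hyperprior on each alpha_k (automatic
relevance determination) lets unneeded factors switch off; 1/alpha_k is the
factor's relevance.

This module owns the state containers and everything prior-related; the
coordinate-ascent updates live in :mod:`pathfa.inference`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import digamma, expit

from .data_io import CovariateTable, ExpressionMatrix
from .gene_sets import AnnotationMatrix

# Fixed broad prior precision for covariate-factor weights (incl. the
# per-gene intercept added under Hurdle/Poisson noise): these columns are
# effectively unregularized and excluded from ARD.
COVARIATE_ALPHA = 1e-6

_KINDS = ("covariate", "annotated", "sparse_unannotated", "dense_unannotated")


@dataclass
class FactorSpec:
    """One latent factor: its kind, indicator prior, and bindings."""

    name: str
    kind: str
    prior_pi: float = 0.5
    annotation_column: int | None = None
    fixed_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if (self.kind == "annotated") != (self.annotation_column is not None):
            raise ValueError("annotated factors (exactly) must set annotation_column")
        if (self.kind == "covariate") != (self.fixed_states is not None):
            raise ValueError("covariate factors (exactly) must set fixed_states")
        if not (0.0 < self.prior_pi < 1.0) and self.kind != "covariate":
            raise ValueError("prior_pi must lie in (0, 1)")


@dataclass
class Hyperparameters:
    """Prior hyperparameters.

    ``fnr``/``fpr`` are the assumed annotation error rates of the gene-set
    database relative to the true regulatory support. ``ard_a``/``ard_b``
    parameterize the broad Gamma prior on factor precisions alpha_k, and
    ``noise_a``/``noise_b`` the Gamma prior on per-gene residual precisions.
    """

    fnr: float = 0.001
    fpr: float = 0.01
    ard_a: float = 1e-3
    ard_b: float = 1e-3
    noise_a: float = 1e-3
    noise_b: float = 1e-3
    prior_pi_annotated: float = 0.5
    prior_pi_sparse: float = 0.01
    prior_pi_dense: float = 0.99

    def __post_init__(self) -> None:
        for name in ("fnr", "fpr", "prior_pi_annotated", "prior_pi_sparse",
                     "prior_pi_dense"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("ard_a", "ard_b", "noise_a", "noise_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def annotation_loglik(z: int, I: int, hyper: Hyperparameters, n_cells: int) -> float:
    """Log-likelihood of an annotation entry, replicated once per cell.

    With the link active (z=1) the database entry is Bernoulli(1-FPR); with
    it inactive, Bernoulli(FNR). Replication by ``n_cells`` keeps the
    annotation's contribution to the indicator posterior proportional to the
    data's, independent of dataset size.
    """
    if z not in (0, 1) or I not in (0, 1):
        raise ValueError("z and I must be binary")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if z == 1:
        p1 = 1.0 - hyper.fpr
    else:
        p1 = hyper.fnr
    return n_cells * (math.log(p1) if I == 1 else math.log1p(-p1))


def annotation_evidence_matrix(
    annotation: AnnotationMatrix, spec: list[FactorSpec],
    hyper: Hyperparameters, n_cells: int,
) -> np.ndarray:
    """G x K matrix of log p(I|z=1) - log p(I|z=0), times n_cells.

    Zero for factors without an annotation column; added to the indicator
    log-odds inside the weight update.
    """
    G = annotation.n_genes
    K = len(spec)
    delta = np.zeros((G, K))
    l1_1 = math.log(1.0 - hyper.fpr)
    l1_0 = math.log(hyper.fpr)
    l0_1 = math.log(hyper.fnr)
    l0_0 = math.log1p(-hyper.fnr)
    for k, f in enumerate(spec):
        if f.annotation_column is None:
            continue
        I = annotation.incidence[:, f.annotation_column].astype(float)
        delta[:, k] = n_cells * (I * (l1_1 - l0_1) + (1 - I) * (l1_0 - l0_0))
    return delta


@dataclass
class ModelState:
    """All variational posteriors plus the model configuration.

    Factorization: q(X) Gaussian, fully factorized over cells and factors
    (covariate columns are point masses at their fixed states); q(w, z)
    coupled per gene-factor pair — gamma = q(z=1), (W_mean1, W_var1) the
    slab moments given z=1, so E[w] = gamma * W_mean1; q(alpha_k) and
    q(tau_g) Gamma.
    """

    spec: list[FactorSpec]
    annotation: AnnotationMatrix
    hyper: Hyperparameters
    noise: str
    n_cells: int
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    X_mean: np.ndarray = None
    X_var: np.ndarray = None
    gamma: np.ndarray = None
    W_mean1: np.ndarray = None
    W_var1: np.ndarray = None
    alpha_shape: np.ndarray = None
    alpha_rate: np.ndarray = None
    tau_shape: np.ndarray = None
    tau_rate: np.ndarray = None
    gene_means: np.ndarray | None = None  # Gaussian centering offsets
    elbo_trace: list = field(default_factory=list)
    initialized: bool = False
    seed: int | None = None

    # --- derived structure -------------------------------------------------
    @property
    def n_factors(self) -> int:
        return len(self.spec)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.spec]

    @property
    def kinds(self) -> np.ndarray:
        return np.array([f.kind for f in self.spec], dtype=object)

    @property
    def is_covariate(self) -> np.ndarray:
        return np.array([f.kind == "covariate" for f in self.spec], dtype=bool)

    @property
    def prior_pi(self) -> np.ndarray:
        return np.array(
            [1.0 if f.kind == "covariate" else f.prior_pi for f in self.spec]
        )

    def factor_index(self, name: str) -> int:
        names = self.factor_names
        try:
            return names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown factor {name!r}; known factors: {names}"
            ) from None

    def annotated_indices(self) -> list[int]:
        return [k for k, f in enumerate(self.spec) if f.kind == "annotated"]

    # --- posterior moments -------------------------------------------------
    def expected_weights(self) -> np.ndarray:
        """E[w] = gamma * slab mean (spike contributes zero)."""
        return self.gamma * self.W_mean1

    def expected_w2(self) -> np.ndarray:
        """E[w^2] = gamma * (slab mean^2 + slab var)."""
        return self.gamma * (self.W_mean1**2 + self.W_var1)

    def e_alpha(self) -> np.ndarray:
        out = self.alpha_shape / self.alpha_rate
        out[self.is_covariate] = COVARIATE_ALPHA
        return out

    def e_log_alpha(self) -> np.ndarray:
        out = digamma(self.alpha_shape) - np.log(self.alpha_rate)
        out[self.is_covariate] = math.log(COVARIATE_ALPHA)
        return out

    def e_tau(self) -> np.ndarray:
        return self.tau_shape / self.tau_rate

    def e_log_tau(self) -> np.ndarray:
        return digamma(self.tau_shape) - np.log(self.tau_rate)

    def expected_latent(self) -> np.ndarray:
        """E[F] = E[X] E[W]^T (plus gene means under Gaussian centering)."""
        F = self.X_mean @ self.expected_weights().T
        if self.gene_means is not None:
            F = F + self.gene_means[None, :]
        return F

    def latent_variance(self) -> np.ndarray:
        """Var[F] under the factorized posterior."""
        Ex2 = self.X_mean**2 + self.X_var
        Ew2 = self.expected_w2()
        W_mean = self.expected_weights()
        return Ex2 @ Ew2.T - (self.X_mean**2) @ (W_mean**2).T

    def config_json(self) -> str:
        cfg = {
            "noise": self.noise,
            "n_cells": int(self.n_cells),
            "n_genes": int(self.n_genes),
            "seed": self.seed,
            "hyperparameters": {
                k: float(v) for k, v in vars(self.hyper).items()
            },
            "factors": [
                {"name": f.name, "kind": f.kind, "prior_pi": float(f.prior_pi)}
                for f in self.spec
            ],
        }
        return json.dumps(cfg, indent=2)


def _validate_noise_scale(Y: ExpressionMatrix, noise: str) -> None:
    if noise not in ("gaussian", "hurdle", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    if noise == "poisson" and Y.scale != "raw_counts":
        raise ValueError("the Poisson noise model requires raw counts")
    if noise == "hurdle" and np.any(Y.values < 0):
        raise ValueError(
            "the Hurdle noise model requires non-negative values "
            "(zeros are modelled as dropout candidates)"
        )


def gaussian_targets(state: ModelState, Y: ExpressionMatrix) -> np.ndarray:
    """The latent-Gaussian target scale of each noise model.

    Gaussian: the (centered) matrix itself. Hurdle/Poisson: log(y+1), the
    scale on which factors act; used for initialization heuristics.
    """
    if state.noise == "gaussian":
        return Y.values - state.gene_means[None, :]
    T = np.log1p(Y.values)
    if state.gene_means is not None:  # zero-free Hurdle reduction
        T = T - state.gene_means[None, :]
    return T


def assemble_model(
    Y: ExpressionMatrix,
    annotation: AnnotationMatrix,
    covariates: CovariateTable | None = None,
    n_sparse: int = 5,
    n_dense: int = 3,
    hyper: Hyperparameters | None = None,
    noise: str = "gaussian",
) -> ModelState:
    """Instantiate the (unfitted) model state.

    Factors are laid out in fixed order: covariates, annotated (one per
    annotation column), sparse unannotated, dense unannotated. Under
    Gaussian noise genes are mean-centered (the offsets are kept and
    restored downstream); under Hurdle/Poisson noise a per-gene intercept is
    added as a fixed all-ones covariate instead, since centering is
    undefined for the zero process. A Hurdle model on data without zeros
    has no zero process, so it reduces exactly to the Gaussian model on
    log(y+1): centering applies and no intercept factor is added.
    """
    hyper = hyper or Hyperparameters()
    if n_sparse < 0 or n_dense < 0:
        raise ValueError("n_sparse and n_dense must be >= 0")
    _validate_noise_scale(Y, noise)
    if annotation.n_genes != Y.n_genes or not np.array_equal(
        annotation.gene_ids, Y.gene_ids
    ):
        raise ValueError(
            "annotation gene order must equal the expression matrix's gene order"
        )
    if covariates is not None and covariates.values.shape[0] != Y.n_cells:
        raise ValueError("covariate rows must match cell count")

    hurdle_zero_free = noise == "hurdle" and not np.any(Y.values == 0)
    spec: list[FactorSpec] = []
    if noise == "poisson" or (noise == "hurdle" and not hurdle_zero_free):
        spec.append(
            FactorSpec(
                "_intercept", "covariate", prior_pi=1.0,
                fixed_states=np.ones(Y.n_cells),
            )
        )
    if covariates is not None:
        for j, name in enumerate(covariates.names):
            spec.append(
                FactorSpec(
                    str(name), "covariate", prior_pi=1.0,
                    fixed_states=covariates.values[:, j].copy(),
                )
            )
    for a, name in enumerate(annotation.set_names):
        spec.append(
            FactorSpec(
                str(name), "annotated",
                prior_pi=hyper.prior_pi_annotated, annotation_column=a,
            )
        )
    for h in range(n_sparse):
        spec.append(
            FactorSpec(
                f"sparse_{h + 1}", "sparse_unannotated",
                prior_pi=hyper.prior_pi_sparse,
            )
        )
    for h in range(n_dense):
        spec.append(
            FactorSpec(
                f"dense_{h + 1}", "dense_unannotated",
                prior_pi=hyper.prior_pi_dense,
            )
        )
    names = [f.name for f in spec]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate factor names: {dup}")

    if noise == "gaussian":
        gene_means = Y.values.mean(axis=0)
    elif hurdle_zero_free:
        gene_means = np.log1p(Y.values).mean(axis=0)
    else:
        gene_means = None
    return ModelState(
        spec=spec,
        annotation=annotation,
        hyper=hyper,
        noise=noise,
        n_cells=Y.n_cells,
        cell_ids=Y.cell_ids,
        gene_ids=Y.gene_ids,
        gene_means=gene_means,
    )


def initialize_state(
    state: ModelState, Y: ExpressionMatrix, seed: int = 0
) -> ModelState:
    """Deterministically initialize all variational posteriors.

    Annotated factor states start at the leading principal-component score
    of their annotated-gene submatrix (unit variance, sign fixed so the
    loading vector sums positive); dense unannotated states at successive
    leading principal components of the whole matrix, so likely-confounding
    broad variance is absorbed by dense factors from the first sweep rather
    than leaking into collinear annotated factors; sparse unannotated
    states at seeded standard normals. Indicators start at the
    annotation-implied posterior under the indicator prior; slab means at
    zero (intercept at the per-gene target mean); alpha at its prior mean;
    tau at 1/empirical gene variance.
    """
    if state.initialized:
        raise ValueError("state is already initialized")
    rng = np.random.default_rng(seed)
    N, G, K = state.n_cells, state.n_genes, state.n_factors
    hyper = state.hyper

    T = gaussian_targets(state, Y)
    Tc = T - T.mean(axis=0)

    n_dense = sum(f.kind == "dense_unannotated" for f in state.spec)
    if n_dense:
        from sklearn.utils.extmath import randomized_svd

        n_pc = min(n_dense, N - 1, G)
        u_pc, s_pc, vt_pc = randomized_svd(
            Tc, n_components=n_pc, random_state=int(seed) % (2**32)
        )

    X_mean = np.zeros((N, K))
    X_var = np.ones((N, K))
    dense_seen = 0
    for k, f in enumerate(state.spec):
        if f.kind == "covariate":
            X_mean[:, k] = f.fixed_states
            X_var[:, k] = 0.0
        elif f.kind == "annotated":
            genes = state.annotation.incidence[:, f.annotation_column] == 1
            sub = Tc[:, genes]
            u, s, vt = np.linalg.svd(sub, full_matrices=False)
            score = u[:, 0] * s[0]
            if vt[0].sum() < 0:
                score = -score
            sd = score.std()
            X_mean[:, k] = score / sd if sd > 0 else 0.0
        elif f.kind == "dense_unannotated" and dense_seen < n_pc:
            score = u_pc[:, dense_seen] * s_pc[dense_seen]
            if vt_pc[dense_seen].sum() < 0:
                score = -score
            sd = score.std()
            X_mean[:, k] = score / sd if sd > 0 else rng.standard_normal(N)
            dense_seen += 1
        else:
            X_mean[:, k] = rng.standard_normal(N)

    delta = annotation_evidence_matrix(state.annotation, state.spec, hyper, 1)
    logit_pi = np.array(
        [0.0 if f.kind == "covariate" else math.log(f.prior_pi / (1 - f.prior_pi))
         for f in state.spec]
    )
    gamma = expit(logit_pi[None, :] + delta)
    gamma = np.clip(gamma, 1e-10, 1 - 1e-10)
    gamma[:, state.is_covariate] = 1.0

    W_mean1 = np.zeros((G, K))
    W_var1 = np.ones((G, K))
    for k, f in enumerate(state.spec):
        if f.kind == "covariate":
            W_var1[:, k] = 1.0 / COVARIATE_ALPHA
            if f.name == "_intercept":
                if state.noise == "poisson":
                    lam = np.maximum(Y.values.mean(axis=0), 1e-3)
                    W_mean1[:, k] = np.log(np.expm1(lam))
                else:
                    # per-gene mean of log(y+1) over nonzero observations
                    vals = np.log1p(Y.values)
                    nz = Y.values != 0
                    cnt = np.maximum(nz.sum(axis=0), 1)
                    W_mean1[:, k] = (vals * nz).sum(axis=0) / cnt

    # alpha posterior concentrated at the prior mean
    prior_mean_alpha = hyper.ard_a / hyper.ard_b
    alpha_shape = np.ones(K)
    alpha_rate = np.full(K, 1.0 / prior_mean_alpha)

    var_g = np.maximum(Tc.var(axis=0), 1e-8)
    tau_shape = np.ones(G)
    tau_rate = var_g.copy()

    return replace(
        state,
        X_mean=X_mean,
        X_var=X_var,
        gamma=gamma,
        W_mean1=W_mean1,
        W_var1=W_var1,
        alpha_shape=alpha_shape,
        alpha_rate=alpha_rate,
        tau_shape=tau_shape,
        tau_rate=tau_rate,
        elbo_trace=[],
        initialized=True,
        seed=seed,
    )
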