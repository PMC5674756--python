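"""Independent oracles used by unit and acceptance tests.

These deliberately avoid the package's own algebra: evidences come from
multivariate-normal densities over the raw observations and slab moments
from numerical quadrature.
"""

import numpy as np
from scipy.stats import multivariate_normal, norm

from pathfa.gene_sets import AnnotationMatrix
from pathfa.model_core import FactorSpec, Hyperparameters, ModelState


def enumerate_spike_slab(y, x, tau, alpha, pi):
    """Exact posterior of (z, w) for one gene and one factor with fixed
    states, by enumeration over z with conjugate integration over w.

    y ~ N(x w z, 1/tau) elementwise; w ~ N(0, 1/alpha); z ~ Bernoulli(pi).
    Returns (gamma, slab mean, slab variance); slab moments via quadrature.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    cov0 = np.eye(n) / tau
    cov1 = cov0 + np.outer(x, x) / alpha
    log_z1 = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov1)
    log_z0 = multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov0)
    logit = np.log(pi / (1 - pi)) + log_z1 - log_z0
    gamma = 1.0 / (1.0 + np.exp(-logit))

    def log_unnorm(w):
        return norm.logpdf(w, 0, 1 / np.sqrt(alpha)) + np.sum(
            norm.logpdf(y[:, None], x[:, None] * w[None, :], 1 / np.sqrt(tau)),
            axis=0,
        )

    # locate the posterior mode and width numerically, then integrate a
    # fine grid spanning many posterior standard deviations
    lim = 1 / np.sqrt(alpha) * 8 + 8
    coarse = np.linspace(-lim, lim, 4001)
    lu = log_unnorm(coarse)
    center = coarse[np.argmax(lu)]
    half = lu >= lu.max() - 0.5
    width = max(coarse[half][-1] - coarse[half][0], 1e-6)
    grid = np.linspace(center - 12 * width, center + 12 * width, 400_001)
    dens = np.exp(log_unnorm(grid) - lu.max())
    z = np.trapezoid(dens, grid)
    mean = np.trapezoid(grid * dens, grid) / z
    var = np.trapezoid((grid - mean) ** 2 * dens, grid) / z
    return gamma, mean, var


def single_gene_factor_state(y, x, tau, alpha, pi, kind="sparse_unannotated"):
    """A 1-gene ModelState whose single factor has point-mass states ``x``
    and (near-)point-mass alpha/tau, for exercising the coupled update."""
    n = len(x)
    ann = AnnotationMatrix(
        np.zeros((1, 0), dtype=np.int8),
        np.array(["g0"], dtype=object),
        np.array([], dtype=object),
    )
    spec = [FactorSpec("f", kind, prior_pi=pi)]
    big = 1e12  # alpha posterior concentrated: E[alpha]=alpha, E[log alpha]~=log alpha
    state = ModelState(
        spec=spec, annotation=ann, hyper=Hyperparameters(), noise="gaussian",
        n_cells=n,
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_ids=ann.gene_ids,
        X_mean=np.asarray(x, float)[:, None],
        X_var=np.zeros((n, 1)),
        gamma=np.full((1, 1), pi),
        W_mean1=np.zeros((1, 1)),
        W_var1=np.ones((1, 1)),
        alpha_shape=np.array([big]),
        alpha_rate=np.array([big / alpha]),
        tau_shape=np.array([big]),
        tau_rate=np.array([big / tau]),
        gene_means=np.zeros(1),
        initialized=True,
    )
    return state


def mann_whitney_auc(scores, labels):
    """AUC by exhaustive concordant-pair counting (ties credit 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
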