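"""Downstream outputs of a fitted model: relevance, refinement, residuals,
factor-state export, and the sparse-factor diagnostic."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .inference import FittedModel


@dataclass
class FactorRelevance:
    name: str
    kind: str
    relevance: float
    n_annotated: int
    n_gained: int
    n_lost: int
    rank: int


@dataclass
class RelevanceReport:
    """Factors ranked by relevance = posterior mean of 1/alpha_k."""

    factors: list[FactorRelevance] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {f.name: f.relevance for f in self.factors}

    def ranking(self) -> list[str]:
        return [f.name for f in sorted(self.factors, key=lambda f: f.rank)]


@dataclass
class RefinementResult:
    """Genes added to / removed from each annotated factor's set."""

    per_factor: dict[str, dict[str, list[tuple[str, float]]]] = field(
        default_factory=dict
    )

    def added(self, factor: str) -> list[tuple[str, float]]:
        return self.per_factor[factor]["added"]

    def removed(self, factor: str) -> list[tuple[str, float]]:
        return self.per_factor[factor]["removed"]


def factor_relevance(fitted: FittedModel) -> RelevanceReport:
    """Rank factors by the posterior mean of the ARD variance 1/alpha_k.

    1/alpha_k is the expected variance a factor explains on the genes it
    regulates; deactivated factors have alpha_k driven large and relevance
    near zero. The inverse-Gamma mean rate/(shape-1) is used; when
    shape <= 1 the fallback rate/shape applies, with a warning. Covariate
    factors have no learned alpha — their reported relevance is the mean
    expected squared weight over genes (the same quantity 1/alpha_k
    estimates for regulated genes) — and are flagged by kind. Ties break by
    assembly order.
    """
    state = fitted.state
    refinement = refine_gene_sets(fitted)
    relevances = np.empty(state.n_factors)
    for k, f in enumerate(state.spec):
        if f.kind == "covariate":
            ew2 = state.gamma[:, k] * (
                state.W_mean1[:, k] ** 2 + state.W_var1[:, k]
            )
            relevances[k] = float(ew2.mean())
        else:
            shape, rate = state.alpha_shape[k], state.alpha_rate[k]
            if shape > 1:
                relevances[k] = rate / (shape - 1.0)
            else:
                warnings.warn(
                    f"alpha posterior shape <= 1 for factor {f.name!r}; "
                    "using rate/shape for the relevance"
                )
                relevances[k] = rate / shape
    order = np.argsort(-relevances, kind="stable")
    ranks = np.empty(state.n_factors, dtype=int)
    ranks[order] = np.arange(1, state.n_factors + 1)

    report = RelevanceReport()
    for k in order:
        f = state.spec[k]
        if f.kind == "annotated":
            n_annot = int(
                state.annotation.incidence[:, f.annotation_column].sum()
            )
            n_gained = len(refinement.per_factor[f.name]["added"])
            n_lost = len(refinement.per_factor[f.name]["removed"])
        else:
            n_annot = n_gained = n_lost = 0
        report.factors.append(
            FactorRelevance(
                name=f.name, kind=f.kind, relevance=float(relevances[k]),
                n_annotated=n_annot, n_gained=n_gained, n_lost=n_lost,
                rank=int(ranks[k]),
            )
        )
    return report


def refine_gene_sets(
    fitted: FittedModel, threshold: float = 0.5
) -> RefinementResult:
    """Data-driven gene-set augmentation from the indicator posterior.

    A gene is added to a factor's set iff it was not annotated and
    gamma > threshold; removed iff annotated and gamma < threshold
    (strict inequalities: gamma exactly at the threshold changes nothing).
    """
    state = fitted.state
    annotated = state.annotated_indices()
    if not annotated:
        raise ValueError("model has no annotated factors to refine")
    result = RefinementResult()
    genes = state.gene_ids
    for k in annotated:
        f = state.spec[k]
        I = state.annotation.incidence[:, f.annotation_column] == 1
        gk = state.gamma[:, k]
        added_idx = np.where(~I & (gk > threshold))[0]
        removed_idx = np.where(I & (gk < threshold))[0]
        result.per_factor[f.name] = {
            "added": [(str(genes[i]), float(gk[i])) for i in added_idx],
            "removed": [(str(genes[i]), float(gk[i])) for i in removed_idx],
        }
    return result


def residual_expression(
    fitted: FittedModel, Y: ExpressionMatrix, remove: list[str]
) -> ExpressionMatrix:
    """Expression with selected factors' reconstructed contributions removed.

    Gaussian: residual = Y - sum_{k in remove} E[x_k] E[w_k]^T (gene means
    are untouched, so the matrix stays on the input scale). Hurdle: zeros
    are first imputed by the posterior-mean latent value E[f], nonzeros
    mapped to log(y+1), then the removed contributions are subtracted.
    Poisson: residuals are formed on the latent log(1+exp)-link scale E[f].
    """
    state = fitted.state
    idx = [state.factor_index(name) for name in remove]
    contribution = np.zeros((state.n_cells, state.n_genes))
    W_mean = state.expected_weights()
    for k in idx:
        contribution += np.outer(state.X_mean[:, k], W_mean[:, k])

    if state.noise == "gaussian":
        base = Y.values.copy()
    elif state.noise == "hurdle":
        base = np.log1p(Y.values)
        zero = Y.values == 0
        F = state.expected_latent()
        base[zero] = F[zero]
    else:
        base = state.expected_latent()
    return ExpressionMatrix(
        base - contribution, Y.cell_ids, Y.gene_ids, "log_counts"
    )


def export_factor_states(fitted: FittedModel, factors: list[str]) -> pd.DataFrame:
    """Posterior mean and sd of the chosen factors, one row per cell.

    Suitable for bivariate plots or as input to an external embedding.
    Covariate factors come back as their fixed input values with sd 0.
    """
    if not factors:
        raise ValueError("no factors requested")
    state = fitted.state
    data = {}
    for name in factors:
        k = state.factor_index(name)
        data[f"{name}_mean"] = state.X_mean[:, k]
        data[f"{name}_sd"] = np.sqrt(state.X_var[:, k])
    return pd.DataFrame(data, index=state.cell_ids)


def diagnose_sparse_need(
    fitted: FittedModel, churn_threshold: float = 1.0
) -> tuple[bool, pd.DataFrame]:
    """Decide whether sparse unannotated factors should be added.

    On a standard model (no sparse factors), excessive annotation churn —
    gains plus losses at the 0.5 posterior threshold amounting to at least
    100% of an annotated set — signals structure the annotation cannot
    express; the recommendation is then to refit with five sparse factors.
    The threshold is inclusive.
    """
    state = fitted.state
    if any(f.kind == "sparse_unannotated" for f in state.spec):
        raise ValueError(
            "the churn diagnostic applies to the standard model "
            "(fitted without sparse unannotated factors)"
        )
    rows = []
    fire = False
    for k in state.annotated_indices():
        f = state.spec[k]
        I = state.annotation.incidence[:, f.annotation_column] == 1
        gk = state.gamma[:, k]
        gained = int(np.sum(~I & (gk > 0.5)))
        lost = int(np.sum(I & (gk < 0.5)))
        n_annot = max(int(I.sum()), 1)
        churn = (gained + lost) / n_annot
        fire = fire or churn >= churn_threshold
        rows.append((f.name, n_annot, gained, lost, churn))
    table = pd.DataFrame(
        rows, columns=["factor", "n_annotated", "n_gained", "n_lost", "churn"]
    )
    return fire, table
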