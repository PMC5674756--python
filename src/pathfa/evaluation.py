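"""Scoring driver recovery and annotation augmentation against ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .gene_sets import AnnotationMatrix


@dataclass
class RecoveryResult:
    """ROC of recovering the simulated driver pathways from factor scores."""

    roc_points: list[tuple[float, float]]
    auc: float
    ranking: list[str]


@dataclass
class AugmentationResult:
    """AUCs for re-including deleted genes and expelling inserted ones."""

    auc_added: float
    auc_removed: float
    per_factor_added: dict[str, float] = field(default_factory=dict)
    per_factor_removed: dict[str, float] = field(default_factory=dict)


def driver_recovery(relevances, active_mask) -> RecoveryResult:
    """ROC/AUC over the relevance ranking of factors.

    ``relevances`` is either a name -> score mapping or a score array
    aligned with ``active_mask`` (True = simulated driver). Ties contribute
    averaged steps (mid-rank convention), so the AUC equals the
    Mann-Whitney statistic.
    """
    if isinstance(relevances, dict):
        names = list(relevances.keys())
        scores = np.array([relevances[n] for n in names], dtype=float)
    else:
        scores = np.asarray(relevances, dtype=float)
        names = [f"factor_{i}" for i in range(len(scores))]
    labels = np.asarray(active_mask, dtype=bool)
    if labels.shape != scores.shape:
        raise ValueError("relevances and active_mask lengths differ")
    if labels.all() or not labels.any():
        raise ValueError("need at least one active and one inactive factor")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    order = np.argsort(-scores, kind="stable")
    return RecoveryResult(
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        ranking=[names[i] for i in order],
    )


def augmentation_recovery(
    gamma: np.ndarray,
    corrupted_annotation: AnnotationMatrix,
    true_annotation: AnnotationMatrix,
) -> AugmentationResult:
    """Score annotation repair, false negatives and false positives apart.

    ``gamma`` is the G x A posterior indicator matrix for the annotated
    factors, column-aligned with both annotation matrices (the model was
    fitted on the corrupted annotation). Among genes *absent* from a
    corrupted set, genes truly in the set (deleted during corruption) should
    rank high by gamma (auc_added); among genes *present*, inserted genes
    should rank high by 1 - gamma (auc_removed). Factors whose corrupted
    and true columns agree contribute no positives and are skipped; results
    are pooled across the remaining factors, with per-factor AUCs also
    reported where both classes exist.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != corrupted_annotation.incidence.shape:
        raise ValueError("gamma shape does not match the annotation matrices")
    if corrupted_annotation.incidence.shape != true_annotation.incidence.shape:
        raise ValueError("corrupted and true annotations differ in shape")
    corr = corrupted_annotation.incidence.astype(bool)
    true = true_annotation.incidence.astype(bool)
    touched = np.where((corr != true).any(axis=0))[0]
    if touched.size == 0:
        raise ValueError("annotations are identical; nothing was corrupted")

    add_scores, add_labels = [], []
    rem_scores, rem_labels = [], []
    res = AugmentationResult(auc_added=np.nan, auc_removed=np.nan)
    for k in touched:
        name = str(corrupted_annotation.set_names[k])
        absent = ~corr[:, k]
        s_a, l_a = gamma[absent, k], true[absent, k]
        add_scores.append(s_a)
        add_labels.append(l_a)
        if l_a.any() and not l_a.all():
            res.per_factor_added[name] = float(roc_auc_score(l_a, s_a))
        present = corr[:, k]
        s_r, l_r = 1.0 - gamma[present, k], ~true[present, k]
        rem_scores.append(s_r)
        rem_labels.append(l_r)
        if l_r.any() and not l_r.all():
            res.per_factor_removed[name] = float(roc_auc_score(l_r, s_r))

    add_labels_all = np.concatenate(add_labels)
    rem_labels_all = np.concatenate(rem_labels)
    if add_labels_all.any():
        res.auc_added = float(
            roc_auc_score(add_labels_all, np.concatenate(add_scores))
        )
    if rem_labels_all.any():
        res.auc_removed = float(
            roc_auc_score(rem_labels_all, np.concatenate(rem_scores))
        )
    return res
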