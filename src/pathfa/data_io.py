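"""Expression matrix I/O, normalization, variable-gene filtering, result export.

Internal orientation is always cells x genes (rows = cells). Dense matrices
travel as TSV/CSV with a header row of gene ids and a first column of cell
ids; sparse matrices as Matrix Market triplets with ``genes.tsv`` /
``barcodes.tsv`` sidecars, the layout 10x-style tools emit.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with value-scale semantics.

    ``scale`` is ``"raw_counts"`` (non-negative integers; required by the
    Poisson noise model and by size-factor normalization) or ``"log_counts"``
    (finite log-transformed values; Gaussian/Hurdle models).
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    scale: str = "log_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError(
                f"label lengths ({len(self.cell_ids)} cells, {len(self.gene_ids)} "
                f"genes) do not match matrix shape {n}x{g}"
            )
        if self.scale not in ("raw_counts", "log_counts"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        if self.scale == "raw_counts":
            if np.any(self.values < 0):
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("raw counts must be integers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class CovariateTable:
    """Known per-cell covariates (e.g. batch, detected-gene count)."""

    values: np.ndarray
    names: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.names = np.asarray(self.names, dtype=object)
        if self.values.shape[1] != len(self.names):
            raise ValueError("covariate count does not match name count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariates contain non-finite entries")


def read_expression(
    path,
    format: str = "tsv",
    orientation: str = "cells_by_genes",
    scale: str = "log_counts",
) -> ExpressionMatrix:
    """Read a dense TSV/CSV or a Matrix Market triplet into cells x genes form.

    For ``format="mtx"``, ``genes.tsv`` and ``barcodes.tsv`` must sit next to
    the matrix file; the on-disk matrix is genes x cells unless
    ``orientation`` says otherwise (the common 10x convention).
    """
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except ValueError as exc:
            raise ValueError(f"{path}: parse error: {exc}") from exc
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ValueError(f"{path}: non-numeric values in columns {bad}")
        if orientation == "genes_by_cells":
            df = df.T
        return ExpressionMatrix(
            df.to_numpy(float), df.index.to_numpy(), df.columns.to_numpy(), scale
        )
    elif format == "mtx":
        d = os.path.dirname(os.path.abspath(path))
        genes_path = os.path.join(d, "genes.tsv")
        cells_path = os.path.join(d, "barcodes.tsv")
        for p in (genes_path, cells_path):
            if not os.path.exists(p):
                raise FileNotFoundError(f"MTX sidecar file missing: {p}")
        mat = scipy.sparse.csr_matrix(scipy.io.mmread(path)).toarray()
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy()
        cells = pd.read_csv(cells_path, sep="\t", header=None)[0].to_numpy()
        if orientation == "genes_by_cells":
            mat = mat.T
        n, g = mat.shape
        if len(cells) != n or len(genes) != g:
            raise ValueError(
                f"{path}: matrix is {n} cells x {g} genes but sidecars list "
                f"{len(cells)} barcodes and {len(genes)} genes"
            )
        return ExpressionMatrix(mat, cells, genes, scale)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_expression(Y: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write a matrix as dense TSV/CSV or MTX triplet with sidecars."""
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        Y.to_frame().to_csv(path, sep=sep, index_label="cell")
    elif format == "mtx":
        d = os.path.dirname(os.path.abspath(path))
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(Y.values))
        pd.Series(Y.gene_ids).to_csv(
            os.path.join(d, "genes.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(Y.cell_ids).to_csv(
            os.path.join(d, "barcodes.tsv"), sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def size_factor_normalize(Y: ExpressionMatrix) -> ExpressionMatrix:
    """Median-ratio size-factor normalization followed by log(x+1).

    The size factor of a cell is the median, over genes expressed in every
    cell, of the ratio of its count to the per-gene geometric mean; counts
    are divided by it before the log transform. Two cells with proportional
    counts therefore map onto the same normalized profile.
    """
    if Y.scale != "raw_counts":
        raise ValueError("size_factor_normalize expects raw counts")
    counts = Y.values
    zero_cells = np.where(counts.sum(axis=1) == 0)[0]
    if zero_cells.size:
        ids = list(Y.cell_ids[zero_cells])
        raise ValueError(f"cells with all-zero counts: {ids}")
    expressed_everywhere = np.all(counts > 0, axis=0)
    if not expressed_everywhere.any():
        raise ValueError(
            "no gene is expressed in every cell; cannot form geometric means"
        )
    ref = counts[:, expressed_everywhere]
    log_geo_mean = np.mean(np.log(ref), axis=0)
    size_factors = np.exp(np.median(np.log(ref) - log_geo_mean, axis=1))
    normalized = np.log1p(counts / size_factors[:, None])
    return ExpressionMatrix(normalized, Y.cell_ids, Y.gene_ids, "log_counts")


def filter_variable_genes(
    Y: ExpressionMatrix,
    n_keep: int,
    spike_in_pattern: str | None = None,
    window: int = 51,
) -> ExpressionMatrix:
    """Keep the ``n_keep`` genes most variable relative to a mean-CV^2 trend.

    A rolling median of log CV^2 against log mean (``window`` genes wide) is
    the null trend; genes are ranked by their residual above it and the top
    ``n_keep`` kept, in their original order. With ``spike_in_pattern`` the
    trend is fit on spike-in genes only (technical-noise baseline) but
    residuals are still scored for all genes.
    """
    if n_keep > Y.n_genes:
        raise ValueError(f"n_keep={n_keep} exceeds gene count {Y.n_genes}")
    vals = Y.values
    mean = vals.mean(axis=0)
    var = vals.var(axis=0)
    if np.all(var == 0):
        raise ValueError("matrix is constant; no variable genes to select")
    if n_keep == Y.n_genes:
        return Y
    eps = 1e-12
    # CV^2 on a strictly positive pseudo-mean so log-scale is defined
    safe_mean = np.where(np.abs(mean) < eps, eps, np.abs(mean))
    log_cv2 = np.log(var + eps) - 2 * np.log(safe_mean)
    log_mean = np.log(safe_mean)

    if spike_in_pattern is not None:
        import re

        fit_mask = np.array(
            [bool(re.search(spike_in_pattern, str(g))) for g in Y.gene_ids]
        )
        if not fit_mask.any():
            raise ValueError(f"no gene matches spike-in pattern {spike_in_pattern!r}")
    else:
        fit_mask = np.ones(Y.n_genes, dtype=bool)

    order = np.argsort(log_mean[fit_mask])
    xs = log_mean[fit_mask][order]
    ys = log_cv2[fit_mask][order]
    half = max(1, min(window, len(xs)) // 2)
    trend = np.array(
        [np.median(ys[max(0, i - half) : i + half + 1]) for i in range(len(xs))]
    )
    trend_at = np.interp(log_mean, xs, trend)
    residual = log_cv2 - trend_at
    keep_idx = np.sort(np.argsort(-residual, kind="stable")[:n_keep])
    return ExpressionMatrix(
        vals[:, keep_idx], Y.cell_ids, Y.gene_ids[keep_idx], Y.scale
    )


def read_covariates(path) -> CovariateTable:
    """Read a numeric covariate table (TSV, first column = cell ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CovariateTable(df.to_numpy(float), df.columns.to_numpy())


def write_results(fitted, out_dir) -> dict[str, str]:
    """Write the standard result tables of a fitted model.

    Emits ``relevance.tsv``, ``factor_states.tsv``, ``weights.tsv``,
    ``refinement.tsv`` and ``run_log.json`` under ``out_dir`` and returns a
    name -> path mapping.
    """
    from .downstream import factor_relevance, refine_gene_sets

    os.makedirs(out_dir, exist_ok=True)
    state = fitted.state
    paths = {}

    report = factor_relevance(fitted)
    rel_df = pd.DataFrame(
        {
            "factor": [r.name for r in report.factors],
            "type": [r.kind for r in report.factors],
            "relevance": [r.relevance for r in report.factors],
            "n_annotated": [r.n_annotated for r in report.factors],
            "n_gained": [r.n_gained for r in report.factors],
            "n_lost": [r.n_lost for r in report.factors],
            "rank": [r.rank for r in report.factors],
        }
    )
    paths["relevance"] = os.path.join(out_dir, "relevance.tsv")
    rel_df.to_csv(paths["relevance"], sep="\t", index=False)

    names = [f.name for f in state.spec]
    xs_df = pd.DataFrame(state.X_mean, index=state.cell_ids, columns=names)
    paths["factor_states"] = os.path.join(out_dir, "factor_states.tsv")
    xs_df.to_csv(paths["factor_states"], sep="\t", index_label="cell")

    w_df = pd.DataFrame(
        state.expected_weights(), index=state.annotation.gene_ids, columns=names
    )
    paths["weights"] = os.path.join(out_dir, "weights.tsv")
    w_df.to_csv(paths["weights"], sep="\t", index_label="gene")

    refinement = refine_gene_sets(fitted)
    rows = []
    for fname, res in refinement.per_factor.items():
        for gene, post in res["added"]:
            rows.append((fname, gene, "added", post))
        for gene, post in res["removed"]:
            rows.append((fname, gene, "removed", post))
    ref_df = pd.DataFrame(rows, columns=["factor", "gene", "action", "posterior"])
    paths["refinement"] = os.path.join(out_dir, "refinement.tsv")
    ref_df.to_csv(paths["refinement"], sep="\t", index=False)

    import platform
    import sys

    log = {
        "config": fitted.config_dict(),
        "converged": bool(fitted.converged),
        "n_iter": int(fitted.n_iter),
        "elbo_trace": [float(v) for v in state.elbo_trace],
        "final_elbo": float(state.elbo_trace[-1]) if state.elbo_trace else None,
        "churn_flags": {k: bool(v) for k, v in fitted.churn_flags.items()},
        "environment": {
            "python": sys.version.split()[0],
            "platform": platform.platform(),
        },
    }
    paths["run_log"] = os.path.join(out_dir, "run_log.json")
    with open(paths["run_log"], "w") as fh:
        json.dump(log, fh, indent=2)
    return paths
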