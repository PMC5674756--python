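"""Gene-set annotations: GMT parsing, filtering, and factor prescreening.

Gene sets (pathways) inform the sparsity prior of annotated factors: the
binary incidence matrix built here says which genes a pathway factor is
allowed, a priori, to load on. Collections in the tens-to-hundreds of sets
(MSigDB hallmark, filtered REACTOME) are the intended scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets.

    Attributes
    ----------
    sets : list of (str, set of str)
        ``(set_name, genes)`` pairs in file order. Names are unique and
        every set is non-empty.
    source : str
        Free-text provenance (e.g. the GMT path).
    """

    sets: list[tuple[str, set[str]]] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        names = [name for name, _ in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene-set names: {dup}")
        for name, genes in self.sets:
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"gene set {name!r} contains an empty gene id")

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.sets]


@dataclass
class AnnotationMatrix:
    """Binary gene x set incidence matrix aligned to an expression matrix.

    ``incidence[g, k] == 1`` iff gene ``g`` belongs to set ``k``.
    """

    incidence: np.ndarray
    gene_ids: np.ndarray
    set_names: np.ndarray

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.set_names = np.asarray(self.set_names, dtype=object)
        if self.incidence.ndim != 2:
            raise ValueError("incidence must be 2-D (genes x sets)")
        g, a = self.incidence.shape
        if len(self.gene_ids) != g or len(self.set_names) != a:
            raise ValueError(
                f"label lengths ({len(self.gene_ids)} genes, "
                f"{len(self.set_names)} sets) do not match incidence shape {g}x{a}"
            )
        vals = np.unique(self.incidence)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("incidence entries must be 0/1")
        self.incidence = self.incidence.astype(np.int8)

    @property
    def n_genes(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_sets(self) -> int:
        return self.incidence.shape[1]

    def set_sizes(self) -> np.ndarray:
        return self.incidence.sum(axis=0)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.incidence, index=self.gene_ids, columns=self.set_names)
        df.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "AnnotationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), df.index.to_numpy(), df.columns.to_numpy())


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (one set per line: name, description, genes...).

    Duplicate genes within a line are deduplicated; file order is kept.

    Raises
    ------
    ValueError
        On a line with fewer than 3 tab-separated fields (named by line
        number) or on duplicate set names.
    """
    sets: list[tuple[str, set[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            genes = {g for g in fields[2:] if g}
            sets.append((name, genes))
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection back to GMT (description column left blank)."""
    with open(path, "w") as fh:
        for name, genes in collection.sets:
            fh.write("\t".join([name, ""] + sorted(genes)) + "\n")


def build_annotation_matrix(
    collection: GeneSetCollection,
    gene_universe,
    min_genes: int = 15,
    max_genes: int = 1000,
) -> AnnotationMatrix:
    """Intersect sets with the expression gene universe and size-filter them.

    Each set is intersected with ``gene_universe`` (exact match after
    case-folding); sets whose intersection size falls outside
    ``[min_genes, max_genes]`` are dropped. Column order follows the
    surviving-set order of the collection; row order is ``gene_universe``
    order, so the incidence aligns with the expression matrix.
    """
    gene_universe = np.asarray(gene_universe, dtype=object)
    if len(gene_universe) == 0:
        raise ValueError("gene_universe is empty")
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    index = {str(g).casefold(): i for i, g in enumerate(gene_universe)}
    cols = []
    names = []
    for name, genes in collection.sets:
        rows = sorted({index[g.casefold()] for g in genes if g.casefold() in index})
        if min_genes <= len(rows) <= max_genes:
            col = np.zeros(len(gene_universe), dtype=np.int8)
            col[rows] = 1
            cols.append(col)
            names.append(name)
    if not cols:
        raise ValueError(
            "no gene set survived filtering; relax min_genes/max_genes "
            f"(currently [{min_genes}, {max_genes}]) or check gene identifiers"
        )
    incidence = np.stack(cols, axis=1)
    return AnnotationMatrix(incidence, gene_universe, np.asarray(names, dtype=object))


def prescreen_gene_sets(
    Y,
    annotation: AnnotationMatrix,
    keep: int,
    subsample_cells: int = 2000,
    seed: int = 0,
) -> AnnotationMatrix:
    """Retain the ``keep`` gene sets whose genes are most dominated by one axis
    of variation.

    Score per set: the proportion of variance of the standardized
    annotated-gene submatrix captured by its leading principal component,
    computed on a random subsample of at most ``subsample_cells`` cells.
    Cheap, and insensitive to gene-wise scaling of ``Y``. Sets come back in
    descending score order.
    """
    from .data_io import ExpressionMatrix

    if keep <= 0:
        raise ValueError("keep must be positive")
    if keep > annotation.n_sets:
        raise ValueError(
            f"keep={keep} exceeds the number of annotated sets ({annotation.n_sets})"
        )
    values = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    if values.shape[1] != annotation.n_genes:
        raise ValueError("expression matrix and annotation gene dimensions differ")
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    if subsample_cells < n:
        rows = np.sort(rng.choice(n, size=subsample_cells, replace=False))
        values = values[rows]

    scores = np.empty(annotation.n_sets)
    for k in range(annotation.n_sets):
        sub = values[:, annotation.incidence[:, k] == 1]
        sub = sub - sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        sub = sub / sd
        sv = np.linalg.svd(sub, compute_uv=False)
        total = np.sum(sv**2)
        scores[k] = (sv[0] ** 2 / total) if total > 0 else 0.0

    order = np.argsort(-scores, kind="stable")[:keep]
    return AnnotationMatrix(
        annotation.incidence[:, order],
        annotation.gene_ids,
        annotation.set_names[order],
    )
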