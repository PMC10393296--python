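"""Single-cell expression screens: cell-class enrichment of candidate TFs and
TF-gene correlation profiles.

Counts are normalized per cell to counts-per-10k (no log) before any mean, fold
or correlation is computed, so library depth cannot masquerade as biology.  The
enrichment screen compares a gene's normalized expression in a target cell class
against all other cells: the fold ratio of class means is paired with a
two-sample Wilcoxon rank-sum test on the per-cell values, and Benjamini-Hochberg
control is applied over the candidate list.  A hit must clear both the fold
threshold (default 5) and the FDR (default 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats

from ._utils import bh_adjust

UNDEFINED_R = np.nan


@dataclass
class CellByGeneMatrix:
    """Cells x genes count matrix with one class label per cell.

    ``counts`` may be dense or scipy sparse; it is kept as given and only
    row-normalized lazily.
    """

    counts: object                  # (n_cells, n_genes), non-negative
    cell_ids: list[str]
    gene_ids: list[str]
    cell_class: list[str]

    def __post_init__(self):
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError("dimension mismatch between counts and id lists")
        if len(self.cell_class) != n_cells:
            raise ValueError("one class label per cell required")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def classes(self) -> list[str]:
        seen = []
        for c in self.cell_class:
            if c not in seen:
                seen.append(c)
        return seen

    def class_mask(self, label: str) -> np.ndarray:
        return np.asarray([c == label for c in self.cell_class])

    def gene_column(self, gene: str, normalized: bool = True) -> np.ndarray:
        """Per-cell values for one gene, CP10K-normalized by default."""
        if gene not in self._gene_index:
            raise KeyError(f"gene {gene!r} not in matrix")
        j = self._gene_index[gene]
        col = self.counts[:, j]
        col = np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col, float).ravel()
        if not normalized:
            return col
        return col * self._scale_factors()

    def _scale_factors(self) -> np.ndarray:
        if not hasattr(self, "_sf"):
            totals = np.asarray(self.counts.sum(axis=1)).ravel().astype(float)
            totals[totals == 0] = 1.0
            self._sf = 1e4 / totals
        return self._sf


@dataclass(frozen=True)
class ScreenHit:
    gene_id: str
    fold_enrichment: float
    target_mean: float
    other_mean: float
    p_value: float
    q_value: float
    passes: bool


@dataclass
class CorrelationProfile:
    tf: str
    r_values: dict[str, float]                 # gene -> Pearson R (NaN if undefined)
    set_summaries: pd.DataFrame                # per gene set: n, median, q1, q3


def enrichment_screen(
    matrix: CellByGeneMatrix,
    target_class: str,
    candidate_genes,
    min_fold: float = 5.0,
    fdr: float = 0.001,
    epsilon: float = 1e-3,
    other_mode: str = "pooled",
    fold_only: bool = False,
) -> list[ScreenHit]:
    """Screen candidate genes for enrichment in a target cell class.

    ``other_mode`` is ``"pooled"`` (fold vs the mean over all non-target cells)
    or ``"max"`` (fold vs the maximum per-class mean among the other classes —
    a stricter specificity screen).  ``fold_only`` skips the rank-sum test and
    gates hits on the fold threshold alone.
    """
    candidate_genes = list(candidate_genes)
    target = matrix.class_mask(target_class)
    if not target.any():
        raise ValueError(f"target class {target_class!r} has no cells")
    if other_mode not in ("pooled", "max"):
        raise ValueError("other_mode must be 'pooled' or 'max'")
    other_classes = [c for c in matrix.classes() if c != target_class]

    folds, pvals, t_means, o_means = [], [], [], []
    for gene in candidate_genes:
        vals = matrix.gene_column(gene)
        t_vals, o_vals = vals[target], vals[~target]
        t_mean = float(t_vals.mean())
        if other_mode == "pooled":
            o_mean = float(o_vals.mean()) if o_vals.size else 0.0
        else:
            o_mean = max(
                (float(vals[matrix.class_mask(c)].mean()) for c in other_classes),
                default=0.0,
            )
        fold = t_mean / max(o_mean, epsilon)
        if fold_only:
            p = np.nan
        elif t_vals.size and o_vals.size and (np.ptp(vals) > 0):
            p = float(stats.mannwhitneyu(t_vals, o_vals, alternative="greater").pvalue)
        else:
            p = 1.0
        folds.append(fold)
        pvals.append(p)
        t_means.append(t_mean)
        o_means.append(o_mean)

    if fold_only:
        qvals = [np.nan] * len(candidate_genes)
        passes = [f >= min_fold for f in folds]
    else:
        qvals = bh_adjust(pvals)
        passes = [(f >= min_fold) and (q <= fdr) for f, q in zip(folds, qvals)]
    hits = [
        ScreenHit(g, float(f), tm, om, float(p), float(q), bool(ok))
        for g, f, tm, om, p, q, ok in zip(
            candidate_genes, folds, t_means, o_means, pvals, qvals, passes
        )
    ]
    hits.sort(key=lambda h: (-h.passes, h.q_value if np.isfinite(h.q_value) else 1.0,
                             -h.fold_enrichment))
    return hits


def class_detection_profile(
    matrix: CellByGeneMatrix,
    gene: str,
    classes=None,
    min_detected_fraction: float = 0.05,
) -> dict[str, bool]:
    """Per-class detection flags: a gene is detected in a class when it is
    nonzero in at least ``min_detected_fraction`` of the class's cells."""
    if classes is None:
        classes = matrix.classes()
    raw = matrix.gene_column(gene, normalized=False)
    out = {}
    for cls in classes:
        mask = matrix.class_mask(cls)
        if not mask.any():
            raise ValueError(f"class {cls!r} has no cells")
        out[cls] = bool((raw[mask] > 0).mean() >= min_detected_fraction)
    return out


def expression_correlation(
    matrix: CellByGeneMatrix,
    tf: str,
    gene_sets: dict[str, list] | None = None,
    cell_subset: str | None = None,
    genes=None,
) -> CorrelationProfile:
    """Pearson correlation of every gene with a TF across a cell subset.

    ``cell_subset`` restricts to one cell class (e.g. the ciliated cells);
    ``gene_sets`` names gene groups (core ciliome, subtype, panneuronal,
    ubiquitous...) for which distribution summaries are reported.  Genes whose
    vector is constant over the subset get NaN.
    """
    mask = matrix.class_mask(cell_subset) if cell_subset else np.ones(matrix.n_cells, bool)
    if mask.sum() < 3:
        raise ValueError("cell subset smaller than 3 cells")
    tf_vals = matrix.gene_column(tf)[mask]
    if genes is None:
        genes = list(matrix.gene_ids)
    tf_const = np.ptp(tf_vals) == 0

    r_values = {}
    for gene in genes:
        vals = matrix.gene_column(gene)[mask]
        if tf_const or np.ptp(vals) == 0:
            r_values[gene] = UNDEFINED_R
            continue
        r_values[gene] = float(stats.pearsonr(tf_vals, vals).statistic)

    rows = []
    for name, ids in (gene_sets or {}).items():
        rs = np.array([r_values[g] for g in ids if g in r_values], dtype=float)
        rs = rs[np.isfinite(rs)]
        if rs.size:
            q1, med, q3 = np.percentile(rs, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append({"gene_set": name, "n": rs.size, "median_r": med, "q1": q1, "q3": q3})
    return CorrelationProfile(tf=tf, r_values=r_values, set_summaries=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_matrix_tsv(counts_path, classes_path) -> CellByGeneMatrix:
    """Dense TSV (cells x genes, first column = cell id) plus a two-column
    cell-class TSV (cell_id, cell_class)."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    labels = pd.read_csv(classes_path, sep="\t", index_col=0).iloc[:, 0]
    labels = labels.reindex(df.index)
    if labels.isna().any():
        raise ValueError("cells without a class label")
    return CellByGeneMatrix(
        counts=df.to_numpy(),
        cell_ids=list(df.index),
        gene_ids=list(df.columns),
        cell_class=list(labels),
    )


def write_matrix_mtx(matrix: CellByGeneMatrix, prefix) -> None:
    """Write MTX triplet plus row (cells), column (genes) and class files."""
    from scipy.io import mmwrite

    counts = matrix.counts
    if not sparse.issparse(counts):
        counts = sparse.csr_matrix(counts)
    mmwrite(f"{prefix}.mtx", counts)
    with open(f"{prefix}.cells.tsv", "w") as fh:
        fh.write("cell_id\tcell_class\n")
        for cid, cls in zip(matrix.cell_ids, matrix.cell_class):
            fh.write(f"{cid}\t{cls}\n")
    with open(f"{prefix}.genes.tsv", "w") as fh:
        fh.write("gene_id\n")
        for g in matrix.gene_ids:
            fh.write(f"{g}\n")


def read_matrix_mtx(prefix) -> CellByGeneMatrix:
    from scipy.io import mmread

    counts = sparse.csr_matrix(mmread(f"{prefix}.mtx"))
    cells = pd.read_csv(f"{prefix}.cells.tsv", sep="\t")
    genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t")
    return CellByGeneMatrix(
        counts=counts,
        cell_ids=list(cells["cell_id"]),
        gene_ids=list(genes["gene_id"]),
        cell_class=list(cells["cell_class"]),
    )
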