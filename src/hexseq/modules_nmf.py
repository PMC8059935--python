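"""Gene-module discovery by non-negative matrix factorization (NMF).

A genes x cells matrix of variance-stabilized, non-negative expression is
factored as ``X ~ W S H`` with rank-20 basis ``W`` (genes x modules), usage
``H`` (modules x cells), and an optional nonsmooth-NMF smoothing matrix
``S = (1 - s) I + (s / q) 11'``.  Solved by seeded multiplicative updates on
the Frobenius objective, whose trace is non-increasing.

Downstream, genes are ranked per module by basis coefficient; a module's
"top contributing" genes are the longest leading run of its ranking in which
every gene loads strictly higher on this module than on any other.  Modules
found in two tissues are matched by top-200 gene overlap (pairs under 25%
overlap dropped), and module expression is projected to wells with a
cells-per-well-weighted high/low binarization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModuleSet",
    "ModuleMatch",
    "prepare_expression",
    "factorize",
    "top_contributing_genes",
    "match_modules",
    "celltype_fractions",
    "project_module",
]

DEFAULT_RANK = 20
DEFAULT_TOP_N = 200
DEFAULT_MIN_FRAC = 0.25


@dataclass
class GeneModuleSet:
    """NMF basis with per-module gene rankings and top-gene selections."""

    basis: pd.DataFrame            # genes x modules, non-negative
    usage: np.ndarray              # modules x cells
    objective_trace: np.ndarray
    tissue_tag: str = ""
    sorted_genes: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sorted_genes:
            order = np.argsort(-self.basis.to_numpy(), axis=0, kind="stable")
            self.sorted_genes = [
                list(self.basis.index[order[:, m]])
                for m in range(self.basis.shape[1])
            ]

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    def top_genes(self, m: int) -> list[str]:
        return top_contributing_genes(self, m)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in range(self.rank):
            top = set(self.top_genes(m))
            for rank_pos, g in enumerate(self.sorted_genes[m]):
                rows.append((g, m, float(self.basis.loc[g].iloc[m]),
                             rank_pos, g in top))
        return pd.DataFrame(rows, columns=["gene", "module", "coefficient",
                                           "rank", "is_top"])


def prepare_expression(adata: ad.AnnData, min_cells: int = 5,
                       target_sum: float = 1e4) -> pd.DataFrame:
    """Variance-stabilized non-negative genes x cells matrix for NMF.

    Log-normalization (library size to ``target_sum``, log1p) followed by
    per-gene standardization with negative residuals clipped to zero — an
    approximation of regularized-NB Pearson residuals that preserves the
    non-negativity NMF needs.  Genes seen in fewer than ``min_cells`` cells
    are dropped.
    """
    X = sp.csr_matrix(adata.X).astype(float)
    detected = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = detected >= min_cells
    X = X[:, keep]
    totals = np.asarray(X.sum(axis=1)).ravel()
    sf = np.divide(target_sum, totals, out=np.ones_like(totals), where=totals > 0)
    logn = np.log1p(X.multiply(sf[:, None]).toarray())
    mu = logn.mean(axis=0)
    sd = logn.std(axis=0)
    sd[sd == 0] = 1.0
    resid = np.clip((logn - mu) / sd, 0.0, None)
    return pd.DataFrame(resid.T, index=adata.var_names[keep],
                        columns=adata.obs_names)


def factorize(expression: pd.DataFrame, rank: int = DEFAULT_RANK,
              seed: int = 0, max_iter: int = 400, tol: float = 1e-6,
              smoothing: float = 0.0, tissue_tag: str = "") -> GeneModuleSet:
    """Multiplicative-update NMF of a non-negative genes x cells matrix.

    Minimizes ``||X - W S H||_F`` with random non-negative initialization
    (deterministic given ``seed``); ``smoothing`` in [0, 1) interposes the
    nonsmooth-NMF matrix ``S`` (0 = plain NMF).  Stops when the relative
    objective change falls below ``tol``.
    """
    X = np.asarray(expression, dtype=float)
    if (X < 0).any():
        raise ValueError("expression matrix must be non-negative")
    if not 0 <= smoothing < 1:
        raise ValueError("smoothing must be in [0, 1)")
    n_genes, n_cells = X.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / max(rank, 1)) or 1.0
    W = rng.uniform(0.0, 1.0, size=(n_genes, rank)) * scale
    H = rng.uniform(0.0, 1.0, size=(rank, n_cells)) * scale
    S = ((1.0 - smoothing) * np.eye(rank)
         + smoothing / rank * np.ones((rank, rank)))
    eps = 1e-12

    trace = []
    prev = np.inf
    for _ in range(max_iter):
        Hs = S @ H
        W *= (X @ Hs.T) / np.maximum(W @ (Hs @ Hs.T), eps)
        Ws = W @ S
        H *= (Ws.T @ X) / np.maximum((Ws.T @ Ws) @ H, eps)
        obj = float(np.linalg.norm(X - W @ S @ H, "fro"))
        trace.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(prev, 1.0):
            break
        prev = obj

    basis = pd.DataFrame(W @ S if smoothing else W, index=expression.index,
                         columns=[f"M{m}" for m in range(rank)])
    return GeneModuleSet(basis=basis, usage=H, objective_trace=np.asarray(trace),
                         tissue_tag=tissue_tag)


def top_contributing_genes(modules: GeneModuleSet, m: int) -> list[str]:
    """Longest leading run of module ``m``'s ranking that dominates everywhere.

    Walk the module's descending-coefficient gene list and keep genes while
    each one's coefficient in ``m`` is strictly greater than its coefficient
    in every other module; stop at the first violation.  May be empty.
    """
    B = modules.basis.to_numpy()
    col = {g: i for i, g in enumerate(modules.basis.index)}
    out: list[str] = []
    for g in modules.sorted_genes[m]:
        row = B[col[g]]
        others = np.delete(row, m)
        if others.size and not (row[m] > others.max()):
            break
        out.append(g)
    return out


@dataclass(frozen=True)
class ModuleMatch:
    """A matched module pair with its top-gene overlap."""

    module_a: int
    module_b: int
    overlap_count: int
    top_n: int
    tie: bool = False

    @property
    def overlap_fraction(self) -> float:
        return self.overlap_count / self.top_n


def match_modules(set_a: GeneModuleSet, set_b: GeneModuleSet,
                  top_n: int = DEFAULT_TOP_N,
                  min_frac: float = DEFAULT_MIN_FRAC) -> list[ModuleMatch]:
    """Match each module of A to the B module sharing most top-``top_n`` genes.

    Matches with overlap fraction below ``min_frac`` are dropped (the 25%
    boundary itself is retained).  Ties go to the smaller B index and are
    reported on the match.
    """
    def tops(s: GeneModuleSet, m: int) -> set[str]:
        ranked = s.sorted_genes[m]
        if len(ranked) < top_n:
            logger.warning("module %s/%d has only %d ranked genes (< top_n=%d)",
                           s.tissue_tag, m, len(ranked), top_n)
        return set(ranked[:top_n])

    tops_b = [tops(set_b, m) for m in range(set_b.rank)]
    out = []
    for ma in range(set_a.rank):
        ta = tops(set_a, ma)
        overlaps = np.array([len(ta & tb) for tb in tops_b])
        best = int(overlaps.argmax())
        tie = int((overlaps == overlaps[best]).sum()) > 1
        match = ModuleMatch(ma, best, int(overlaps[best]), top_n, tie=tie)
        if match.overlap_fraction >= min_frac:
            out.append(match)
    return out


def celltype_fractions(expression: pd.DataFrame, cell_type_labels,
                       genes) -> pd.Series:
    """Cell-type composition of a module's (overlapping) gene set.

    For each cell type: average each gene over the type's cells, take the
    median across the genes, then normalize the per-type medians to sum to 1.
    """
    genes = [g for g in genes if g in expression.index]
    if not genes:
        raise ValueError("none of the genes are present in the matrix")
    labels = pd.Series(np.asarray(cell_type_labels, dtype=object),
                       index=expression.columns)
    sub = expression.loc[genes]
    medians = {}
    for ct, cols in labels.groupby(labels).groups.items():
        medians[ct] = float(sub[list(cols)].mean(axis=1).median())
    out = pd.Series(medians, name="fraction").sort_index()
    total = out.sum()
    if total <= 0:
        logger.warning("all cell-type medians are zero; fractions undefined")
        return out * np.nan
    return out / total


def project_module(adata: ad.AnnData, module_genes,
                   layer: str | None = None,
                   well_key: str = "well_id") -> pd.DataFrame:
    """Project a module's expression to wells with high/low binarization.

    Per well: median over its cells of each gene's (log-normalized)
    expression, then mean over the module genes.  The global threshold is the
    cells-per-well-weighted average of the well statistics; wells strictly
    above it are 'high', other wells with nonzero module expression 'low',
    and zero-expression wells 'none'.
    """
    genes = [g for g in module_genes if g in adata.var_names]
    if not genes:
        raise ValueError("no module genes present in the matrix")
    M = adata[:, genes].layers[layer] if layer else adata[:, genes].X
    M = np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
    df = pd.DataFrame(M, index=adata.obs[well_key].values, columns=genes)
    per_well = df.groupby(level=0).median().mean(axis=1)
    n_cells = df.groupby(level=0).size()
    threshold = float(np.average(per_well, weights=n_cells))
    label = np.where(per_well > threshold, "high",
                     np.where(per_well > 0, "low", "none"))
    return pd.DataFrame({"mean_expr": per_well, "n_cells": n_cells,
                         "label": label}).rename_axis("well_id")
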