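"""Ambient-RNA decontamination by expectation-maximization.

Transcripts released by lysed cells are captured in other cells' libraries,
inflating cross-population (and cross-species) counts.  The generative model:
each transcript of cell ``c`` (in cluster ``k``) carries a Bernoulli hidden
state — with probability ``1 - theta_c`` it is drawn from the cluster's native
categorical expression distribution ``phi_k`` over genes, and with probability
``theta_c`` from a contamination distribution ``eta_k`` aggregated from the
other clusters.  ``theta_c``, the per-cell contamination proportion, carries a
Beta prior.

Fitting is plain EM with MAP updates for ``theta`` (point estimates rather
than a variational posterior).  ``eta_k`` is recomputed every M-step as the
native-count-weighted average of ``phi_j`` over clusters ``j != k``.  ``phi``
is initialized by subtracting ``theta_init`` times the pooled other-cluster
profile from each cluster's observed profile and clipping at zero: without
this the native/contamination split sits on a likelihood ridge (a cluster
profile can absorb any constant share of the contamination signature), and
the background-subtracted start point selects the maximal-contamination end
of the ridge, which is the planted truth whenever some cells are clean.

Decontaminated counts are the per-entry posterior expectation of the native
component, never exceeding the raw counts.
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
    "ContaminationModel",
    "flag_cross_species_outliers",
    "fit",
    "decontaminate",
    "contamination_summary",
]

_EPS = 1e-300


@dataclass
class ContaminationModel:
    """Fitted per-cluster native/contamination distributions and per-cell theta."""

    clusters: list
    genes: list
    phi: np.ndarray                  # clusters x genes, rows sum to 1
    eta: np.ndarray                  # clusters x genes, rows sum to 1
    theta: pd.Series                 # per-cell contamination proportion
    cluster_of: pd.Series            # per-cell cluster label
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    prior: tuple[float, float] = (1.0, 1.0)

    def theta_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell": self.theta.index,
                             "cluster": self.cluster_of.values,
                             "theta": self.theta.values})


def flag_cross_species_outliers(adata: ad.AnnData, human_cells=None,
                                log_threshold: float = 6.0) -> list[str]:
    """Mouse genes implausibly abundant in human cells (cross-species spill).

    Returns mouse gene ids whose natural-log total count in the human cell
    population exceeds ``log_threshold`` on the log(counts + 1) scale; these
    are removed ahead of decontamination because they would otherwise dominate
    the contamination signature.  Human genes are never flagged.
    """
    if human_cells is None:
        if "species_call" in adata.obs:
            human_mask = (adata.obs["species_call"] == "human").to_numpy()
        else:
            raise ValueError("provide human_cells or run species calling first")
    else:
        human_mask = adata.obs_names.isin(human_cells)
    if not human_mask.any():
        logger.warning("no human cells available; no outlier genes flagged")
        return []
    mouse_genes = (adata.var["species"] == "mouse").to_numpy()
    X = sp.csr_matrix(adata.X)
    totals = np.asarray(X[human_mask].sum(axis=0)).ravel()
    flagged = np.log(totals + 1.0) > log_threshold
    return list(adata.var_names[flagged & mouse_genes])


def _cluster_native_profiles(native: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize per-cluster native counts to (phi, eta).

    eta_k is the native-count-weighted average of phi_j over clusters j != k.
    """
    totals = native.sum(axis=1, keepdims=True)
    phi = np.divide(native, np.maximum(totals, _EPS))
    weighted = native.sum(axis=0, keepdims=True) - native  # leave-one-out sums
    eta = np.divide(weighted, np.maximum(weighted.sum(axis=1, keepdims=True), _EPS))
    return phi, eta


def fit(adata: ad.AnnData, cluster_labels, max_iter: int = 200,
        tol: float = 1e-4, seed: int | None = 0, theta_init: float = 0.3,
        prior: tuple[float, float] = (1.0, 1.0)) -> ContaminationModel:
    """Fit the contamination mixture by EM.

    Parameters
    ----------
    cluster_labels
        Per-cell population labels (>= 2 distinct values) from any upstream
        clustering; this module does not cluster.
    tol
        Convergence threshold on the largest per-cell change in theta
        between iterations.
    theta_init
        Starting contamination proportion for every cell; also scales the
        background subtraction that initializes ``phi``.
    prior
        Beta(alpha, beta) hyperparameters of the theta prior; (1, 1) is flat
        (MAP reduces to maximum likelihood).

    The EM objective (log-likelihood plus log prior) is checked to be
    non-decreasing every iteration.  Deterministic: the fit has no internal
    randomness; ``seed`` is accepted for interface uniformity.
    """
    labels = pd.Series(np.asarray(cluster_labels, dtype=object),
                       index=adata.obs_names)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters to define a contamination source")
    a, b = prior
    if a < 1 or b < 1:
        raise ValueError("Beta prior hyperparameters must be >= 1 for MAP updates")

    X = sp.csr_matrix(adata.X).astype(np.float64)
    n_cells, n_genes = X.shape
    k_of = labels.map({c: i for i, c in enumerate(clusters)}).to_numpy()
    coo = X.tocoo()
    row, col, val = coo.row, coo.col, coo.data
    k_nnz = k_of[row]
    cell_totals = np.asarray(X.sum(axis=1)).ravel()

    # raw cluster profiles and background-subtracted phi init
    raw = np.zeros((len(clusters), n_genes))
    np.add.at(raw, (k_nnz, col), val)
    raw_phi, raw_eta = _cluster_native_profiles(raw)
    phi0 = np.maximum(raw_phi - theta_init * raw_eta, 0.0)
    degenerate = phi0.sum(axis=1) <= 0
    phi0[degenerate] = raw_phi[degenerate]
    native = phi0 / phi0.sum(axis=1, keepdims=True) * raw.sum(axis=1, keepdims=True)
    phi, eta = _cluster_native_profiles(native)

    theta = np.full(n_cells, float(theta_init))
    trace = []
    converged = False
    prev = -np.inf
    for it in range(max_iter):
        phi_nnz = phi[k_nnz, col]
        eta_nnz = eta[k_nnz, col]
        t_nnz = theta[row]
        mix = (1.0 - t_nnz) * phi_nnz + t_nnz * eta_nnz
        ll = float(np.dot(val, np.log(np.maximum(mix, _EPS))))
        ll += float(np.sum((a - 1) * np.log(np.maximum(theta, _EPS))
                           + (b - 1) * np.log(np.maximum(1 - theta, _EPS))))
        trace.append(ll)
        if len(trace) > 1 and ll + 1e-6 * max(1.0, abs(prev)) < prev:
            raise AssertionError(
                f"EM objective decreased at iteration {it}: {prev} -> {ll}")
        prev = ll

        # E-step: posterior contamination responsibility per nonzero entry
        z = np.divide(t_nnz * eta_nnz, np.maximum(mix, _EPS))
        # M-step: MAP theta, then phi from native-weighted counts, eta from phi
        cont = np.zeros(n_cells)
        np.add.at(cont, row, val * z)
        theta_new = (cont + a - 1.0) / (cell_totals + a + b - 2.0)
        theta_new = np.clip(theta_new, 0.0, 1.0)
        delta = float(np.max(np.abs(theta_new - theta)))
        theta = theta_new
        if delta < tol:
            converged = True
            break
        native = np.zeros((len(clusters), n_genes))
        np.add.at(native, (k_nnz, col), val * (1.0 - z))
        phi, eta = _cluster_native_profiles(native)

    if not converged:
        logger.warning("EM reached max_iter=%d without converging", max_iter)

    # Identification: the mixture likelihood is exactly invariant under
    # phi_k -> (1-lam) phi_k + lam eta_k, theta_c -> (theta_c - lam)/(1-lam)
    # (a cluster profile can absorb any constant share of its contamination
    # signature), so the fit alone cannot pin theta's origin.  Convention:
    # shift each cluster so its least-contaminated cell is clean (theta = 0).
    # Inert whenever some cell already sits at theta = 0.
    for ki in range(len(clusters)):
        in_k = k_of == ki
        if not in_k.any():
            continue
        lam = float(theta[in_k].min())
        if lam > 0:
            theta[in_k] = (theta[in_k] - lam) / (1.0 - lam)
            phi[ki] = (1.0 - lam) * phi[ki] + lam * eta[ki]
    return ContaminationModel(
        clusters=list(clusters), genes=list(adata.var_names), phi=phi, eta=eta,
        theta=pd.Series(theta, index=adata.obs_names, name="theta"),
        cluster_of=labels, loglik_trace=np.asarray(trace), converged=converged,
        prior=(a, b))


def decontaminate(adata: ad.AnnData, model: ContaminationModel) -> ad.AnnData:
    """Subtract the expected contamination component from every count.

    Each entry is replaced by its posterior expected native component
    ``x * (1 - z)``, rounded toward zero into ``X``; the real-valued matrix is
    kept in ``layers['native_expected']``.  Corrected counts never exceed the
    raw counts and are never negative.
    """
    if list(adata.var_names) != model.genes:
        raise ValueError("matrix genes do not match the fitted model")
    if not adata.obs_names.equals(model.theta.index):
        raise ValueError("matrix cells do not match the fitted model")
    X = sp.csr_matrix(adata.X).astype(np.float64)
    coo = X.tocoo()
    k_idx = {c: i for i, c in enumerate(model.clusters)}
    k_of = model.cluster_of.map(k_idx).to_numpy()
    k_nnz = k_of[coo.row]
    phi_nnz = model.phi[k_nnz, coo.col]
    eta_nnz = model.eta[k_nnz, coo.col]
    t_nnz = model.theta.to_numpy()[coo.row]
    mix = (1.0 - t_nnz) * phi_nnz + t_nnz * eta_nnz
    z = np.divide(t_nnz * eta_nnz, np.maximum(mix, _EPS))
    native_val = coo.data * (1.0 - z)
    native = sp.coo_matrix((native_val, (coo.row, coo.col)), shape=X.shape)
    out = adata.copy()
    out.layers["native_expected"] = native.tocsr()
    out.X = sp.csr_matrix(
        (np.floor(native_val), (coo.row, coo.col)), shape=X.shape)
    out.X.eliminate_zeros()
    out.obs["theta"] = model.theta.values
    return out


def contamination_summary(model: ContaminationModel) -> pd.Series:
    """Median contamination proportion per cluster, in percent."""
    return (model.theta.groupby(model.cluster_of.values).median() * 100.0
            ).rename("median_contamination_pct")
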