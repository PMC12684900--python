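"""PCA on reference genotypes, least-squares projection, PC distances.

The PCA is the population-genetic standard: genotype codes (0/1/2) are
centered per site by their mean and scaled by sqrt(p(1-p)) with
p = mean/2, monomorphic sites dropped, and the standardized matrix is
decomposed by SVD. Query samples — possibly with missing genotypes — are
placed by least squares: their observed, standardized genotypes are
regressed on the loadings restricted to the observed sites, the approach
used to project low-coverage samples onto a reference PC space.

The distance between two projected versions of the same individual is the
sum of weighted per-PC distances over the top K PCs (default 10),

    D(a, b) = sum_k w_k |a_k - b_k|,   w_k = lambda_k / sum_j lambda_j,

i.e. an eigenvalue-weighted L1 metric; squared-difference and unweighted
variants are available for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from canroh.variant_io import MISSING

DEFAULT_N_PCS = 10


@dataclasses.dataclass
class PCAModel:
    """Fitted PC space: per-site centering/scaling and orthonormal loadings."""

    site_means: np.ndarray      # (n_sites,) over the ORIGINAL site list
    site_scales: np.ndarray     # (n_sites,); 0 marks dropped monomorphic sites
    loadings: np.ndarray        # (n_kept_sites, K), orthonormal columns
    eigenvalues: np.ndarray     # (K,), non-increasing
    kept: np.ndarray            # boolean (n_sites,): sites used by the model

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]


def fit_pca(reference_genotypes: np.ndarray, k: int = DEFAULT_N_PCS
            ) -> tuple[PCAModel, np.ndarray]:
    """Fit a PC space on complete reference genotypes.

    Parameters
    ----------
    reference_genotypes : (n_samples, n_sites) codes 0/1/2, no missing
    k : number of PCs to retain

    Returns
    -------
    (model, scores) with reference scores of shape (n_samples, k).
    """
    G = np.asarray(reference_genotypes, dtype=float)
    if np.any(G == MISSING) or np.isnan(G).any():
        raise ValueError("reference genotypes must be complete")
    n, m = G.shape
    means = G.mean(axis=0)
    p = means / 2.0
    scales = np.sqrt(p * (1.0 - p))
    kept = scales > 0
    if not kept.any():
        raise ValueError("all sites are monomorphic in the reference")
    if k > min(n, int(kept.sum())):
        raise ValueError("k exceeds the available rank")
    X = (G[:, kept] - means[kept]) / scales[kept]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # fix loading signs: largest-magnitude entry of each column positive
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    loadings = Vt.T
    eigenvalues = s**2 / (n - 1)
    scores = U * s
    model = PCAModel(site_means=means, site_scales=scales,
                     loadings=loadings, eigenvalues=eigenvalues, kept=kept)
    return model, scores


def project(query_genotypes: np.ndarray, model: PCAModel) -> np.ndarray:
    """Project one query sample (codes 0/1/2, -1/NaN = missing) into the
    fitted PC space by least squares over its observed sites."""
    x = np.asarray(query_genotypes, dtype=float).ravel()
    if x.shape[0] != model.site_means.shape[0]:
        raise ValueError("query length does not match the model's site list")
    obs = (x != MISSING) & ~np.isnan(x) & model.kept
    n_obs = int(obs.sum())
    if n_obs < model.n_pcs:
        raise ValueError(f"only {n_obs} observed sites for "
                         f"{model.n_pcs} PCs")
    z = (x[obs] - model.site_means[obs]) / model.site_scales[obs]
    L = model.loadings[obs[model.kept]]
    scores, *_ = np.linalg.lstsq(L, z, rcond=None)
    return scores


def weighted_pc_distance(scores_a: np.ndarray, scores_b: np.ndarray,
                         eigenvalues: np.ndarray,
                         k: int = DEFAULT_N_PCS,
                         squared: bool = False,
                         weighted: bool = True) -> float:
    """Sum of weighted per-PC distances over the top k PCs.

    w_k proportional to the k-th eigenvalue (normalized over the k used);
    per-PC distance is |a_k - b_k| (or squared difference with
    ``squared``). ``weighted=False`` gives uniform weights 1/k.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    if k > min(a.size, b.size, lam.size):
        raise ValueError("k exceeds the available number of PCs")
    a, b, lam = a[:k], b[:k], lam[:k]
    w = lam / lam.sum() if weighted else np.full(k, 1.0 / k)
    d = (a - b) ** 2 if squared else np.abs(a - b)
    return float((w * d).sum())
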