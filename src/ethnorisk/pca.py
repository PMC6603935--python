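"""Covariance PCA of the ethnicity-by-SNP relative-risk grids.

Each gene group yields a small matrix (ethnicities as cases, SNP RRs as
variables).  Principal components are the eigenvectors of the *covariance*
matrix of the mean-centered variables — no variance scaling by default, so
SNPs with larger RR spread dominate, which is the intended reading of the
risk grids (a ``scale=True`` switch gives correlation PCA for sensitivity).
Ethnicity scores and biplot-scaled SNP loadings place cases and variables in
the same PC plane: nearby ethnicities have similar group-wide risk profiles.

With four cases at most three components carry variance; two are retained by
default (the PC plane).  The decomposition is deterministic: dense symmetric
eigensolver plus a fixed sign convention (each component's largest-magnitude
loading is nonnegative).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError
from .risk import RelativeRiskMatrix

logger = logging.getLogger(__name__)

#: Total variance at or below this is treated as degenerate (all cases identical).
DEGENERATE_VARIANCE_TOL = 1e-12


class CovariancePCA(BaseEstimator, TransformerMixin):
    """PCA by eigendecomposition of the covariance (or correlation) matrix.

    sklearn-compatible transformer.  Unlike :class:`sklearn.decomposition.PCA`
    it keeps the *full* eigenvalue spectrum in ``explained_variance_`` (so the
    explained ratios always sum to one) while ``components_`` holds only the
    retained components.

    Parameters
    ----------
    n_components : number of components to retain (default 2, the PC plane);
        ``None`` retains all.
    scale : if True, divide centered columns by their standard deviation
        (correlation PCA).  Zero-variance columns are left unscaled.

    Fitted attributes
    -----------------
    mean_, scale_ : per-feature centering/scaling vectors
    components_ : (n_components, n_features) retained eigenvectors (rows)
    explained_variance_ : all eigenvalues, descending, clipped at zero
    explained_variance_ratio_ : eigenvalues / total variance (zeros when degenerate)
    degenerate_ : True when the total variance is numerically zero
    """

    def __init__(self, n_components: int | None = 2, scale: bool = False) -> None:
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None) -> "CovariancePCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ConfigError("X must be a 2-D array (cases x variables)")
        n, p = X.shape
        if n < 2 or p < 2:
            raise ConfigError(f"need at least 2 cases and 2 variables, got {X.shape}")
        if not np.isfinite(X).all():
            raise ConfigError("X contains non-finite values")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.scale:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0.0] = 1.0
            self.scale_ = sd
        else:
            self.scale_ = np.ones(p)
        Xc = Xc / self.scale_
        cov = (Xc.T @ Xc) / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        eigvecs = eigvecs[:, order]
        # fixed sign convention: largest-|loading| entry of each component >= 0
        for j in range(eigvecs.shape[1]):
            i = int(np.argmax(np.abs(eigvecs[:, j])))
            if eigvecs[i, j] < 0:
                eigvecs[:, j] = -eigvecs[:, j]
        total = float(eigvals.sum())
        self.degenerate_ = total <= DEGENERATE_VARIANCE_TOL
        self.explained_variance_ = eigvals
        self.explained_variance_ratio_ = (
            np.zeros_like(eigvals) if self.degenerate_ else eigvals / total
        )
        k = eigvals.size if self.n_components is None else min(self.n_components, eigvals.size)
        self.n_components_ = int(k)
        self.components_ = eigvecs[:, :k].T
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return ((X - self.mean_) / self.scale_) @ self.components_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass(frozen=True)
class PcaResult:
    """PCA of one gene group's RR grid: scores, biplot loadings, spectrum."""

    group: str
    ethnicities: tuple[str, ...]
    snp_labels: tuple[str, ...]
    snp_rsids: tuple[str, ...]
    snp_genes: tuple[str, ...]
    scores: dict[str, tuple[float, ...]]
    loadings: dict[str, tuple[float, ...]]
    explained_variance: tuple[float, ...]
    explained_ratio: tuple[float, ...]
    n_components_retained: int
    degenerate: bool
    scaled: bool


def run_pca(
    matrix: RelativeRiskMatrix,
    group: str,
    n_components: int = 2,
    scale: bool = False,
) -> PcaResult:
    """Covariance PCA of one group's ethnicity-by-SNP RR grid.

    Scores are the centered ethnicity rows projected on the retained
    components; loadings are eigenvector coordinates scaled by
    sqrt(eigenvalue) for biplot overlay.  An all-equal grid (zero total
    variance) yields a degenerate result with every score at the origin.
    """
    snps = matrix.group_snps(group)
    sub = matrix.group_values(group)
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ConfigError(
            f"group {group!r}: PCA needs >=2 ethnicities and >=2 SNPs, got {sub.shape}"
        )
    pca = CovariancePCA(n_components=n_components, scale=scale).fit(sub.to_numpy())
    scores_arr = pca.transform(sub.to_numpy())
    if pca.degenerate_:
        scores_arr = np.zeros_like(scores_arr)
    k = pca.n_components_
    sqrt_ev = np.sqrt(pca.explained_variance_[:k])
    loadings_arr = pca.components_.T * sqrt_ev  # (n_snps, k)
    return PcaResult(
        group=group,
        ethnicities=tuple(sub.index),
        snp_labels=tuple(sub.columns),
        snp_rsids=tuple(s.rsid for s in snps),
        snp_genes=tuple(s.gene for s in snps),
        scores={eth: tuple(map(float, row)) for eth, row in zip(sub.index, scores_arr)},
        loadings={lab: tuple(map(float, row)) for lab, row in zip(sub.columns, loadings_arr)},
        explained_variance=tuple(map(float, pca.explained_variance_)),
        explained_ratio=tuple(map(float, pca.explained_variance_ratio_)),
        n_components_retained=k,
        degenerate=bool(pca.degenerate_),
        scaled=scale,
    )


def export_biplot_data(result: PcaResult, out_dir: str | Path) -> dict[str, Path]:
    """Write ``scores.csv`` (ethnicity, PC1, ...), ``loadings.csv`` (rsid, gene,
    PC1, ...) and a ``variance.json`` sidecar with the spectrum, the loading
    scaling convention and the degenerate flag."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    k = result.n_components_retained
    pc_cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        [(eth, *result.scores[eth]) for eth in result.ethnicities],
        columns=["ethnicity", *pc_cols],
    )
    loadings = pd.DataFrame(
        [
            (rsid, gene, *result.loadings[lab])
            for lab, rsid, gene in zip(result.snp_labels, result.snp_rsids, result.snp_genes)
        ],
        columns=["rsid", "gene", *pc_cols],
    )
    paths = {
        "scores": out_dir / "scores.csv",
        "loadings": out_dir / "loadings.csv",
        "variance": out_dir / "variance.json",
    }
    scores.to_csv(paths["scores"], index=False, float_format="%.17g")
    loadings.to_csv(paths["loadings"], index=False, float_format="%.17g")
    sidecar = {
        "group": result.group,
        "explained_variance": list(result.explained_variance),
        "explained_ratio": list(result.explained_ratio),
        "n_components_retained": k,
        "degenerate": result.degenerate,
        "scaled": result.scaled,
        "loading_scaling": "eigenvector * sqrt(eigenvalue)",
    }
    paths["variance"].write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return paths


def pairwise_case_distances(result: PcaResult) -> dict[tuple[str, str], float]:
    """Euclidean distances between ethnicity scores in the retained PC plane.

    Close ethnicities have similar risk profiles for the group.  A degenerate
    result gives all-zero distances with a logged warning.
    """
    if result.degenerate:
        logger.warning("degenerate PCA for group %s: all pairwise distances are zero",
                       result.group)
    out: dict[tuple[str, str], float] = {}
    for a, b in combinations(result.ethnicities, 2):
        va = np.asarray(result.scores[a])
        vb = np.asarray(result.scores[b])
        out[(a, b)] = float(np.linalg.norm(va - vb))
    return out
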