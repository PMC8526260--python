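"""1000 -> 32 compression of the ventricular-activity feature, and fusion.

Three interchangeable backends, all sklearn transformers operating on
matrices of shape (n_beats, 1000):

* :class:`DWTCompressor` — db4 discrete wavelet transform, five levels;
  the level-5 approximation coefficients are the 32 features.  The input
  is first resampled to 1024 samples and decomposed with periodization
  boundary handling so the approximation has exactly 1024/2^5 = 32
  coefficients.  Training-free and deterministic.
* :class:`PCACompressor` — top-32 right singular vectors of the centred
  training matrix (classic PCA via SVD).
* :class:`LPPCompressor` — locality-preserving projections: a k-NN graph
  with heat-kernel weights, then the generalized eigenproblem
  ``X^T L X a = lambda X^T D X a`` solved for the smallest eigenvalues.

Fusion concatenates, per lead in fixed lead order, the 7 rule features
followed by the 32 compressed values: 12 x (7 + 32) = 468 features.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pywt
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

from mi_ecgkit.features import RULE_FEATURE_NAMES

N_COMPRESSED = 32


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


class DWTCompressor(BaseEstimator, TransformerMixin):
    """db4 five-level approximation coefficients (training-free)."""

    def __init__(self, wavelet: str = "db4", level: int = 5,
                 resample_to: int = 1024):
        self.wavelet = wavelet
        self.level = level
        self.resample_to = resample_to

    def fit(self, X, y=None):
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_matrix(X)
        n = X.shape[1]
        if n != self.resample_to:
            grid = np.linspace(0, n - 1, self.resample_to)
            base = np.arange(n)
            X = np.vstack([np.interp(grid, base, row) for row in X])
        coeffs = pywt.wavedec(X, self.wavelet, mode="periodization",
                              level=self.level, axis=-1)
        return coeffs[0]

    def inverse_approximation(self, approx: np.ndarray, n_out: int = 1000
                              ) -> np.ndarray:
        """Reconstruct from the approximation only (details zeroed)."""
        approx = _as_matrix(approx)
        zeros = [np.zeros((approx.shape[0], approx.shape[1] * 2 ** (k)))
                 for k in range(self.level)]
        rec = pywt.waverec([approx] + zeros, self.wavelet,
                           mode="periodization", axis=-1)
        grid = np.linspace(0, rec.shape[1] - 1, n_out)
        base = np.arange(rec.shape[1])
        return np.vstack([np.interp(grid, base, row) for row in rec])


class PCACompressor(BaseEstimator, TransformerMixin):
    """Top-k principal components of the training matrix (SVD)."""

    def __init__(self, n_components: int = N_COMPRESSED):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if X.shape[0] < self.n_components:
            raise ValueError(
                f"need at least {self.n_components} training rows, "
                f"got {X.shape[0]}")
        self.pca_ = PCA(n_components=self.n_components,
                        svd_solver="full").fit(X)
        self.components_ = self.pca_.components_      # V^T, k x n
        self.mean_ = self.pca_.mean_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pca_")
        return self.pca_.transform(_as_matrix(X))

    def explained_variance(self) -> np.ndarray:
        check_is_fitted(self, "pca_")
        return self.pca_.explained_variance_


class LPPCompressor(BaseEstimator, TransformerMixin):
    """Locality-preserving projections.

    A k-NN adjacency graph (k=7) with heat-kernel weights
    ``exp(-||xi-xj||^2 / t)`` (t = mean squared neighbor distance by
    default) defines graph Laplacian L and degree D; the projection
    directions are the generalized eigenvectors of
    ``X^T L X a = lambda (X^T D X + ridge I) a`` with the smallest
    eigenvalues.  A PCA pre-reduction to the data rank conditions the
    problem.  Fitted on training folds only.
    """

    def __init__(self, n_components: int = N_COMPRESSED, n_neighbors: int = 7,
                 t: float | None = None, ridge: float = 1e-8,
                 pca_prereduce: bool = True):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.t = t
        self.ridge = ridge
        self.pca_prereduce = pca_prereduce

    def fit(self, X, y=None):
        X = _as_matrix(X)
        m, n = X.shape
        if m < self.n_components:
            raise ValueError(
                f"need at least {self.n_components} training rows, got {m}")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.pca_prereduce:
            rank = min(m - 1, n)
            self._pre = PCA(n_components=rank, svd_solver="full").fit(Xc)
            # keep only directions with non-negligible variance
            keep = self._pre.explained_variance_ > 1e-12
            self._pre.components_ = self._pre.components_[keep]
            Z = Xc @ self._pre.components_.T
        else:
            self._pre = None
            Z = Xc
        k = min(self.n_neighbors, m - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
        dist, idx = nn.kneighbors(Z)
        dist, idx = dist[:, 1:], idx[:, 1:]   # drop self
        t = self.t if self.t is not None else float(np.mean(dist ** 2))
        t = max(t, 1e-300)
        W = np.zeros((m, m))
        rows = np.repeat(np.arange(m), k)
        W[rows, idx.ravel()] = np.exp(-(dist.ravel() ** 2) / t)
        W = np.maximum(W, W.T)                # symmetric, zero diagonal
        np.fill_diagonal(W, 0.0)
        D = np.diag(W.sum(axis=1))
        L = D - W
        A = Z.T @ L @ Z
        B = Z.T @ D @ Z + self.ridge * np.eye(Z.shape[1])
        ncomp = min(self.n_components, Z.shape[1])
        vals, vecs = linalg.eigh(A, B,
                                 subset_by_index=(0, ncomp - 1))
        if ncomp < self.n_components:   # pad with zero directions
            vecs = np.hstack([vecs, np.zeros((Z.shape[1],
                                              self.n_components - ncomp))])
            vals = np.concatenate([vals,
                                   np.full(self.n_components - ncomp, np.nan)])
        self.eigenvalues_ = vals
        self._dirs = vecs                     # (rank, k), ordered by eigenvalue
        if self._pre is not None:
            self.projection_ = (self._pre.components_.T @ vecs).T  # (k, n)
        else:
            self.projection_ = vecs.T
        self.W_ = W
        self.t_ = t
        self.n_features_in_ = n
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "projection_")
        return (_as_matrix(X) - self.mean_) @ self.projection_.T

    def objective(self, X) -> float:
        """The locality objective sum_ij ||y_i - y_j||^2 W_ij at the fitted
        projection, evaluated on ``X`` with the training graph."""
        Y = self.transform(X)
        d2 = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
        return float((d2 * self.W_).sum())


COMPRESSORS = {"dwt": DWTCompressor, "pca": PCACompressor, "lpp": LPPCompressor}


def make_compressor(method: str, **kwargs):
    try:
        return COMPRESSORS[method.lower()](**kwargs)
    except KeyError:
        raise ValueError(f"unknown compression method {method!r}; "
                         f"choose from {sorted(COMPRESSORS)}")


# -- thin functional wrappers over the estimator surface --------------------

def dwt_compress(vf: np.ndarray) -> np.ndarray:
    """1000-sample ventricular feature -> 32 db4 approximation values."""
    return DWTCompressor().fit_transform(np.atleast_2d(vf))[0]


def pca_fit(training: np.ndarray, n_components: int = N_COMPRESSED
            ) -> PCACompressor:
    return PCACompressor(n_components=n_components).fit(training)


def pca_transform(proj: PCACompressor, vf: np.ndarray) -> np.ndarray:
    return proj.transform(np.atleast_2d(vf))[0]


def lpp_fit(training: np.ndarray, **kwargs) -> LPPCompressor:
    return LPPCompressor(**kwargs).fit(training)


def lpp_transform(graph: LPPCompressor, vf: np.ndarray) -> np.ndarray:
    return graph.transform(np.atleast_2d(vf))[0]


# -- fusion -----------------------------------------------------------------

def fuse_features(rule: pd.DataFrame | None, compressed: np.ndarray | None,
                  lead_names: list[str], feature_set: str = "fused"
                  ) -> pd.DataFrame:
    """Fuse per-lead rule and compressed blocks into the final matrix.

    Per lead, in fixed lead order: the 7 rule features then the 32
    compressed values.  ``feature_set`` selects "fused" (12x39 = 468),
    "rule" (84) or "ventricular" (384).
    """
    blocks = []
    for li, lead in enumerate(lead_names):
        if feature_set in ("fused", "rule"):
            cols = [f"{lead}_{f}" for f in RULE_FEATURE_NAMES]
            missing = [c for c in cols if c not in rule.columns]
            if missing:
                raise ValueError(f"missing rule features for lead {lead}")
            blocks.append(rule[cols].reset_index(drop=True))
        if feature_set in ("fused", "ventricular"):
            vals = compressed[:, li, :]
            cols = [f"{lead}_vf_{k:02d}" for k in range(vals.shape[1])]
            blocks.append(pd.DataFrame(vals, columns=cols))
    if not blocks:
        raise ValueError(f"unknown feature set {feature_set!r}")
    return pd.concat(blocks, axis=1)


def fit_compressors(qt: np.ndarray, compressor) -> list:
    """Fit one compressor instance per lead on (n_beats, n_leads, 1000).

    Trainable backends (PCA, LPP) must only ever see training-fold rows
    here; :func:`apply_compressors` then transforms any rows.
    """
    from sklearn.base import clone

    return [clone(compressor).fit(qt[:, li, :]) for li in range(qt.shape[1])]


def apply_compressors(qt: np.ndarray, fitted: list) -> np.ndarray:
    """Transform (n_beats, n_leads, 1000) -> (n_beats, n_leads, 32)."""
    n, L, _ = qt.shape
    out = np.empty((n, L, N_COMPRESSED))
    for li in range(L):
        out[:, li, :] = fitted[li].transform(qt[:, li, :])
    return out


def projection_to_json(comp) -> str:
    """Serialize a fitted PCA/LPP projection (matrix + means + params)."""
    if isinstance(comp, PCACompressor):
        payload = {"method": "pca", "components": comp.components_.tolist(),
                   "mean": comp.mean_.tolist(),
                   "params": comp.get_params()}
    elif isinstance(comp, LPPCompressor):
        payload = {"method": "lpp", "projection": comp.projection_.tolist(),
                   "mean": comp.mean_.tolist(), "t": comp.t_,
                   "params": comp.get_params()}
    elif isinstance(comp, DWTCompressor):
        payload = {"method": "dwt", "params": comp.get_params()}
    else:
        raise TypeError(f"cannot serialize {type(comp).__name__}")
    return json.dumps(payload)
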