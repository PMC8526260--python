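"""Baseline-wander and high-frequency noise removal by wavelet decomposition.

Each lead is decomposed with a multilevel DWT; the coarsest approximation
(the baseline-drift band) is zeroed, the finest detail levels are
soft-thresholded with the universal threshold sigma*sqrt(2 ln n) (sigma
estimated from the median absolute deviation of the finest details), and
the signal is reconstructed.  The decomposition depth is chosen so the
approximation band falls below ~0.7 Hz: ``ceil(log2(fs / 0.7))`` capped
at 9 levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class WaveletSpec:
    """Parameters of a discrete wavelet analysis."""

    basis: str = "db6"
    scale: float = 1.0        # a > 0
    translation: float = 0.0  # b
    levels: int = 6
    mode: str = "symmetric"

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale factor a must be positive")
        if self.levels < 1:
            raise ValueError("need at least one decomposition level")


def dwt(signal: np.ndarray, spec: WaveletSpec) -> list[np.ndarray]:
    """Multilevel DWT: ``[approximation, detail_L, ..., detail_1]``.

    Perfect reconstruction holds with :func:`idwt`.
    """
    signal = np.asarray(signal, dtype=float)
    try:
        wavelet = pywt.Wavelet(spec.basis)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet basis {spec.basis!r}") from exc
    if signal.size < wavelet.dec_len:
        raise ValueError("signal shorter than the analysis filter")
    return pywt.wavedec(signal, wavelet, mode=spec.mode, level=spec.levels)


def idwt(coeffs: list[np.ndarray], spec: WaveletSpec, n: int | None = None
         ) -> np.ndarray:
    """Inverse of :func:`dwt`; trims to ``n`` samples if given."""
    x = pywt.waverec(coeffs, pywt.Wavelet(spec.basis), mode=spec.mode)
    return x[:n] if n is not None else x


def denoise_levels(fs: float, cutoff_hz: float = 0.7, cap: int = 9) -> int:
    """Decomposition depth putting the approximation band below the cutoff."""
    return min(cap, max(1, math.ceil(math.log2(fs / cutoff_hz))))


class WaveletDenoiser(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer removing drift and noise.

    Parameters
    ----------
    fs : sampling rate in Hz (needed to pick the decomposition depth).
    wavelet : analysis basis; db6 by default (smooth enough not to distort
        the QRS complex the downstream features depend on).
    levels : decomposition depth, or None to derive it from ``fs``.
    n_detail_thresholded : how many of the finest detail levels get
        soft-thresholded; 2 by default so QRS morphology is preserved.
    mode : boundary extension; symmetric avoids edge spikes that would
        otherwise confuse the delineator.
    """

    def __init__(self, fs: float = 1000.0, wavelet: str = "db6",
                 levels: int | None = None, n_detail_thresholded: int = 2,
                 mode: str = "symmetric"):
        self.fs = fs
        self.wavelet = wavelet
        self.levels = levels
        self.n_detail_thresholded = n_detail_thresholded
        self.mode = mode

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.n_features_in_ = X.shape[1]
        if self.levels is not None:
            self.levels_ = self.levels
        else:
            # auto depth, capped to what the record length supports
            max_lv = pywt.dwt_max_level(X.shape[0], pywt.Wavelet(self.wavelet))
            self.levels_ = max(1, min(denoise_levels(self.fs), max_lv))
        return self

    def transform(self, X) -> np.ndarray:
        """Denoise each column (lead) of ``X`` independently."""
        if not hasattr(self, "levels_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        if np.isnan(X).any():
            raise ValueError("record contains NaNs")
        n = X.shape[0]
        if n < 2 ** self.levels_:
            raise ValueError(
                f"record of {n} samples is shorter than 2^{self.levels_}; "
                "reduce the decomposition depth")
        out = np.empty_like(X)
        spec = WaveletSpec(self.wavelet, levels=self.levels_, mode=self.mode)
        for j in range(X.shape[1]):
            coeffs = dwt(X[:, j], spec)
            coeffs[0] = np.zeros_like(coeffs[0])  # baseline-drift band
            finest = coeffs[-1]
            sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
            thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
            if thr > 0:
                for lev in range(1, self.n_detail_thresholded + 1):
                    if len(coeffs) > lev:
                        coeffs[-lev] = pywt.threshold(coeffs[-lev], thr,
                                                      "soft")
            out[:, j] = idwt(coeffs, spec, n)
        return out[:, 0] if squeeze else out


def denoise(samples: np.ndarray, fs: float, **kwargs) -> np.ndarray:
    """Functional wrapper over :class:`WaveletDenoiser`."""
    return WaveletDenoiser(fs=fs, **kwargs).fit_transform(samples)
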