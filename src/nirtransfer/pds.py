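"""Piecewise direct standardization (PDS) — the classical comparator.

Each destination wavelength j is regressed (PLS1) on a small moving window
of source wavelengths centred at j; the per-wavelength coefficient vectors
b_j assemble into a banded diagonal transformation matrix.  PDS therefore
requires the two instruments to share the same number of wavelength points;
unequal grids must be resampled onto a common axis first
(:func:`nirtransfer.spectra.resample_to_axis`).

Each windowed regression is mean-centred and its intercept retained, so the
transform also removes additive absorbance offsets between instruments
(systematic shifts of ~0.1 AU are typical between bench and handheld units).
Edge windows are clipped to the axis, never padded.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import PairingError, ParameterError, ShapeError
from .ipca import _check_transfer_size
from .pls import _coef_sequence, _nipals_pls1
from .spectra import SpectrumSet

__all__ = ["PDSTransfer", "fit_pds", "apply_pds"]


class PDSTransfer(TransformerMixin, BaseEstimator):
    """Moving-window direct standardization between equal-length grids.

    Parameters
    ----------
    window : int
        Odd window width W in points.
    n_components : int
        Latent variables (nLV) for every windowed PLS1 regression; capped at
        the (possibly clipped) window width at the axis edges.

    Attributes
    ----------
    coefficients_ : list of (lo, hi, b_j)
        Per destination wavelength j: the source column range [lo, hi) and
        the regression vector over it.
    intercepts_ : ndarray (p,)
        Per-wavelength offsets.
    """

    def __init__(self, window: int = 17, n_components: int = 2):
        self.window = window
        self.n_components = n_components

    def fit(self, X, Y):
        """Fit from paired transfer sets on a common p-point grid."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        n, p = X.shape
        if Y.shape[0] != n:
            raise PairingError(
                f"transfer sets are not paired: {n} vs {Y.shape[0]} samples"
            )
        if Y.shape[1] != p:
            raise ShapeError(
                f"PDS needs equal grids: source has {p} points, destination "
                f"{Y.shape[1]}; resample onto a common axis first"
            )
        if self.window % 2 == 0 or not 1 <= self.window <= p:
            raise ParameterError(
                f"window must be odd and within [1, {p}]; got {self.window}"
            )
        if not 1 <= self.n_components <= min(max(n - 1, 1), self.window):
            raise ParameterError(
                f"n_components={self.n_components} outside "
                f"[1, min(n_t-1={n - 1}, window={self.window})]"
            )
        _check_transfer_size(n)
        half = self.window // 2
        coeffs: list[tuple[int, int, np.ndarray]] = []
        intercepts = np.empty(p)
        for j in range(p):
            lo, hi = max(0, j - half), min(p, j + half + 1)
            Xw = X[:, lo:hi]
            yj = Y[:, j]
            xm = Xw.mean(axis=0)
            ym = yj.mean()
            if np.ptp(yj) == 0.0:
                b = np.zeros(hi - lo)  # flat response: pure offset column
            else:
                a = min(self.n_components, hi - lo, max(n - 1, 1))
                W, P, q = _nipals_pls1(Xw - xm, yj - ym, a)
                b = _coef_sequence(W, P, q)[:, -1]
            coeffs.append((lo, hi, b))
            intercepts[j] = ym - xm @ b
        self.coefficients_ = coeffs
        self.intercepts_ = intercepts
        self.n_features_in_ = p
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ShapeError(
                f"expected {self.n_features_in_} wavelengths, got {X.shape[1]}"
            )
        out = np.empty_like(X)
        for j, (lo, hi, b) in enumerate(self.coefficients_):
            out[:, j] = X[:, lo:hi] @ b + self.intercepts_[j]
        return out

    def banded_matrix(self) -> np.ndarray:
        """Assemble the full p x p transform; zero outside the window band."""
        p = self.n_features_in_
        F = np.zeros((p, p))
        for j, (lo, hi, b) in enumerate(self.coefficients_):
            F[lo:hi, j] = b
        return F


# ---------------------------------------------------------------------------
# SpectrumSet-level surface
# ---------------------------------------------------------------------------

def fit_pds(
    src_transfer: SpectrumSet,
    dest_transfer: SpectrumSet,
    window: int,
    n_lv: int,
) -> PDSTransfer:
    """Fit PDS from paired transfer sets measured on equal-length grids."""
    if src_transfer.n_samples != dest_transfer.n_samples:
        raise PairingError(
            f"transfer sets are not paired: {src_transfer.n_samples} vs "
            f"{dest_transfer.n_samples} samples"
        )
    model = PDSTransfer(window=window, n_components=n_lv)
    model.fit(src_transfer.absorbance, dest_transfer.absorbance)
    model.src_axis_ = src_transfer.wavelengths
    model.dest_axis_ = dest_transfer.wavelengths
    model.dest_label_ = dest_transfer.instrument_label
    return model


def apply_pds(model: PDSTransfer, spectra: SpectrumSet) -> SpectrumSet:
    """Standardize ``spectra`` onto the destination instrument's response."""
    if spectra.n_wavelengths != model.n_features_in_:
        raise ShapeError(
            f"model expects {model.n_features_in_} wavelengths, spectra have "
            f"{spectra.n_wavelengths}"
        )
    out = model.transform(spectra.absorbance)
    label = (model.dest_label_ or "destination") + " (transferred)"
    return spectra.with_absorbance(
        out, wavelengths=model.dest_axis_, instrument_label=label
    )
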