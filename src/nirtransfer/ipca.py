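"""Score-space PCA calibration transfer between unequal wavelength grids.

The method (here ``IPCATransfer``) links two spectrometers through the
principal-component scores of the *destination* instrument's transfer-set
spectra rather than through the spectra themselves:

1. thin SVD of the destination transfer matrix X_dest = U S V^T; the top
   ``k`` components give scores T = U_k S_k and loadings P = V_k, the
   remainder is the discarded noise part E;
2. the source instrument's paired transfer spectra are regressed onto those
   scores through a generalized inverse, F = pinv(X_src) @ T;
3. any spectrum measured on the source grid is then mapped into the
   destination grid as X @ F @ P^T.

Because the link runs through the k-dimensional score space, the two
instruments' wavelength grids never need the same number of points — this is
what lets a 125-point handheld spectrum be rebuilt on a 1557-point benchtop
axis (or vice versa).  No centring is applied inside the transfer: the
decomposition acts on raw absorbance, matching the package's "no
pretreatment" default; centring, if wanted, comes through a PreprocessSpec
applied identically to both instruments upstream.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    ConditioningWarning,
    LeverageWarning,
    PairingError,
    ParameterError,
    ShapeError,
    TransferSetSizeWarning,
)
from .spectra import SpectrumSet

__all__ = ["IPCATransfer", "fit_ipca", "apply_ipca", "fit_bidirectional"]


def _flip_signs(U: np.ndarray, Vt: np.ndarray):
    """Deterministic SVD sign convention: the largest-|.| loading entry of
    each component is made positive (the factorization itself leaves the
    sign of each U/V column pair free)."""
    k = Vt.shape[0]
    signs = np.empty(k)
    for i in range(k):
        signs[i] = 1.0 if Vt[i, np.argmax(np.abs(Vt[i]))] >= 0 else -1.0
    return U * signs, Vt * signs[:, None]


def _check_transfer_size(n: int) -> None:
    if n < 10:
        warnings.warn(
            f"transfer set has only {n} samples; at least 10 are needed for a "
            "meaningful transformation",
            TransferSetSizeWarning,
            stacklevel=3,
        )
    elif n < 30:
        warnings.warn(
            f"transfer set has {n} samples; 30+ representative samples are "
            "recommended for quantitative use",
            TransferSetSizeWarning,
            stacklevel=3,
        )


class IPCATransfer(TransformerMixin, BaseEstimator):
    """Bidirectionally applicable PCA score-space transfer map (one direction
    per fitted instance).

    Parameters
    ----------
    n_components : int
        Number of retained principal components (nPC) of the destination
        transfer spectra.
    rcond : float
        Relative singular-value cutoff for the generalized inverse of the
        source transfer matrix.
    direction_label : str
        Free text naming the direction, e.g. ``"MicroNIR->FT-NIR"``.

    Attributes
    ----------
    transform_matrix_ : ndarray (p_src, k)
        The matrix F mapping source-grid spectra into the score space.
    loadings_ : ndarray (p_dest, k)
        Orthonormal destination loadings P.
    scores_ : ndarray (n_t, k)
        Destination transfer-set scores T = U_k S_k.
    residual_ : ndarray (n_t, p_dest)
        Discarded noise part E of the destination transfer matrix.
    singular_values_ : ndarray
        All singular values of the destination transfer matrix.
    """

    def __init__(
        self,
        n_components: int = 5,
        rcond: float = 1e-12,
        direction_label: str = "",
    ):
        self.n_components = n_components
        self.rcond = rcond
        self.direction_label = direction_label

    def fit(self, X, Y):
        """Fit from paired transfer sets: X on the source grid (n_t x p_src),
        Y on the destination grid (n_t x p_dest), identical sample order."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        n, p_src = X.shape
        n_y, p_dest = Y.shape
        if n != n_y:
            raise PairingError(
                f"transfer sets are not paired: {n} source vs {n_y} destination "
                "samples"
            )
        k = self.n_components
        if not 1 <= k <= min(n, p_dest):
            raise ParameterError(
                f"n_components={k} outside [1, min(n_t={n}, p_dest={p_dest})]"
            )
        _check_transfer_size(n)

        U, sv, Vt = np.linalg.svd(Y, full_matrices=False)
        U, Vt = _flip_signs(U, Vt)
        self.scores_ = U[:, :k] * sv[:k]
        self.loadings_ = Vt[:k].T
        self.residual_ = Y - self.scores_ @ self.loadings_.T
        self.singular_values_ = sv

        Ux, sx, Vxt = np.linalg.svd(X, full_matrices=False)
        if sx[-1] < 1e-10 * sx[0]:
            warnings.warn(
                "source transfer matrix is near rank deficiency "
                f"(sigma_min/sigma_max = {sx[-1] / sx[0]:.2e}); the generalized "
                "inverse truncates the unstable directions",
                ConditioningWarning,
                stacklevel=2,
            )
        keep = sx > self.rcond * sx[0]
        pinv = (Vxt[keep].T / sx[keep]) @ Ux[:, keep].T
        self.transform_matrix_ = pinv @ self.scores_
        self._src_basis = Vxt[keep]  # row-space basis, for leverage checks
        self.n_features_in_ = p_src
        self.n_components_ = k
        return self

    def transform(self, X):
        """Map source-grid spectra (m x p_src) onto the destination grid."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ShapeError(
                f"expected {self.n_features_in_} wavelengths, got {X.shape[1]}"
            )
        self._warn_on_leverage(X)
        return X @ self.transform_matrix_ @ self.loadings_.T

    def _warn_on_leverage(self, X: np.ndarray) -> None:
        """Warn when inputs lie mostly outside the transfer set's row space —
        the transformation only constrains that subspace."""
        norms = np.linalg.norm(X, axis=1)
        live = norms > 0
        if not live.any():
            return
        proj = X[live] @ self._src_basis.T
        out_frac2 = 1.0 - (np.linalg.norm(proj, axis=1) / norms[live]) ** 2
        if np.median(out_frac2) > 0.5:
            warnings.warn(
                "more than half of the input energy lies outside the span of "
                "the source transfer set; transferred spectra may be unreliable",
                LeverageWarning,
                stacklevel=3,
            )


# ---------------------------------------------------------------------------
# SpectrumSet-level surface
# ---------------------------------------------------------------------------

def fit_ipca(
    src_transfer: SpectrumSet,
    dest_transfer: SpectrumSet,
    n_pc: int,
    direction_label: str | None = None,
) -> IPCATransfer:
    """Fit the transfer map taking ``src_transfer``'s instrument onto
    ``dest_transfer``'s instrument.

    Both SpectrumSets must hold the same physical samples in the same row
    order (paired transfer standards).
    """
    if src_transfer.n_samples != dest_transfer.n_samples:
        raise PairingError(
            f"transfer sets are not paired: {src_transfer.n_samples} vs "
            f"{dest_transfer.n_samples} samples"
        )
    if (
        src_transfer.sample_ids != dest_transfer.sample_ids
        and set(src_transfer.sample_ids) == set(dest_transfer.sample_ids)
    ):
        raise PairingError(
            "transfer sets hold the same sample ids in different orders; "
            "reorder before fitting"
        )
    if direction_label is None:
        direction_label = (
            f"{src_transfer.instrument_label or 'src'}->"
            f"{dest_transfer.instrument_label or 'dest'}"
        )
    model = IPCATransfer(n_components=n_pc, direction_label=direction_label)
    model.fit(src_transfer.absorbance, dest_transfer.absorbance)
    model.src_axis_ = src_transfer.wavelengths
    model.dest_axis_ = dest_transfer.wavelengths
    model.dest_label_ = dest_transfer.instrument_label
    return model


def apply_ipca(model: IPCATransfer, spectra: SpectrumSet) -> SpectrumSet:
    """Transfer ``spectra`` (source grid) onto the destination grid.

    Reference values and sample ids are carried through unchanged; the
    output is tagged as transferred.
    """
    if spectra.n_wavelengths != model.src_axis_.size:
        raise ShapeError(
            f"model expects {model.src_axis_.size} wavelengths, spectra have "
            f"{spectra.n_wavelengths}"
        )
    out = model.transform(spectra.absorbance)
    label = (model.dest_label_ or "destination") + " (transferred)"
    return spectra.with_absorbance(
        out, wavelengths=model.dest_axis_, instrument_label=label
    )


def fit_bidirectional(
    source_transfer: SpectrumSet,
    target_transfer: SpectrumSet,
    n_pc_fwd: int,
    n_pc_bwd: int,
) -> tuple[IPCATransfer, IPCATransfer]:
    """Fit both directions at once.

    Returns ``(source->target, target->source)`` — two independent fits; the
    method is symmetric in roles, so each direction gets its own SVD and
    transformation matrix.
    """
    fwd = fit_ipca(source_transfer, target_transfer, n_pc_fwd)
    bwd = fit_ipca(target_transfer, source_transfer, n_pc_bwd)
    return fwd, bwd
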