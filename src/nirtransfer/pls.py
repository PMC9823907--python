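"""From-scratch NIPALS PLS1 regression with leave-one-out nLV selection.

This is the modelling engine used everywhere in the package: the source and
target quantitation models, and the per-window regressions inside piecewise
direct standardization.  PLS1 under NIPALS is fully deterministic — no
random initialisation — which keeps every downstream result reproducible.

X and y are mean-centred inside the fit (standard multivariate-calibration
practice); no variable scaling is applied, since absorbance units are
homogeneous across the axis.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DegenerateResponseError, ParameterError, ShapeError
from .spectra import SpectrumSet

__all__ = ["NIPALSPLS", "fit_pls", "predict", "loo_select_nlv"]

_EPS = np.finfo(float).eps


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Core NIPALS loop on centred data.

    Returns weights W (p x a), X-loadings P (p x a) and y-loadings q (a,),
    with a <= n_components (early stop when the residual is numerically
    exhausted).
    """
    X = Xc.copy()
    y = yc.copy()
    W, P, q = [], [], []
    scale = max(np.abs(Xc).max(initial=0.0), 1.0)
    for _ in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e3 * _EPS * scale * max(np.linalg.norm(y), 1.0):
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= (1e3 * _EPS * scale) ** 2:
            break
        p = X.T @ t / tt
        qa = float(y @ t / tt)
        X -= np.outer(t, p)
        y -= qa * t
        W.append(w)
        P.append(p)
        q.append(qa)
    if not W:
        raise DegenerateResponseError(
            "response has no covariance with the spectra; nothing to regress"
        )
    return np.column_stack(W), np.column_stack(P), np.asarray(q)


def _coef_sequence(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression vectors for 1..a components, shape (p, a).

    b_a = W_a (P_a^T W_a)^{-1} q_a; computed incrementally from the
    triangular structure of P^T W.
    """
    p_dim, a = W.shape
    coefs = np.empty((p_dim, a))
    M = P.T @ W  # upper triangular (up to rounding)
    for k in range(1, a + 1):
        coefs[:, k - 1] = W[:, :k] @ np.linalg.solve(M[:k, :k], q[:k])
    return coefs


class NIPALSPLS(RegressorMixin, BaseEstimator):
    """Univariate-response partial least squares (PLS1) via NIPALS.

    Parameters
    ----------
    n_components : int
        Number of latent variables (nLV) to extract.

    Attributes
    ----------
    x_mean_ : ndarray of shape (p,)
    y_mean_ : float
    coef_ : ndarray of shape (p,)
        Regression vector mapping centred spectra to the centred response.
    x_weights_, x_loadings_ : ndarray of shape (p, n_components_)
    y_loadings_ : ndarray of shape (n_components_,)
    n_components_ : int
        Latent variables actually extracted (may be < ``n_components`` when
        the data rank is exhausted).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ShapeError(f"{y.size} responses for {n} spectra")
        if not 1 <= self.n_components <= min(n - 1 if n > 1 else 1, p):
            raise ParameterError(
                f"n_components={self.n_components} outside [1, min(n-1={n - 1}, p={p})]"
            )
        if np.ptp(y) == 0.0:
            raise DegenerateResponseError("constant response vector")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        W, P, q = _nipals_pls1(X - self.x_mean_, y - self.y_mean_, self.n_components)
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.n_components_ = W.shape[1]
        self.coef_ = _coef_sequence(W, P, q)[:, -1]
        self.n_features_in_ = p
        self.n_samples_ = n
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coef_.size:
            raise ShapeError(
                f"expected {self.coef_.size} wavelengths, got {X.shape[1]}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


# ---------------------------------------------------------------------------
# SpectrumSet-level surface
# ---------------------------------------------------------------------------

def _require_references(s: SpectrumSet) -> np.ndarray:
    if s.references is None:
        raise ParameterError("SpectrumSet carries no reference values to regress on")
    return s.references


def fit_pls(s: SpectrumSet, n_lv: int) -> NIPALSPLS:
    """Fit a PLS1 model of the reference values on the spectra.

    The returned estimator additionally records the training wavelength axis
    (``axis_``) and reference unit for downstream shape checks and reports.
    """
    y = _require_references(s)
    model = NIPALSPLS(n_components=n_lv).fit(s.absorbance, y)
    model.axis_ = s.wavelengths
    model.reference_unit_ = s.reference_unit
    model.training_meta_ = {
        "n_samples": s.n_samples,
        "axis_fingerprint": _axis_fingerprint(s.wavelengths),
        "instrument_label": s.instrument_label,
    }
    return model


def _axis_fingerprint(wl: np.ndarray) -> str:
    return f"{wl.size}:{wl[0]:.6f}:{wl[-1]:.6f}"


def predict(model: NIPALSPLS, s: SpectrumSet) -> np.ndarray:
    """Predict reference values for every sample in ``s``."""
    if s.n_wavelengths != model.coef_.size:
        raise ShapeError(
            f"model expects {model.coef_.size} wavelengths, spectra have "
            f"{s.n_wavelengths}"
        )
    return model.predict(s.absorbance)


def loo_select_nlv(s: SpectrumSet, max_lv: int) -> tuple[int, np.ndarray]:
    """Leave-one-out choice of the number of latent variables.

    For every candidate nLV in 1..max_lv, each sample is predicted by a model
    fitted on the remaining n-1; the nLV minimising RMSECV is returned (ties
    broken towards the smallest nLV) together with the full RMSECV curve.
    """
    y = _require_references(s)
    X = s.absorbance
    n, p = X.shape
    if n < 3:
        raise ParameterError("leave-one-out selection needs at least 3 samples")
    if not 1 <= max_lv <= min(n - 2, p):
        raise ParameterError(
            f"max_lv={max_lv} outside [1, min(n-2={n - 2}, p={p})]"
        )
    press = np.zeros(max_lv)
    counts = np.zeros(max_lv, dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        xm, ym = Xi.mean(axis=0), yi.mean()
        W, P, q = _nipals_pls1(Xi - xm, yi - ym, max_lv)
        coefs = _coef_sequence(W, P, q)  # (p, a_i)
        preds = (X[i] - xm) @ coefs + ym
        a_i = coefs.shape[1]
        press[:a_i] += (preds - y[i]) ** 2
        # rank-exhausted folds keep their deepest available model
        if a_i < max_lv:
            press[a_i:] += (preds[-1] - y[i]) ** 2
        counts[:] += 1
    rmsecv = np.sqrt(press / counts)
    chosen = int(np.argmin(rmsecv)) + 1  # argmin takes the first = smallest nLV
    return chosen, rmsecv
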