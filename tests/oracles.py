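"""Independent oracles used by the test suite.

Everything here is deliberately written without reference to the package
under test (and without scipy's special functions where the package itself
leans on scipy), so that each check is a genuine second route to the same
quantity.
"""

import math

import numpy as np


# -- Student t two-sided p-value via continued-fraction incomplete beta ----

def _betacf(a: float, b: float, x: float) -> float:
    """Continued fraction for the incomplete beta function (Lentz)."""
    max_it, eps, fpmin = 300, 3e-16, 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < fpmin:
        d = fpmin
    d = 1.0 / d
    h = d
    for m in range(1, max_it + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < fpmin:
            d = fpmin
        c = 1.0 + aa / c
        if abs(c) < fpmin:
            c = fpmin
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < fpmin:
            d = fpmin
        c = 1.0 + aa / c
        if abs(c) < fpmin:
            c = fpmin
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            break
    return h


def reg_inc_beta(a: float, b: float, x: float) -> float:
    """Regularized incomplete beta I_x(a, b)."""
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_bt = (
        math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
        + a * math.log(x)
        + b * math.log1p(-x)
    )
    bt = math.exp(ln_bt)
    if x < (a + 1.0) / (a + b + 2.0):
        return bt * _betacf(a, b, x) / a
    return 1.0 - bt * _betacf(b, a, 1.0 - x) / b


def t_two_sided_p(t: float, df: int) -> float:
    """Two-sided p-value of a t statistic with df degrees of freedom."""
    return reg_inc_beta(df / 2.0, 0.5, df / (df + t * t))


def paired_t_oracle(a, b):
    """Textbook paired t-test from first principles."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    sd = d.std(ddof=1)
    t = d.mean() / (sd / math.sqrt(n))
    return t, t_two_sided_p(t, n - 1)


# -- truncated SVD reconstruction ------------------------------------------

def rank_k_approx(Y: np.ndarray, k: int) -> np.ndarray:
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    return (U[:, :k] * s[:k]) @ Vt[:k]


# -- brute-force Kennard-Stone ---------------------------------------------

def kennard_stone_bruteforce(A: np.ndarray, n_select: int) -> list:
    """Maximin selection by exhaustive search, lowest-index tie-break."""
    A = np.asarray(A, float)
    n = A.shape[0]
    D = np.sqrt(((A[:, None, :] - A[None, :, :]) ** 2).sum(axis=2))
    best_pair, best_d = (0, 1), -1.0
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] > best_d:
                best_d, best_pair = D[i, j], (i, j)
    selected = list(best_pair)
    while len(selected) < n_select:
        best_cand, best_min = None, -1.0
        for c in range(n):
            if c in selected:
                continue
            dmin = min(D[c, s] for s in selected)
            if dmin > best_min:
                best_min, best_cand = dmin, c
        selected.append(best_cand)
    return selected
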