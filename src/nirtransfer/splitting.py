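"""Sample-set division: Kennard-Stone selection and the
calibration / transfer / validation split.

Kennard-Stone picks a space-filling calibration subset deterministically:
seed with the pair at maximum Euclidean distance in spectral space, then
repeatedly add the sample whose minimum distance to the selected set is
largest (maximin).  Ties break towards the lowest original index, making the
selection fully reproducible and nested in the selection count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .exceptions import ParameterError, TransferSetSizeWarning
from .spectra import SpectrumSet

__all__ = ["SplitAssignment", "remove_outliers", "kennard_stone", "make_split"]


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint calibration / transfer / validation index sets (0-based)."""

    calibration_idx: tuple[int, ...]
    transfer_idx: tuple[int, ...]
    validation_idx: tuple[int, ...]
    seed: int
    method_note: str = ""

    def __post_init__(self) -> None:
        sets = (
            set(self.calibration_idx),
            set(self.transfer_idx),
            set(self.validation_idx),
        )
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ParameterError("split index sets are not pairwise disjoint")

    def to_dict(self) -> dict:
        return {
            "calibration_idx": list(self.calibration_idx),
            "transfer_idx": list(self.transfer_idx),
            "validation_idx": list(self.validation_idx),
            "seed": self.seed,
            "method_note": self.method_note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitAssignment":
        return cls(
            calibration_idx=tuple(d["calibration_idx"]),
            transfer_idx=tuple(d["transfer_idx"]),
            validation_idx=tuple(d["validation_idx"]),
            seed=int(d["seed"]),
            method_note=d.get("method_note", ""),
        )


def remove_outliers(s: SpectrumSet, indices) -> SpectrumSet:
    """Drop the samples at the given 0-based indices, preserving the order of
    the rest (outlier lists are taken as given, not detected)."""
    idx = sorted(set(int(i) for i in indices))
    if idx and (idx[0] < 0 or idx[-1] >= s.n_samples):
        raise IndexError(
            f"outlier index out of range [0, {s.n_samples - 1}]: {idx}"
        )
    keep = [i for i in range(s.n_samples) if i not in set(idx)]
    return s.subset(keep)


def kennard_stone(X: SpectrumSet | np.ndarray, n_select: int) -> list[int]:
    """Classical Kennard-Stone maximin selection on raw spectra.

    Returns the selected 0-based indices in selection order; the first two
    are the maximum-distance pair.
    """
    A = X.absorbance if isinstance(X, SpectrumSet) else np.atleast_2d(np.asarray(X, float))
    n = A.shape[0]
    if not 2 <= n_select <= n:
        raise ParameterError(f"n_select={n_select} outside [2, n={n}]")
    if n <= 3000:
        D = squareform(pdist(A))
        i, j = np.unravel_index(np.argmax(D), D.shape)  # first occurrence =
        first = sorted((int(i), int(j)))                 # lowest index pair
        selected = list(first)
        min_d = np.minimum(D[selected[0]], D[selected[1]])
    else:  # memory-lean path for very large sets
        selected, min_d = _seed_pair_blocked(A)
        D = None
    min_d[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_d))  # argmax takes the first = lowest index
        selected.append(nxt)
        d_new = D[nxt] if D is not None else cdist(A[nxt : nxt + 1], A).ravel()
        min_d = np.minimum(min_d, d_new)
        min_d[nxt] = -np.inf
    return selected


def _seed_pair_blocked(A: np.ndarray):
    n = A.shape[0]
    best = (-1.0, 0, 1)
    for start in range(0, n, 512):
        block = cdist(A[start : start + 512], A)
        bi, bj = np.unravel_index(np.argmax(block), block.shape)
        if block[bi, bj] > best[0]:
            best = (float(block[bi, bj]), start + int(bi), int(bj))
    _, i, j = best
    sel = sorted((i, j))
    d0 = cdist(A[sel[0] : sel[0] + 1], A).ravel()
    d1 = cdist(A[sel[1] : sel[1] + 1], A).ravel()
    return sel, np.minimum(d0, d1)


def make_split(
    s: SpectrumSet,
    n_cal: int,
    n_transfer: int,
    n_val: int,
    seed: int,
    transfer_from: str = "prediction_pool",
) -> SplitAssignment:
    """Kennard-Stone calibration selection plus seeded random subdivision.

    ``transfer_from="prediction_pool"`` (default): KS picks the calibration
    set; the remaining samples are randomly divided into transfer and
    validation sets.  ``transfer_from="calibration"``: the transfer standards
    are instead drawn randomly from the KS calibration selection (and removed
    from it, keeping the three sets disjoint), while the validation samples
    are drawn from the remainder.
    """
    n = s.n_samples
    if transfer_from not in ("prediction_pool", "calibration"):
        raise ParameterError(
            f"transfer_from must be 'prediction_pool' or 'calibration', "
            f"got {transfer_from!r}"
        )
    if min(n_cal, n_transfer, n_val) < 1 or n_cal + n_transfer + n_val > n:
        raise ParameterError(
            f"infeasible split {n_cal}/{n_transfer}/{n_val} of {n} samples"
        )
    rng = np.random.default_rng(seed)
    if transfer_from == "prediction_pool":
        cal = kennard_stone(s, n_cal)
        pool = [i for i in range(n) if i not in set(cal)]
        perm = rng.permutation(len(pool))
        transfer = sorted(pool[k] for k in perm[:n_transfer])
        validation = sorted(pool[k] for k in perm[n_transfer : n_transfer + n_val])
    else:
        ks = kennard_stone(s, n_cal + n_transfer)
        perm = rng.permutation(len(ks))
        transfer = sorted(ks[k] for k in perm[:n_transfer])
        cal = sorted(set(ks) - set(transfer))
        pool = [i for i in range(n) if i not in set(ks)]
        validation = sorted(
            pool[k] for k in rng.permutation(len(pool))[:n_val]
        )
    if n_transfer < 10:
        warnings.warn(
            f"transfer set of {n_transfer} is below the recommended minimum of 10",
            TransferSetSizeWarning,
            stacklevel=2,
        )
    elif n_transfer < 30:
        warnings.warn(
            f"transfer set of {n_transfer} samples; 30+ recommended for "
            "quantitative use",
            TransferSetSizeWarning,
            stacklevel=2,
        )
    if n_transfer > n_cal:
        warnings.warn(
            "transfer set larger than the calibration set",
            TransferSetSizeWarning,
            stacklevel=2,
        )
    return SplitAssignment(
        calibration_idx=tuple(sorted(cal)),
        transfer_idx=tuple(transfer),
        validation_idx=tuple(validation),
        seed=seed,
        method_note=(
            f"Kennard-Stone calibration selection (Euclidean, raw absorbance), "
            f"transfer standards from {transfer_from}, random subdivision with "
            f"seed {seed}"
        ),
    )
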