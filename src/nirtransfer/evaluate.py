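"""Evaluation: RMSEP, paired t-tests, difference spectra and the nPC x nLV
grid search used to tune the score-space transfer.

RMSEP (root mean squared error of prediction, validation set) is the main
index throughout; the paired t-test compares two prediction series on the
same validation samples (p > 0.05 at CI 95% reads as "no significant
difference" between, e.g., transferred-target and source predictions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ParameterError, ShapeError
from .ipca import apply_ipca, fit_ipca
from .pls import NIPALSPLS, fit_pls, predict
from .spectra import SpectrumSet

__all__ = [
    "EvaluationReport",
    "GridSearchSurface",
    "rmsep",
    "paired_t_test",
    "difference_spectra",
    "grid_search",
    "percent_change",
]


@dataclass(frozen=True)
class EvaluationReport:
    """One scenario's validation result (references vs predictions)."""

    scenario_label: str
    references: np.ndarray
    predictions: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.references, dtype=float).ravel()
        p = np.asarray(self.predictions, dtype=float).ravel()
        if r.size != p.size or r.size == 0:
            raise ShapeError(
                f"{r.size} references vs {p.size} predictions"
            )
        object.__setattr__(self, "references", r)
        object.__setattr__(self, "predictions", p)

    @property
    def n(self) -> int:
        return self.references.size

    @property
    def rmsep(self) -> float:
        return rmsep(self.references, self.predictions)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_label,
            "n": self.n,
            "rmsep": self.rmsep,
            "unit": self.unit,
            "references": self.references.tolist(),
            "predictions": self.predictions.tolist(),
        }


@dataclass(frozen=True)
class GridSearchSurface:
    """RMSEP over an nPC x nLV grid, with the argmin cell."""

    pc_values: tuple[int, ...]
    lv_values: tuple[int, ...]
    rmsep_matrix: np.ndarray  # |pc| x |lv|
    best: tuple[int, int]

    def best_rmsep(self) -> float:
        i = self.pc_values.index(self.best[0])
        j = self.lv_values.index(self.best[1])
        return float(self.rmsep_matrix[i, j])


def rmsep(references, predictions) -> float:
    """Root mean squared prediction error, in the reference units."""
    r = np.asarray(references, dtype=float).ravel()
    p = np.asarray(predictions, dtype=float).ravel()
    if r.size != p.size:
        raise ShapeError(f"{r.size} references vs {p.size} predictions")
    if r.size == 0:
        raise ParameterError("empty prediction series")
    return float(np.sqrt(np.mean((p - r) ** 2)))


def paired_t_test(a, b, ci: float = 95.0) -> tuple[float, float]:
    """Two-sided paired t-test on the differences a - b.

    Returns ``(t, p)``.  Degenerate conventions: all differences exactly zero
    gives ``(0, 1)``; zero-variance differences with nonzero mean give
    ``(+-inf, 0)``.  ``ci`` is recorded by callers for significance labelling
    and does not change the statistic.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ShapeError(f"{a.size} vs {b.size} paired values")
    if a.size < 2:
        raise ParameterError("paired t-test needs at least 2 pairs")
    if not 0 < ci < 100:
        raise ParameterError(f"confidence level must be in (0, 100), got {ci}")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def difference_spectra(
    original: SpectrumSet, transferred: SpectrumSet
) -> SpectrumSet:
    """Per-sample difference (original - transferred) on a shared axis."""
    if original.n_wavelengths != transferred.n_wavelengths or not np.allclose(
        original.wavelengths, transferred.wavelengths
    ):
        raise ShapeError("difference spectra need identical wavelength axes")
    if original.n_samples != transferred.n_samples:
        raise ShapeError(
            f"{original.n_samples} vs {transferred.n_samples} samples"
        )
    return original.with_absorbance(
        original.absorbance - transferred.absorbance,
        instrument_label="difference",
    )


def percent_change(rmsep_ref: float, rmsep_new: float) -> float:
    """Relative RMSEP improvement in percent: 100*(ref - new)/ref."""
    if rmsep_ref == 0:
        raise ParameterError("reference RMSEP is zero; percent change undefined")
    return 100.0 * (rmsep_ref - rmsep_new) / rmsep_ref


def grid_search(
    cal_src: SpectrumSet,
    transfer_pair: tuple[SpectrumSet, SpectrumSet],
    val_target: SpectrumSet,
    pc_grid,
    lv_grid,
) -> GridSearchSurface:
    """Exhaustive RMSEP surface over transfer nPC and model nLV.

    ``transfer_pair`` is ``(transfer set on the validation spectra's
    instrument, transfer set on the calibration instrument)`` — i.e. in
    fit order (source-of-the-map, destination-of-the-map) so that
    transferred validation spectra land on ``cal_src``'s axis.  For every
    grid cell the score-space transfer is refitted with that nPC, the
    validation spectra transferred, a PLS model with that nLV fitted on
    ``cal_src``, and the RMSEP of the transferred predictions recorded.
    Ties in the argmin break towards smaller nPC, then smaller nLV.
    """
    pc_values = tuple(int(v) for v in pc_grid)
    lv_values = tuple(int(v) for v in lv_grid)
    if not pc_values or not lv_values:
        raise ParameterError("empty parameter grid")
    if val_target.references is None:
        raise ParameterError("validation spectra need reference values")
    src_t, dest_t = transfer_pair
    surface = np.empty((len(pc_values), len(lv_values)))
    models: dict[int, NIPALSPLS] = {}  # nLV -> PLS model (independent of nPC)
    for i, pc in enumerate(pc_values):
        try:
            tm = fit_ipca(src_t, dest_t, pc)
            transferred = apply_ipca(tm, val_target)
        except Exception as exc:
            raise type(exc)(f"grid cell (pc={pc}): {exc}") from exc
        for j, lv in enumerate(lv_values):
            try:
                if lv not in models:
                    models[lv] = fit_pls(cal_src, lv)
                preds = predict(models[lv], transferred)
            except Exception as exc:
                raise type(exc)(f"grid cell (pc={pc}, lv={lv}): {exc}") from exc
            surface[i, j] = rmsep(val_target.references, preds)
    lo = surface.min()
    ties = [
        (pc_values[i], lv_values[j])
        for i in range(len(pc_values))
        for j in range(len(lv_values))
        if surface[i, j] == lo
    ]
    best = min(ties)  # smaller nPC first, then smaller nLV

    return GridSearchSurface(
        pc_values=pc_values,
        lv_values=lv_values,
        rmsep_matrix=surface,
        best=best,
    )
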