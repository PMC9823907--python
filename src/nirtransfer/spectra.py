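"""Spectral data container, validation, preprocessing and flat-file I/O.

A :class:`SpectrumSet` couples one instrument's wavelength axis (nm) with an
absorbance matrix (samples x wavelengths) and, optionally, per-sample
reference values of the analyte (e.g. API mass in mg, oil %, total protein in
mg/mL).  It is the currency every other module trades in.

File dialect: delimited text, header row = wavelengths in nm, first column =
sample ID, optional final column named ``reference``.  Instrument label and
reference unit travel in a JSON sidecar (``<file>.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import FormatError, ParameterError, RangeError, ShapeError

__all__ = [
    "SpectrumSet",
    "PreprocessSpec",
    "read_spectra",
    "write_spectra",
    "apply_preprocess",
    "restrict_wavelengths",
    "resample_to_axis",
    "wavenumber_to_wavelength",
]

_PREPROCESS_METHODS = ("none", "savitzky_golay_smooth", "first_derivative", "snv")


@dataclass(frozen=True)
class SpectrumSet:
    """Spectra of one instrument: wavelength axis, absorbance matrix, references.

    Parameters
    ----------
    wavelengths : array of shape (p,)
        Strictly increasing wavelength axis in nm.
    absorbance : array of shape (n_samples, p)
        Absorbance matrix, no missing values.
    sample_ids : sequence of str
        One opaque label per sample; row order is meaningful and preserved
        by every operation in this package.
    references : array of shape (n_samples,), optional
        Analyte reference values aligned with the rows.
    reference_unit : str
        Unit of the reference values ("mg", "%", "mg/mL", ...).
    instrument_label : str
        Free-text instrument tag ("FT-NIR source", "MicroNIR target", ...).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: tuple[str, ...] = ()
    references: np.ndarray | None = None
    reference_unit: str = ""
    instrument_label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float).ravel()
        ab = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if wl.size < 2:
            raise ParameterError("a spectrum needs at least 2 wavelength points")
        diffs = np.diff(wl)
        if np.any(diffs <= 0):
            j = int(np.argmax(diffs <= 0)) + 1
            raise FormatError(
                f"wavelength axis not strictly increasing at column {j} "
                f"({wl[j - 1]:g} followed by {wl[j]:g})"
            )
        if ab.ndim != 2 or ab.shape[1] != wl.size:
            raise ShapeError(
                f"absorbance has {ab.shape[1] if ab.ndim == 2 else '?'} columns, "
                f"axis has {wl.size} wavelengths"
            )
        if ab.shape[0] < 1:
            raise ParameterError("at least one sample is required")
        if not np.all(np.isfinite(ab)):
            raise FormatError("absorbance matrix contains missing/non-finite values")
        ids = tuple(str(s) for s in self.sample_ids) or tuple(
            str(i + 1) for i in range(ab.shape[0])
        )
        if len(ids) != ab.shape[0]:
            raise ShapeError(
                f"{len(ids)} sample ids for {ab.shape[0]} spectra"
            )
        refs = self.references
        if refs is not None:
            refs = np.asarray(refs, dtype=float).ravel()
            if refs.size != ab.shape[0]:
                raise ShapeError(
                    f"{refs.size} reference values for {ab.shape[0]} samples"
                )
            refs.setflags(write=False)
        wl.setflags(write=False)
        ab.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "references", refs)

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        """Row subset in the given order (0-based indices)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_samples):
            raise IndexError(
                f"sample index out of range [0, {self.n_samples - 1}]"
            )
        return replace(
            self,
            absorbance=self.absorbance[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            references=None if self.references is None else self.references[idx],
        )

    def with_absorbance(
        self,
        absorbance: np.ndarray,
        wavelengths: np.ndarray | None = None,
        instrument_label: str | None = None,
    ) -> "SpectrumSet":
        return replace(
            self,
            absorbance=absorbance,
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            instrument_label=(
                self.instrument_label if instrument_label is None else instrument_label
            ),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectrumSet):
            return NotImplemented
        same_refs = (
            self.references is None
            and other.references is None
            or (
                self.references is not None
                and other.references is not None
                and np.array_equal(self.references, other.references)
            )
        )
        return (
            np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.absorbance, other.absorbance)
            and self.sample_ids == other.sample_ids
            and same_refs
            and self.reference_unit == other.reference_unit
            and self.instrument_label == other.instrument_label
        )


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing choice applied identically to both instruments.

    ``method`` is one of ``none`` (the default — raw absorbance),
    ``savitzky_golay_smooth`` (parameters ``window_length``, ``polyorder``),
    ``first_derivative`` (central differences along the nm axis), or ``snv``
    (standard normal variate, per-spectrum centring and scaling).
    """

    method: str = "none"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in _PREPROCESS_METHODS:
            raise ParameterError(
                f"unknown preprocessing method {self.method!r}; "
                f"choose from {_PREPROCESS_METHODS}"
            )
        if self.method == "none" and self.parameters:
            raise ParameterError('method "none" takes no parameters')


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    """Shortest text that round-trips the float64 exactly."""
    return repr(float(x))


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def read_spectra(
    path: str | Path,
    delimiter: str | None = None,
    reference_column: str = "reference",
) -> SpectrumSet:
    """Read a delimited spectral matrix.

    Header row: first cell is the sample-ID column name, then wavelengths in
    nm, then optionally ``reference_column``.  The delimiter defaults to tab
    for ``.tsv`` files and comma otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, newline="") as fh:
        rows = [line.rstrip("\n").split(delimiter) for line in fh if line.strip()]
    if len(rows) < 2:
        raise FormatError(f"{path}: need a header row and at least one sample row")
    header = rows[0]
    has_reference = header[-1].strip() == reference_column
    wl_cells = header[1 : -1 if has_reference else None]
    try:
        wl = np.array([float(c) for c in wl_cells])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength in header ({exc})") from None
    diffs = np.diff(wl)
    if wl.size >= 2 and np.any(diffs <= 0):
        j = int(np.argmax(diffs <= 0)) + 1
        raise FormatError(
            f"{path}: wavelength header not strictly increasing at column {j + 1} "
            f"(value {wl[j]:g})"
        )
    ids, data, refs = [], [], []
    width = len(header)
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != width:
            raise FormatError(
                f"{path}: row {i} has {len(row)} fields, header has {width}"
            )
        ids.append(row[0])
        body = row[1 : -1 if has_reference else None]
        try:
            data.append([float(c) for c in body])
            if has_reference:
                refs.append(float(row[-1]))
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value in row {i} ({exc})") from None
    label, unit = "", ""
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("instrument_label", "")
        unit = meta.get("reference_unit", "")
    return SpectrumSet(
        wavelengths=wl,
        absorbance=np.array(data),
        sample_ids=tuple(ids),
        references=np.array(refs) if has_reference else None,
        reference_unit=unit,
        instrument_label=label,
    )


def write_spectra(
    path: str | Path,
    s: SpectrumSet,
    delimiter: str | None = None,
    write_sidecar: bool = True,
) -> None:
    """Write ``s`` in the flat dialect; exact float round-trip via repr()."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    header = ["sample_id", *(_fmt(w) for w in s.wavelengths)]
    if s.references is not None:
        header.append("reference")
    lines = [delimiter.join(header)]
    for i in range(s.n_samples):
        row = [s.sample_ids[i], *(_fmt(v) for v in s.absorbance[i])]
        if s.references is not None:
            row.append(_fmt(s.references[i]))
        lines.append(delimiter.join(row))
    path.write_text("\n".join(lines) + "\n")
    if write_sidecar and (s.instrument_label or s.reference_unit):
        _sidecar(path).write_text(
            json.dumps(
                {
                    "instrument_label": s.instrument_label,
                    "reference_unit": s.reference_unit,
                },
                indent=2,
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# preprocessing and axis operations
# ---------------------------------------------------------------------------

def apply_preprocess(s: SpectrumSet, spec: PreprocessSpec) -> SpectrumSet:
    """Apply the chosen pretreatment; ``none`` is an exact pass-through.

    The same spec must be applied to both instruments before any transfer
    fit — the transfer algorithms themselves never centre or scale.
    """
    if spec.method == "none":
        return s
    A = s.absorbance
    if spec.method == "savitzky_golay_smooth":
        window = int(spec.parameters.get("window_length", 5))
        order = int(spec.parameters.get("polyorder", 2))
        if window > s.n_wavelengths:
            raise ParameterError(
                f"smoothing window {window} exceeds axis length {s.n_wavelengths}"
            )
        if order >= window:
            raise ParameterError("polyorder must be smaller than window_length")
        out = savgol_filter(A, window_length=window, polyorder=order, axis=1)
    elif spec.method == "first_derivative":
        # central differences on the (possibly non-uniform) nm axis; exact on
        # linear ramps, same-length output via one-sided stencils at the ends
        out = np.gradient(A, s.wavelengths, axis=1)
    elif spec.method == "snv":
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ParameterError("SNV undefined for a perfectly flat spectrum")
        out = (A - mu) / sd
    else:  # pragma: no cover - guarded by PreprocessSpec
        raise ParameterError(f"unknown method {spec.method!r}")
    return s.with_absorbance(out)


def restrict_wavelengths(s: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Keep exactly the columns with lo <= lambda <= hi (inclusive, nm)."""
    if not lo < hi:
        raise ParameterError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise RangeError(
            f"no wavelengths inside [{lo}, {hi}] nm "
            f"(axis spans {s.wavelengths[0]:g}-{s.wavelengths[-1]:g} nm)"
        )
    if mask.sum() < 2:
        raise RangeError(f"fewer than 2 wavelengths inside [{lo}, {hi}] nm")
    return s.with_absorbance(s.absorbance[:, mask], wavelengths=s.wavelengths[mask])


def resample_to_axis(s: SpectrumSet, new_axis: np.ndarray) -> SpectrumSet:
    """Linear interpolation of every sample onto ``new_axis`` (nm).

    Interpolation only — any point outside the original axis span raises
    :class:`RangeError`; extrapolated absorbance is never invented.
    """
    new_axis = np.asarray(new_axis, dtype=float).ravel()
    if new_axis.size < 2 or np.any(np.diff(new_axis) <= 0):
        raise ParameterError("new axis must be strictly increasing with >= 2 points")
    lo, hi = s.wavelengths[0], s.wavelengths[-1]
    eps = 1e-9 * max(abs(lo), abs(hi), 1.0)
    if new_axis[0] < lo - eps or new_axis[-1] > hi + eps:
        raise RangeError(
            f"requested axis [{new_axis[0]:g}, {new_axis[-1]:g}] nm extends beyond "
            f"the measured span [{lo:g}, {hi:g}] nm; extrapolation is not supported"
        )
    out = np.empty((s.n_samples, new_axis.size))
    for i in range(s.n_samples):
        out[i] = np.interp(new_axis, s.wavelengths, s.absorbance[i])
    return s.with_absorbance(out, wavelengths=new_axis)


def wavenumber_to_wavelength(axis_cm1: np.ndarray, absorbance: np.ndarray):
    """Convert a wavenumber axis (cm^-1, decreasing or increasing) to nm.

    Returns the nm axis sorted increasing together with the correspondingly
    reordered absorbance columns; lambda[nm] = 1e7 / nu[cm^-1].
    """
    axis_cm1 = np.asarray(axis_cm1, dtype=float).ravel()
    if np.any(axis_cm1 <= 0):
        raise ParameterError("wavenumbers must be positive")
    nm = 1e7 / axis_cm1
    order = np.argsort(nm)
    return nm[order], np.atleast_2d(absorbance)[:, order]
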