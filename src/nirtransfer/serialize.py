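"""JSON model containers.

All three model families (score-space transfer, PDS, PLS) serialize to a
single JSON layout with a ``method`` tag.  Floats are written through
Python's shortest-repr JSON encoder, so a save/load round trip reproduces
every array bit-for-bit.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from .exceptions import FormatError
from .ipca import IPCATransfer
from .pds import PDSTransfer
from .pls import NIPALSPLS

__all__ = ["save_model", "load_model"]


def _pkg_version() -> str:
    try:
        return version("nirtransfer")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _arr(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def save_model(model, path: str | Path) -> None:
    """Write a fitted transfer/PLS model to ``path`` as JSON."""
    if isinstance(model, IPCATransfer):
        payload = {
            "method": "ipca",
            "n_components": model.n_components_,
            "direction_label": model.direction_label,
            "transform_matrix": _arr(model.transform_matrix_),
            "loadings": _arr(model.loadings_),
            "scores": _arr(model.scores_),
            "singular_values": _arr(model.singular_values_),
            "src_basis": _arr(model._src_basis),
            "src_axis": _arr(getattr(model, "src_axis_", [])),
            "dest_axis": _arr(getattr(model, "dest_axis_", [])),
            "dest_label": getattr(model, "dest_label_", ""),
            "rcond": model.rcond,
        }
    elif isinstance(model, PDSTransfer):
        payload = {
            "method": "pds",
            "window": model.window,
            "n_components": model.n_components,
            "coefficients": [
                {"lo": lo, "hi": hi, "b": _arr(b)}
                for lo, hi, b in model.coefficients_
            ],
            "intercepts": _arr(model.intercepts_),
            "src_axis": _arr(getattr(model, "src_axis_", [])),
            "dest_axis": _arr(getattr(model, "dest_axis_", [])),
            "dest_label": getattr(model, "dest_label_", ""),
        }
    elif isinstance(model, NIPALSPLS):
        payload = {
            "method": "pls1-nipals",
            "n_components": model.n_components_,
            "x_mean": _arr(model.x_mean_),
            "y_mean": model.y_mean_,
            "coef": _arr(model.coef_),
            "axis": _arr(getattr(model, "axis_", [])),
            "reference_unit": getattr(model, "reference_unit_", ""),
            "training_meta": getattr(model, "training_meta_", {}),
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    payload["library_version"] = _pkg_version()
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_model(path: str | Path):
    """Reconstruct a model saved by :func:`save_model`."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read model file {path}: {exc}") from None
    method = payload.get("method")
    if method == "ipca":
        m = IPCATransfer(
            n_components=int(payload["n_components"]),
            rcond=float(payload.get("rcond", 1e-12)),
            direction_label=payload.get("direction_label", ""),
        )
        m.transform_matrix_ = np.asarray(payload["transform_matrix"])
        m.loadings_ = np.asarray(payload["loadings"])
        m.scores_ = np.asarray(payload["scores"])
        m.singular_values_ = np.asarray(payload["singular_values"])
        m._src_basis = np.asarray(payload["src_basis"])
        m.residual_ = None  # noise part is not persisted
        m.n_components_ = int(payload["n_components"])
        m.n_features_in_ = m.transform_matrix_.shape[0]
        m.src_axis_ = np.asarray(payload["src_axis"])
        m.dest_axis_ = np.asarray(payload["dest_axis"])
        m.dest_label_ = payload.get("dest_label", "")
        return m
    if method == "pds":
        m = PDSTransfer(
            window=int(payload["window"]),
            n_components=int(payload["n_components"]),
        )
        m.coefficients_ = [
            (int(c["lo"]), int(c["hi"]), np.asarray(c["b"]))
            for c in payload["coefficients"]
        ]
        m.intercepts_ = np.asarray(payload["intercepts"])
        m.n_features_in_ = m.intercepts_.size
        m.src_axis_ = np.asarray(payload["src_axis"])
        m.dest_axis_ = np.asarray(payload["dest_axis"])
        m.dest_label_ = payload.get("dest_label", "")
        return m
    if method == "pls1-nipals":
        m = NIPALSPLS(n_components=int(payload["n_components"]))
        m.x_mean_ = np.asarray(payload["x_mean"])
        m.y_mean_ = float(payload["y_mean"])
        m.coef_ = np.asarray(payload["coef"])
        m.n_components_ = int(payload["n_components"])
        m.n_features_in_ = m.coef_.size
        m.axis_ = np.asarray(payload["axis"])
        m.reference_unit_ = payload.get("reference_unit", "")
        m.training_meta_ = payload.get("training_meta", {})
        return m
    raise FormatError(f"{path}: unknown model method tag {method!r}")
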