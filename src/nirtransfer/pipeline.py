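"""End-to-end transfer study: simulate/load -> split -> fit transfer ->
transfer -> model -> evaluate.

The three reported scenarios mirror standard calibration-transfer practice:

* ``source_on_source`` — the source model predicting its own validation
  spectra (the accuracy ceiling);
* ``target_raw`` — the untransferred target validation spectra pushed
  through a source model (what you lose by ignoring the instrument change);
* ``target_transferred`` — the target validation spectra mapped into the
  source space first.

When the two instruments' grids differ, the raw-target scenario (and PDS,
which requires equal grids) runs on the overlap of the two axes: the source
spectra are restricted to the overlap, a source model is refitted there,
and the target spectra are linearly resampled onto that restricted axis.
The score-space transfer needs none of this and always uses the full source
model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .evaluate import EvaluationReport, paired_t_test, percent_change
from .exceptions import ParameterError
from .ipca import apply_ipca, fit_ipca
from .pds import apply_pds, fit_pds
from .pls import fit_pls, loo_select_nlv, predict
from .serialize import save_model
from .simulate import SimulationConfig, generate_transfer_task
from .spectra import (
    PreprocessSpec,
    SpectrumSet,
    apply_preprocess,
    read_spectra,
    resample_to_axis,
    restrict_wavelengths,
    write_spectra,
)
from .splitting import make_split

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run depends on (hashable to a run id).

    Either ``source_path``/``target_path`` point at spectral matrix files
    (the source file must carry a ``reference`` column), or ``simulation``
    supplies a :class:`SimulationConfig`; exactly one input mode is allowed.
    """

    source_path: str | None = None
    target_path: str | None = None
    simulation: SimulationConfig | None = None
    method: str = "ipca"  # "ipca" | "pds"
    n_pc: int = 5
    window: int = 17
    n_lv_transfer: int = 2  # latent variables inside PDS windows
    n_lv_model: int | None = None  # None -> leave-one-out selection
    max_lv: int = 10
    n_cal: int = 90
    n_transfer: int = 30
    n_val: int = 42
    split_seed: int = 0
    transfer_from: str = "prediction_pool"
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("ipca", "pds"):
            raise ParameterError(f"method must be 'ipca' or 'pds', got {self.method!r}")
        file_mode = self.source_path is not None and self.target_path is not None
        if file_mode == (self.simulation is not None):
            raise ParameterError(
                "provide either source_path+target_path or a simulation config"
            )

    def hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)

        doc = dataclasses.asdict(self)
        doc.pop("output_dir")  # the run's identity is its science, not its paths
        blob = json.dumps(doc, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _overlap_views(source: SpectrumSet, target: SpectrumSet):
    """Source restricted to the axis overlap + target resampled onto it."""
    lo = max(source.wavelengths[0], target.wavelengths[0])
    hi = min(source.wavelengths[-1], target.wavelengths[-1])
    if not lo < hi:
        raise ParameterError("instrument axes do not overlap")
    src_o = restrict_wavelengths(source, lo, hi)
    tgt_o = resample_to_axis(target, src_o.wavelengths)
    return src_o, tgt_o


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study and return the report bundle.

    Returns a dict with per-scenario :class:`EvaluationReport`s, the paired
    t-test between transferred-target and source predictions, the percent
    RMSEP change of transfer vs raw, the split, the fitted models and the
    config hash.  If ``config.output_dir`` is set, reports, models,
    transferred spectra and a manifest are written there.
    """
    if config.simulation is not None:
        task = generate_transfer_task(
            config.simulation,
            n_cal=config.n_cal,
            n_transfer=config.n_transfer,
            n_val=config.n_val,
            split_seed=config.split_seed,
            transfer_from=config.transfer_from,
        )
        source, target, split = task.source, task.target, task.split
    else:
        source = read_spectra(config.source_path)
        target = read_spectra(config.target_path)
        if source.references is None:
            raise ParameterError("source file needs a reference column")
        split = make_split(
            source,
            n_cal=config.n_cal,
            n_transfer=config.n_transfer,
            n_val=config.n_val,
            seed=config.split_seed,
            transfer_from=config.transfer_from,
        )
    source = apply_preprocess(source, config.preprocess)
    target = apply_preprocess(target, config.preprocess)
    if target.references is None:
        target = dataclasses.replace(
            target,
            references=source.references,
            reference_unit=source.reference_unit,
        )

    cal_s = source.subset(split.calibration_idx)
    tr_s = source.subset(split.transfer_idx)
    val_s = source.subset(split.validation_idx)
    tr_t = target.subset(split.transfer_idx)
    val_t = target.subset(split.validation_idx)

    if config.n_lv_model is None:
        max_lv = min(config.max_lv, cal_s.n_samples - 2, cal_s.n_wavelengths)
        n_lv_model, rmsecv = loo_select_nlv(cal_s, max_lv)
    else:
        n_lv_model, rmsecv = config.n_lv_model, None
    src_model = fit_pls(cal_s, n_lv_model)

    # overlap-axis views for the raw-target scenario (and for PDS)
    src_o, tgt_o = _overlap_views(source, target)
    cal_so = src_o.subset(split.calibration_idx)
    val_to = tgt_o.subset(split.validation_idx)
    overlap_model = fit_pls(cal_so, n_lv_model)

    unit = source.reference_unit
    reports = {
        "source_on_source": EvaluationReport(
            "source model on source validation spectra",
            val_s.references,
            predict(src_model, val_s),
            unit,
        ),
        "target_raw": EvaluationReport(
            "overlap-axis source model on untransferred (resampled) target",
            val_to.references,
            predict(overlap_model, val_to),
            unit,
        ),
    }

    if config.method == "ipca":
        transfer_model = fit_ipca(tr_t, tr_s, config.n_pc)
        transferred = apply_ipca(transfer_model, val_t)
        eval_model = src_model
        scenario = "source model on score-space-transferred target"
    else:
        tr_to = tgt_o.subset(split.transfer_idx)
        tr_so = src_o.subset(split.transfer_idx)
        transfer_model = fit_pds(tr_to, tr_so, config.window, config.n_lv_transfer)
        transferred = apply_pds(transfer_model, val_to)
        eval_model = overlap_model
        scenario = "overlap-axis source model on PDS-transferred target"
    reports["target_transferred"] = EvaluationReport(
        scenario, transferred.references, predict(eval_model, transferred), unit
    )

    t_stat, p_val = paired_t_test(
        reports["target_transferred"].predictions,
        reports["source_on_source"].predictions,
    )
    bundle = {
        "config_hash": config.hash(),
        "method": config.method,
        "n_lv_model": n_lv_model,
        "rmsecv": None if rmsecv is None else rmsecv.tolist(),
        "reports": reports,
        "split": split,
        "transfer_model": transfer_model,
        "source_model": src_model,
        "transferred_validation": transferred,
        "t_statistic": t_stat,
        "p_value": p_val,
        "improvement_pct": percent_change(
            reports["target_raw"].rmsep, reports["target_transferred"].rmsep
        ),
    }
    if config.output_dir is not None:
        _write_outputs(Path(config.output_dir), config, bundle)
    return bundle


def _write_outputs(outdir: Path, config: RunConfig, bundle: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = bundle["config_hash"]
    written: list[str] = []

    def emit(name: str, text: str) -> None:
        (outdir / name).write_text(text)
        written.append(name)

    report_doc = {
        "config_hash": h,
        "method": bundle["method"],
        "n_lv_model": bundle["n_lv_model"],
        "rmsecv": bundle["rmsecv"],
        "t_statistic": bundle["t_statistic"],
        "p_value": bundle["p_value"],
        "improvement_pct": bundle["improvement_pct"],
        "scenarios": {k: r.to_dict() for k, r in bundle["reports"].items()},
        "split": bundle["split"].to_dict(),
    }
    emit("reports.json", json.dumps(report_doc, indent=1) + "\n")
    rows = ["scenario,n,rmsep,t,p"]
    for key, r in bundle["reports"].items():
        t = bundle["t_statistic"] if key == "target_transferred" else ""
        p = bundle["p_value"] if key == "target_transferred" else ""
        rows.append(f"{key},{r.n},{r.rmsep!r},{t},{p}")
    emit("summary.csv", "\n".join(rows) + "\n")
    save_model(bundle["transfer_model"], outdir / "transfer_model.json")
    written.append("transfer_model.json")
    save_model(bundle["source_model"], outdir / "source_model.json")
    written.append("source_model.json")
    write_spectra(outdir / "transferred_validation.csv", bundle["transferred_validation"])
    written.append("transferred_validation.csv")
    emit(
        "manifest.json",
        json.dumps(
            {"config_hash": h, "files": sorted(written)}, indent=1
        )
        + "\n",
    )
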