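import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nirtransfer as nt

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240406)


@pytest.fixture
def small_set():
    """3 samples x 4 wavelengths with reference values."""
    return nt.SpectrumSet(
        wavelengths=np.array([1000.0, 1100.0, 1250.0, 1400.0]),
        absorbance=np.array(
            [
                [0.11, 0.23, 0.31, 0.18],
                [0.14, 0.29, 0.35, 0.22],
                [0.09, 0.20, 0.27, 0.15],
            ]
        ),
        sample_ids=("a", "b", "c"),
        references=np.array([1.2, 1.8, 0.9]),
        reference_unit="mg",
        instrument_label="bench",
    )


@pytest.fixture(scope="session")
def default_task():
    """The default paired-instrument campaign (162 samples, 90/30/42)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", nt.TransferSetSizeWarning)
        return nt.generate_transfer_task(nt.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def task_subsets(default_task):
    t = default_task
    return {
        "cal_s": t.source.subset(t.split.calibration_idx),
        "tr_s": t.source.subset(t.split.transfer_idx),
        "val_s": t.source.subset(t.split.validation_idx),
        "cal_t": t.target.subset(t.split.calibration_idx),
        "tr_t": t.target.subset(t.split.transfer_idx),
        "val_t": t.target.subset(t.split.validation_idx),
    }
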