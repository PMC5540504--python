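import numpy as np
import pytest

from lysetrack import (
    Chromatogram,
    ChromatogramSet,
    RegionOfInterest,
    SampleMeta,
    SimConfig,
)


@pytest.fixture
def clean_config() -> SimConfig:
    """Disturbance-free simulator: no noise, no drift, no retention jitter."""
    return SimConfig(noise_sd=0.0, baseline_drift=0.0, shift_jitter_max=0)


@pytest.fixture
def default_rois() -> tuple[RegionOfInterest, RegionOfInterest]:
    return RegionOfInterest("FT", 20.0, 130.0), RegionOfInterest("EL", 150.0, 300.0)


def make_trace(values, sample_id="s", dt=0.2, **meta) -> Chromatogram:
    values = np.asarray(values, dtype=float)
    return Chromatogram(
        meta=SampleMeta(sample_id=sample_id, **meta),
        time_s=np.arange(values.size) * dt,
        absorbance_mau=values,
    )


def make_set(rows, dt=0.2, cycles=None) -> ChromatogramSet:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    cycles = cycles if cycles is not None else range(rows.shape[0])
    return ChromatogramSet(
        [
            make_trace(row, sample_id=f"s{i}", dt=dt, cycle=int(c))
            for i, (row, c) in enumerate(zip(rows, cycles))
        ]
    )
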