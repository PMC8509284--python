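import numpy as np
import pytest

from renalqmri import phantom as ph
from renalqmri import synthesis as syn


@pytest.fixture(scope="session")
def control_params() -> ph.TissueParameterSet:
    """Healthy-kidney tissue parameters (no dispersion calibration needed)."""
    return ph.TissueParameterSet(
        group="control",
        timepoint="none",
        t1_ms={1: 1304.0, 2: 1283.0, 3: 1808.0},
        t2_ms={1: 44.0, 2: 42.0, 3: 54.0},
        adc_um2_per_ms={1: 1.61, 2: 1.72, 3: 1.72},
    )


@pytest.fixture(scope="session")
def label_map_128() -> np.ndarray:
    return ph.make_label_map((128, 128))


def flat_series(kind: str, truth: float, n_vox: int, snr: float = np.inf, seed: int = 0,
                protocol: syn.Protocol | None = None) -> syn.AcquisitionSeries:
    """A series of identical voxels with one true parameter value."""
    protocol = protocol or syn.Protocol()
    if kind == "IR_T1":
        axis = np.asarray(protocol.ti_ms)
        clean = syn.signal_ir(truth, axis, protocol.tr_ms, protocol.s0_scale, protocol.inv_eff)
        tr = protocol.tr_ms
    elif kind == "ME_T2":
        axis = np.asarray(protocol.te_ms)
        clean = syn.signal_t2(truth, axis, protocol.s0_scale)
        tr = None
    else:
        axis = np.asarray(protocol.b_s_per_mm2)
        clean = syn.signal_dwi(truth * 1e-3, axis, protocol.s0_scale)
        tr = None
    data = np.tile(clean, (n_vox, 1)).reshape(n_vox, 1, 1, axis.size)
    series = syn.AcquisitionSeries(
        kind=kind, data=data, param_axis=axis, tr_ms=tr,
        s0_scale=protocol.s0_scale, snr=snr, seed=seed,
    )
    if np.isfinite(snr):
        series = syn.add_rician_noise(series, snr, seed)
    return series
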