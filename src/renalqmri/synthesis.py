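"""Forward simulation of the three MRI acquisitions from a phantom.

Three magnitude-image series are produced per subject, mirroring a typical
small-animal renal protocol at 7 T:

* inversion recovery with 13 inversion times (30-8000 ms, TR 18 s) for T1,
* a 7-echo spin-echo train (TE 11-77 ms) for T2,
* diffusion weighting over 7 b-values (0-800 s/mm^2) for the ADC.

Signals follow the ideal closed forms; magnitude noise is Rician, i.e. the
modulus of the clean signal plus complex Gaussian channel noise with
per-channel standard deviation sigma = S0 / SNR.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .phantom import PhantomImage

__all__ = [
    "Protocol",
    "AcquisitionSeries",
    "signal_ir",
    "signal_t2",
    "signal_dwi",
    "add_rician_noise",
    "synthesize_subject",
]

#: the 13 inversion times (ms) of the default IR protocol
DEFAULT_TI_MS = (30.0, 100.0, 200.0, 300.0, 500.0, 700.0, 1000.0, 1200.0, 1500.0, 2000.0, 3000.0, 5000.0, 8000.0)
#: the 7 echo times (ms): arithmetic progression 11..77
DEFAULT_TE_MS = (11.0, 22.0, 33.0, 44.0, 55.0, 66.0, 77.0)
#: the 7 diffusion weightings (s/mm^2) spanning 0-800
DEFAULT_B_S_PER_MM2 = (0.0, 100.0, 200.0, 300.0, 400.0, 600.0, 800.0)


@dataclass(frozen=True)
class Protocol:
    """Acquisition parameters shared by a simulated study."""

    ti_ms: tuple[float, ...] = DEFAULT_TI_MS
    te_ms: tuple[float, ...] = DEFAULT_TE_MS
    b_s_per_mm2: tuple[float, ...] = DEFAULT_B_S_PER_MM2
    tr_ms: float = 18000.0
    inv_eff: float = 1.0
    snr: float = 40.0
    s0_scale: float = 1000.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AcquisitionSeries:
    """A 4D magnitude image stack plus its acquisition-parameter axis.

    ``data`` has shape (x, y, slice, n_meas) with a slice axis of length 1
    for the single-slice protocol; ``param_axis`` holds the TI, TE or
    b-value of each measurement and must be strictly increasing.
    """

    kind: str  # "IR_T1" | "ME_T2" | "DWI"
    data: np.ndarray
    param_axis: np.ndarray
    tr_ms: float | None
    s0_scale: float
    snr: float
    seed: int | None = None
    inv_eff: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("IR_T1", "ME_T2", "DWI"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        self.data = np.asarray(self.data, dtype=float)
        self.param_axis = np.asarray(self.param_axis, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, slice, n_meas), got shape {self.data.shape}")
        if self.data.shape[-1] != self.param_axis.size:
            raise ValueError("length of param_axis must match the measurement axis")
        if np.any(np.diff(self.param_axis) <= 0):
            raise ValueError("param_axis must be strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def n_meas(self) -> int:
        return int(self.param_axis.size)


def signal_ir(t1_ms, ti_ms, tr_ms=18000.0, m0=1.0, inv_eff=1.0):
    """Magnitude inversion-recovery signal.

    |m0 * (1 - (1 + inv_eff) * exp(-TI/T1) + exp(-TR/T1))| — longitudinal
    recovery after a (possibly imperfect) inversion, with the finite-TR
    term retained.  Arguments broadcast.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be strictly positive")
    if not 0 < inv_eff <= 1:
        raise ValueError("inversion efficiency must lie in (0, 1]")
    ti = np.asarray(ti_ms, dtype=float)
    mz = 1.0 - (1.0 + inv_eff) * np.exp(-ti / t1) + np.exp(-tr_ms / t1)
    return np.abs(np.asarray(m0) * mz)


def signal_t2(t2_ms, te_ms, m0=1.0):
    """Mono-exponential spin-echo decay m0 * exp(-TE/T2), no offset term."""
    t2 = np.asarray(t2_ms, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be strictly positive")
    return np.asarray(m0) * np.exp(-np.asarray(te_ms, dtype=float) / t2)


def signal_dwi(adc_mm2_per_s, b_s_per_mm2, s0=1.0):
    """Mono-exponential diffusion decay s0 * exp(-b * ADC).

    ``adc_mm2_per_s`` is in mm^2/s so that b * ADC is dimensionless
    (a typical renal ADC of 1.7e-3 mm^2/s at b = 800 gives exp(-1.36)).
    """
    adc = np.asarray(adc_mm2_per_s, dtype=float)
    if np.any(adc < 0):
        raise ValueError("ADC must be non-negative")
    return np.asarray(s0) * np.exp(-np.asarray(b_s_per_mm2, dtype=float) * adc)


def add_rician_noise(
    series: AcquisitionSeries,
    snr: float | None = None,
    seed: int | np.random.Generator | None = 0,
) -> AcquisitionSeries:
    """Replace each voxel s by sqrt((s + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2).

    sigma = s0_scale / SNR.  An infinite SNR returns the input unchanged
    (apart from a copy).  Reproducible for a given integer seed.
    """
    snr = series.snr if snr is None else snr
    if snr <= 0:
        raise ValueError("SNR must be positive")
    if np.isinf(snr):
        return dataclasses.replace(series, data=series.data.copy(), snr=snr)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = series.s0_scale / snr
    n1 = rng.normal(0.0, sigma, size=series.data.shape)
    n2 = rng.normal(0.0, sigma, size=series.data.shape)
    noisy = np.sqrt((series.data + n1) ** 2 + n2**2)
    new_seed = int(seed) if isinstance(seed, (int, np.integer)) else series.seed
    return dataclasses.replace(series, data=noisy, snr=snr, seed=new_seed)


def _clean_stack(truth: np.ndarray, tissue: np.ndarray, model, axis_vals: np.ndarray) -> np.ndarray:
    """Evaluate a signal model voxel-wise over tissue; background stays zero."""
    nx, ny = truth.shape
    out = np.zeros((nx, ny, 1, axis_vals.size), dtype=float)
    vals = truth[tissue]
    out[tissue, 0, :] = model(vals[:, None], axis_vals[None, :])
    return out


def synthesize_subject(
    phantom: PhantomImage,
    protocol: Protocol | None = None,
    seed: int = 0,
) -> dict[str, AcquisitionSeries]:
    """Simulate the three acquisitions of one subject.

    Returns ``{"t1": IR series, "t2": multi-echo series, "dwi": DWI
    series}``.  Noise streams for the three series are drawn from
    independent children of ``seed`` so that, e.g., changing the DWI
    protocol leaves the IR noise untouched.
    """
    protocol = protocol or Protocol()
    tissue = phantom.tissue_mask
    m0 = protocol.s0_scale

    ti = np.asarray(protocol.ti_ms, dtype=float)
    te = np.asarray(protocol.te_ms, dtype=float)
    b = np.asarray(protocol.b_s_per_mm2, dtype=float)

    clean = {
        "t1": _clean_stack(
            phantom.truth_t1, tissue,
            lambda v, x: signal_ir(v, x, tr_ms=protocol.tr_ms, m0=m0, inv_eff=protocol.inv_eff), ti,
        ),
        "t2": _clean_stack(phantom.truth_t2, tissue, lambda v, x: signal_t2(v, x, m0=m0), te),
        "dwi": _clean_stack(
            phantom.truth_adc, tissue, lambda v, x: signal_dwi(v * 1e-3, x, s0=m0), b,
        ),
    }

    kinds = {"t1": ("IR_T1", ti, protocol.tr_ms), "t2": ("ME_T2", te, None), "dwi": ("DWI", b, None)}
    children = np.random.SeedSequence(seed).spawn(3)
    out = {}
    for child, (name, (kind, axis, tr)) in zip(children, kinds.items()):
        series = AcquisitionSeries(
            kind=kind,
            data=clean[name],
            param_axis=axis,
            tr_ms=tr,
            s0_scale=protocol.s0_scale,
            snr=protocol.snr,
            seed=seed,
            inv_eff=protocol.inv_eff,
        )
        out[name] = add_rician_noise(series, protocol.snr, np.random.default_rng(child))
    return out
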