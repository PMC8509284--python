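"""Cohort tissue-parameter presets and dispersion calibration.

The preset compartment values are the group means of a 7 T mouse renal
transplant study: T1/T2 per anatomical layer and ADC for cortex and outer
medulla, for healthy controls, isogenic grafts (no rejection) and
allogenic grafts (chronic rejection) at weeks 3 and 6 after surgery.  The
two medullary stripes share the OM ADC value since diffusion maps cannot
separate them.

Dispersion calibration
----------------------
The published whole-kidney ADC histogram descriptors (SD, IQR) describe
*measured* maps, which carry a predictable fit-noise floor on top of the
true tissue dispersion.  Presets therefore store the measured-domain
targets, and :func:`tissue_parameters` deconvolves them with the
delta-method noise floor of the ADC estimator for the protocol in use
(:func:`~renalqmri.relaxometry.predict_adc_fit_sd`) before choosing
generator parameters:

* isogenic grafts get a smooth within-compartment texture whose SD tops up
  the between-compartment spread to the deconvolved target;
* allogenic grafts get the patchy two-class mixture with (delta, sigma)
  chosen jointly so the measured maps match both the target SD and the
  target IQR (see :func:`~renalqmri.phantom.calibrate_mixture`).
"""

from __future__ import annotations

import numpy as np

from .phantom import (
    CORTEX,
    ISOM,
    OSOM,
    EllipseGeometry,
    Heterogeneity,
    TissueParameterSet,
    calibrate_mixture,
    make_label_map,
)
from .relaxometry import predict_adc_fit_sd
from .synthesis import Protocol

__all__ = ["COMPARTMENT_VALUES", "DISPERSION_TARGETS", "tissue_parameters", "available_presets"]

# group-mean compartment values: T1/T2 in ms, ADC in 1e-3 mm^2/s
# (cortex, OSOM, ISOM); ADC OSOM/ISOM both take the OM value
COMPARTMENT_VALUES: dict[tuple[str, str], dict] = {
    ("control", "none"): {
        "t1": (1304.0, 1283.0, 1808.0),
        "t2": (44.0, 42.0, 54.0),
        "adc": (1.61, 1.72),
    },
    ("isogenic", "w3"): {
        "t1": (1457.0, 1466.0, 1904.0),
        "t2": (48.0, 48.0, 58.0),
        "adc": (1.29, 1.43),
    },
    ("isogenic", "w6"): {
        "t1": (1393.0, 1399.0, 1859.0),
        "t2": (45.0, 44.0, 55.0),
        "adc": (1.40, 1.56),
    },
    ("allogenic", "w3"): {
        "t1": (1965.0, 2134.0, 2282.0),
        "t2": (48.0, 57.0, 54.0),
        "adc": (1.47, 1.47),
    },
    ("allogenic", "w6"): {
        "t1": (1899.0, 2036.0, 2031.0),
        "t2": (44.0, 51.0, 50.0),
        "adc": (1.44, 1.27),
    },
}

#: measured-map whole-kidney ADC dispersion targets (SD, IQR), 1e-3 mm^2/s
DISPERSION_TARGETS: dict[tuple[str, str], tuple[float, float]] = {
    ("isogenic", "w3"): (0.13, 0.17),
    ("isogenic", "w6"): (0.15, 0.12),
    ("allogenic", "w3"): (0.33, 0.45),
    ("allogenic", "w6"): (0.32, 0.43),
}


def available_presets() -> list[tuple[str, str]]:
    return sorted(COMPARTMENT_VALUES)


def _label_weights(label_map: np.ndarray) -> dict[int, float]:
    tissue = label_map > 0
    total = tissue.sum()
    return {c: float((label_map == c).sum()) / total for c in (CORTEX, OSOM, ISOM)}


def _between_compartment_var(adc: dict[int, float], weights: dict[int, float]) -> float:
    m = sum(weights[c] * adc[c] for c in weights)
    return sum(weights[c] * (adc[c] - m) ** 2 for c in weights)


def tissue_parameters(
    group: str,
    timepoint: str = "none",
    protocol: Protocol | None = None,
    label_map: np.ndarray | None = None,
    geometry: EllipseGeometry | None = None,
    patch_scale_vox: float = 4.0,
) -> TissueParameterSet:
    """Build a calibrated :class:`TissueParameterSet` for a study group.

    ``protocol`` (default study protocol if omitted) fixes the ADC
    fit-noise floor used in the dispersion deconvolution; ``label_map``
    (or ``geometry``, rendered at 128x128) fixes the compartment voxel
    weights that set the between-compartment ADC spread.
    """
    key = (group, timepoint)
    if key not in COMPARTMENT_VALUES:
        raise KeyError(f"no preset for {key}; available: {available_presets()}")
    vals = COMPARTMENT_VALUES[key]
    t1 = dict(zip((CORTEX, OSOM, ISOM), vals["t1"]))
    t2 = dict(zip((CORTEX, OSOM, ISOM), vals["t2"]))
    adc_cortex, adc_om = vals["adc"]
    adc = {CORTEX: adc_cortex, OSOM: adc_om, ISOM: adc_om}

    params = TissueParameterSet(
        group=group, timepoint=timepoint, t1_ms=t1, t2_ms=t2, adc_um2_per_ms=adc,
    )

    targets = DISPERSION_TARGETS.get(key)
    if targets is None:
        params.validate()
        return params

    protocol = protocol or Protocol()
    if label_map is None:
        label_map = make_label_map((128, 128), geometry)
    weights = _label_weights(label_map)
    mean_adc = sum(weights[c] * adc[c] for c in weights)
    floor = predict_adc_fit_sd(mean_adc, protocol.b_s_per_mm2, protocol.snr)
    target_sd, target_iqr = targets
    truth_var = target_sd**2 - floor**2
    if truth_var <= 0:
        raise ValueError(
            f"target SD {target_sd} is below the fit-noise floor {floor:.3f} "
            "for this protocol; lower the noise or the floor"
        )

    between_var = _between_compartment_var(adc, weights)
    if group == "isogenic":
        texture_var = max(truth_var - between_var, 0.0)
        params.adc_texture_sd = float(np.sqrt(texture_var))
    else:  # allogenic: patchy mixture, calibrated jointly to SD and IQR
        # work in the measured domain, then strip the noise floor from the
        # within-class width; the class offset delta is noise-free
        avail_var = max(truth_var - between_var, 1e-12)
        delta, sigma_meas = calibrate_mixture(
            float(np.sqrt(avail_var + floor**2)), target_iqr
        )
        sigma_true = float(np.sqrt(max(sigma_meas**2 - floor**2, 1e-12)))
        params.heterogeneity = Heterogeneity(
            enabled=True,
            adc_delta=float(delta),
            within_patch_sd=sigma_true,
            patch_scale_vox=patch_scale_vox,
        )
    params.validate()
    return params
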