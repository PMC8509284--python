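"""Digital kidney phantoms for quantitative renal MRI simulation.

A phantom is a 2D coronal slice through an idealized kidney built from
concentric elliptical bands: the cortex on the outside, the outer stripe
of the outer medulla (OSOM) beneath it, and the inner stripe (ISOM) at the
core.  Each compartment carries ground-truth T1, T2 and ADC values; the
allograft (rejection) phantom additionally overlays a two-class patchy ADC
mixture that emulates the side-by-side regions of high and low diffusivity
seen in chronically rejecting grafts, and transplant phantoms may carry a
smooth within-compartment ADC texture representing ordinary biological
heterogeneity.

Compartment means and histogram metrics depend only on voxel populations,
not on the silhouette, so the elliptical geometry exercises ROI statistics
and cortico-medullary differences exactly as a realistic outline would.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy import stats as _stats

__all__ = [
    "BACKGROUND",
    "CORTEX",
    "OSOM",
    "ISOM",
    "REGIONS",
    "EllipseGeometry",
    "Heterogeneity",
    "TissueParameterSet",
    "PhantomImage",
    "make_label_map",
    "make_heterogeneity_field",
    "make_texture_field",
    "make_phantom",
    "region_mask",
    "mixture_sd",
    "mixture_quantile",
    "mixture_iqr",
    "calibrate_adc_delta",
    "calibrate_mixture",
]

# integer compartment codes of the label map
BACKGROUND, CORTEX, OSOM, ISOM = 0, 1, 2, 3

#: canonical regions; OM and whole kidney are composites of the base codes
REGIONS: dict[str, tuple[int, ...]] = {
    "cortex": (CORTEX,),
    "osom": (OSOM,),
    "isom": (ISOM,),
    "om": (OSOM, ISOM),
    "whole_kidney": (CORTEX, OSOM, ISOM),
}

# minimum physically sensible ADC after heterogeneity, 1e-3 mm^2/s
_ADC_FLOOR = 0.1


@dataclass(frozen=True)
class EllipseGeometry:
    """Concentric elliptical band layout of the kidney slice.

    ``semi_axes_frac`` are the outer-ellipse semi-axes as fractions of the
    half grid size (long axis along x).  The two border fractions are the
    normalized elliptical radii of the cortex/OSOM and OSOM/ISOM borders;
    the band between a border and the next one inward belongs to the outer
    compartment, so cortex occupies (osom_outer, 1], OSOM
    (isom_outer, osom_outer] and ISOM [0, isom_outer].
    """

    semi_axes_frac: tuple[float, float] = (0.81, 0.47)
    osom_outer_frac: float = 0.72
    isom_outer_frac: float = 0.45

    def validate(self) -> None:
        a, b = self.semi_axes_frac
        if not (0 < a <= 1 and 0 < b <= 1):
            raise ValueError(f"semi-axis fractions must lie in (0, 1], got {self.semi_axes_frac}")
        if not (0 < self.isom_outer_frac < self.osom_outer_frac < 1):
            raise ValueError(
                "degenerate geometry: band borders must satisfy "
                f"0 < isom_outer ({self.isom_outer_frac}) < osom_outer "
                f"({self.osom_outer_frac}) < 1 so every band has positive width"
            )


@dataclass
class Heterogeneity:
    """Patchy two-class mixture settings for the allograft ADC field.

    Tissue voxels are split into two spatially coherent classes (expected
    weight 1/2 each) whose ADC means sit at base ± ``adc_delta``; within a
    class voxels vary with standard deviation ``within_patch_sd``.  Both in
    1e-3 mm^2/s.  ``patch_scale_vox`` is the Gaussian correlation length of
    the underlying random field, in voxels.  ``t1_delta_ms``/``t2_delta_ms``
    optionally apply the same patch pattern to the relaxation times.
    """

    enabled: bool = False
    adc_delta: float = 0.0
    within_patch_sd: float = 0.0
    patch_scale_vox: float = 4.0
    t1_delta_ms: float = 0.0
    t2_delta_ms: float = 0.0


@dataclass
class TissueParameterSet:
    """Ground-truth tissue parameters for one subject group.

    Per-compartment values are keyed by compartment code (1 cortex, 2 OSOM,
    3 ISOM).  T1/T2 in ms, ADC in 1e-3 mm^2/s.  ``adc_texture_sd`` adds a
    smooth, zero-mean within-compartment ADC variation (any group);
    ``heterogeneity`` is the rejection-specific patch mixture and may only
    be enabled for the allogenic group.
    """

    group: str
    timepoint: str
    t1_ms: dict[int, float]
    t2_ms: dict[int, float]
    adc_um2_per_ms: dict[int, float]
    adc_texture_sd: float = 0.0
    texture_scale_vox: float = 2.0
    heterogeneity: Heterogeneity = field(default_factory=Heterogeneity)

    def validate(self) -> None:
        if self.group not in ("control", "isogenic", "allogenic"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.timepoint not in ("w3", "w6", "none"):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        for code in (CORTEX, OSOM, ISOM):
            t1, t2 = self.t1_ms[code], self.t2_ms[code]
            adc = self.adc_um2_per_ms[code]
            if t1 <= 0 or t2 <= 0 or adc <= 0:
                raise ValueError(f"tissue parameters must be strictly positive (compartment {code})")
            if t1 <= t2:
                raise ValueError(f"T1 ({t1}) must exceed T2 ({t2}) in compartment {code}")
        if self.heterogeneity.adc_delta < 0:
            raise ValueError("adc_delta must be non-negative")
        if self.heterogeneity.enabled and self.group != "allogenic":
            raise ValueError("patchy heterogeneity is modelled for the allogenic group only")
        if self.adc_texture_sd < 0:
            raise ValueError("adc_texture_sd must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PhantomImage:
    """A label map plus ground-truth parameter grids for one subject."""

    label_map: np.ndarray
    truth_t1: np.ndarray
    truth_t2: np.ndarray
    truth_adc: np.ndarray
    voxel_size_mm: tuple[float, float]
    seed: int
    params: TissueParameterSet

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.label_map, self.truth_t1, self.truth_t2, self.truth_adc)}
        if len(shapes) != 1:
            raise ValueError(f"label map and truth grids must share a shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label_map > BACKGROUND


def region_mask(label_map: np.ndarray, region: str) -> np.ndarray:
    """Boolean mask of a named region (cortex/osom/isom/om/whole_kidney)."""
    try:
        codes = REGIONS[region]
    except KeyError:
        raise KeyError(f"unknown region {region!r}; expected one of {sorted(REGIONS)}") from None
    return np.isin(label_map, codes)


def make_label_map(
    shape: tuple[int, int] = (128, 128),
    geometry: EllipseGeometry | None = None,
) -> np.ndarray:
    """Build the integer compartment label map.

    The layout is three concentric elliptical bands oriented along the long
    axis of the slice: cortex outermost, then OSOM, then ISOM at the core.
    Deterministic: no randomness enters the geometry.
    """
    geometry = geometry or EllipseGeometry()
    geometry.validate()
    nx, ny = shape
    if nx < 64 or ny < 64:
        raise ValueError(f"shape must be at least 64x64, got {shape}")

    ax = geometry.semi_axes_frac[0] * (nx / 2)
    ay = geometry.semi_axes_frac[1] * (ny / 2)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    r = np.sqrt((x / ax) ** 2 + (y / ay) ** 2)  # normalized elliptical radius

    labels = np.zeros(shape, dtype=np.int16)
    labels[r <= 1.0] = CORTEX
    labels[r <= geometry.osom_outer_frac] = OSOM
    labels[r <= geometry.isom_outer_frac] = ISOM
    return labels


def _smooth_unit_field(shape, scale_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-correlated random field, standardized later by the caller."""
    noise = rng.standard_normal(shape)
    if scale_vox > 0:
        noise = ndimage.gaussian_filter(noise, sigma=scale_vox, mode="reflect")
    return noise


def make_texture_field(
    label_map: np.ndarray,
    sd: float,
    scale_vox: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth zero-mean within-tissue variation with exact sample SD ``sd``.

    The field is standardized over tissue voxels so that the realized
    standard deviation equals ``sd`` exactly, which makes dispersion
    calibration independent of the random draw.
    """
    tissue = label_map > BACKGROUND
    out = np.zeros(label_map.shape, dtype=float)
    if sd == 0 or tissue.sum() < 2:
        return out
    f = _smooth_unit_field(label_map.shape, scale_vox, rng)
    v = f[tissue]
    out[tissue] = (v - v.mean()) / v.std() * sd
    return out


def make_heterogeneity_field(
    label_map: np.ndarray,
    adc_base: dict[int, float],
    settings: Heterogeneity,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Patchy two-class ADC field for an allograft phantom.

    A smoothed Gaussian random field with correlation length
    ``patch_scale_vox`` is thresholded at zero, giving two spatially
    coherent classes with expected weight 1/2 each.  Tissue voxels take
    their compartment base value plus or minus ``adc_delta`` according to
    class, plus independent Gaussian within-class variation, and are
    clipped below at 0.1e-3 mm^2/s.  Background stays zero.
    """
    if not settings.enabled:
        raise ValueError("heterogeneity field requested but settings.enabled is False")
    if settings.adc_delta < 0:
        raise ValueError("adc_delta must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tissue = label_map > BACKGROUND
    base = np.zeros(label_map.shape, dtype=float)
    for code, value in adc_base.items():
        base[label_map == code] = value

    patch = _smooth_unit_field(label_map.shape, settings.patch_scale_vox, rng)
    sign = np.where(patch >= 0.0, 1.0, -1.0)
    fld = base + sign * settings.adc_delta
    if settings.within_patch_sd > 0:
        fld = fld + rng.normal(0.0, settings.within_patch_sd, size=fld.shape)
    fld = np.where(tissue, np.maximum(fld, _ADC_FLOOR), 0.0)
    return fld


def make_phantom(
    params: TissueParameterSet,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    geometry: EllipseGeometry | None = None,
    voxel_size_mm: tuple[float, float] = (35.0 / 128, 35.0 / 128),
) -> PhantomImage:
    """Assemble a phantom: label map plus T1/T2/ADC ground-truth grids.

    Control and isogenic phantoms have piecewise-constant relaxation grids;
    isogenic (and optionally other) groups may carry a smooth ADC texture;
    allogenic phantoms overlay the patchy two-class ADC mixture.  Identical
    ``(params, shape, seed)`` give a bit-identical phantom.
    """
    params.validate()
    labels = make_label_map(shape, geometry)
    rng = np.random.default_rng(seed)

    truth = {}
    for name, values in (("t1", params.t1_ms), ("t2", params.t2_ms), ("adc", params.adc_um2_per_ms)):
        grid = np.zeros(shape, dtype=float)
        for code in (CORTEX, OSOM, ISOM):
            grid[labels == code] = values[code]
        truth[name] = grid

    het = params.heterogeneity
    if het.enabled:
        truth["adc"] = make_heterogeneity_field(labels, params.adc_um2_per_ms, het, rng)
        if het.t1_delta_ms or het.t2_delta_ms:
            # reuse a fresh patch pattern for the relaxation times
            patch = _smooth_unit_field(shape, het.patch_scale_vox, rng)
            sign = np.where(patch >= 0, 1.0, -1.0) * (labels > BACKGROUND)
            truth["t1"] = np.maximum(truth["t1"] + sign * het.t1_delta_ms, 0.0)
            truth["t2"] = np.maximum(truth["t2"] + sign * het.t2_delta_ms, 0.0)

    if params.adc_texture_sd > 0:
        tex = make_texture_field(labels, params.adc_texture_sd, params.texture_scale_vox, rng)
        tissue = labels > BACKGROUND
        truth["adc"] = np.where(tissue, np.maximum(truth["adc"] + tex, _ADC_FLOOR), 0.0)

    return PhantomImage(
        label_map=labels,
        truth_t1=truth["t1"],
        truth_t2=truth["t2"],
        truth_adc=truth["adc"],
        voxel_size_mm=voxel_size_mm,
        seed=seed,
        params=params,
    )


# ---------------------------------------------------------------------------
# balanced two-normal mixture: closed forms used for calibration and testing


def mixture_sd(delta: float, sigma: float) -> float:
    """Population SD of the balanced mixture N(-delta, sigma) / N(+delta, sigma)."""
    return float(np.hypot(delta, sigma))


def _mixture_cdf(x, delta, sigma):
    return 0.5 * _stats.norm.cdf(x, -delta, sigma) + 0.5 * _stats.norm.cdf(x, delta, sigma)


def mixture_quantile(p: float, delta: float, sigma: float) -> float:
    """Quantile of the balanced two-normal mixture (centered at zero)."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    span = delta + 10 * sigma
    return float(optimize.brentq(lambda x: _mixture_cdf(x, delta, sigma) - p, -span, span, xtol=1e-12))


def mixture_iqr(delta: float, sigma: float) -> float:
    """Interquartile range of the balanced mixture; 2*q75 by symmetry."""
    return 2.0 * mixture_quantile(0.75, delta, sigma)


def calibrate_adc_delta(target_sd: float, within_patch_sd: float) -> float:
    """Class offset that makes the mixture SD hit ``target_sd``.

    Inverts SD^2 = delta^2 + sigma^2 for the balanced two-class mixture.
    """
    if target_sd <= within_patch_sd:
        raise ValueError(
            f"target SD ({target_sd}) must exceed the within-class SD ({within_patch_sd})"
        )
    return float(np.sqrt(target_sd**2 - within_patch_sd**2))


def calibrate_mixture(target_sd: float, target_iqr: float) -> tuple[float, float]:
    """Choose (delta, sigma) so the balanced mixture matches SD *and* IQR.

    Along the constraint delta^2 + sigma^2 = SD^2 the IQR grows
    monotonically with delta from the pure-Gaussian value 1.349*SD (at
    delta = 0) towards 2*delta (well-separated classes).  A target IQR at
    or below the Gaussian value is therefore matched as closely as possible
    by a single Gaussian (delta = 0).
    """
    if target_sd <= 0 or target_iqr <= 0:
        raise ValueError("targets must be positive")
    gaussian_iqr = mixture_iqr(0.0, target_sd)
    if target_iqr <= gaussian_iqr:
        return 0.0, target_sd

    def f(delta):
        sigma = np.sqrt(target_sd**2 - delta**2)
        return mixture_iqr(delta, sigma) - target_iqr

    hi = target_sd * (1 - 1e-9)
    if f(hi) < 0:  # even maximal separation cannot widen the IQR enough
        raise ValueError(
            f"target IQR {target_iqr} unreachable for SD {target_sd} "
            f"(maximum is about {2 * target_sd:.3f})"
        )
    delta = optimize.brentq(f, 1e-9, hi, xtol=1e-10)
    return float(delta), float(np.sqrt(target_sd**2 - delta**2))
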