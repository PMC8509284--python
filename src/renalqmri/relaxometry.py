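"""Voxel-wise T1, T2 and ADC estimation from acquisition series.

Each estimator is exposed as a small model class in the statsmodels idiom:
construct the model from an :class:`~renalqmri.synthesis.AcquisitionSeries`,
call :meth:`fit`, and receive a :class:`ParameterMap` results object
carrying the estimates, per-voxel standard errors, a validity mask, an R^2
quality map and a text ``summary()``.

Estimators
----------
T1 (inversion recovery)
    Nonlinear least squares of the three-parameter magnitude model
    ``|a - b * exp(-TI/T1)|`` with polarity restoration: for every
    candidate null index the pre-null points are sign-flipped and the
    signed model is fitted; the candidate with the smallest residual wins.
    The nonlinear part is solved by variable projection — for a trial T1
    the amplitudes (a, b) are linear — with a deterministic log-spaced grid
    search followed by golden-section refinement.  The reported T1 is the
    exponential rate constant itself (single-shot readout, no Look-Locker
    correction).

T2 and ADC (mono-exponential decay)
    Weighted log-linear least squares with weights equal to the squared
    signal (the first-order variance weighting for log-transformed
    magnitude data); an optional Levenberg-Marquardt refinement of the
    untransformed model is available behind ``nls_refine``.  On noiseless
    data the two routes agree to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .synthesis import AcquisitionSeries

__all__ = [
    "ParameterMap",
    "InversionRecoveryT1Model",
    "MultiEchoT2Model",
    "MonoExponentialADCModel",
    "fit_t1_ir",
    "fit_t2",
    "fit_adc",
    "predict_adc_fit_sd",
    "T1_BOUNDS_MS",
    "T2_BOUNDS_MS",
    "ADC_BOUNDS_E3",
]

# plausibility bounds; estimates at or beyond a bound are masked out
T1_BOUNDS_MS = (200.0, 5000.0)
T2_BOUNDS_MS = (5.0, 500.0)
ADC_BOUNDS_E3 = (0.05, 4.0)

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class ParameterMap:
    """Results object for one fitted quantitative map.

    ``values`` is the 2D parameter grid (ms for T1/T2, 1e-3 mm^2/s for
    ADC); ``mask`` marks voxels where the fit was attempted, converged and
    passed the quality and plausibility checks; ``quality`` holds the
    coefficient of determination R^2 of the per-voxel fit and ``stderr``
    the linearized per-voxel standard error where available.
    """

    kind: str  # "T1_ms" | "T2_ms" | "ADC_e3mm2s"
    values: np.ndarray
    mask: np.ndarray
    quality: np.ndarray
    stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("T1_ms", "T2_ms", "ADC_e3mm2s"):
            raise ValueError(f"unknown map kind {self.kind!r}")

    @property
    def units(self) -> str:
        return {"T1_ms": "ms", "T2_ms": "ms", "ADC_e3mm2s": "1e-3 mm^2/s"}[self.kind]

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def summary(self) -> str:
        v = self.masked_values()
        lines = [
            f"{self.kind} parameter map ({self.values.shape[0]}x{self.values.shape[1]})",
            f"  fitted voxels : {self.mask.sum()} / {self.mask.size}",
        ]
        if v.size:
            q = self.quality[self.mask]
            lines += [
                f"  mean / median : {v.mean():.4g} / {np.median(v):.4g} {self.units}",
                f"  range         : [{v.min():.4g}, {v.max():.4g}] {self.units}",
                f"  median R^2    : {np.median(q):.5f}",
            ]
            if self.stderr is not None:
                lines.append(f"  median stderr : {np.median(self.stderr[self.mask]):.4g} {self.units}")
        for k, val in self.meta.items():
            lines.append(f"  {k}: {val}")
        return "\n".join(lines)


def _as_voxel_table(series: AcquisitionSeries) -> tuple[np.ndarray, tuple[int, int]]:
    """Flatten (x, y, 1, n) data to an (n_vox, n_meas) table."""
    d = series.data
    shape2d = d.shape[:2]
    return d.reshape(-1, d.shape[-1]), shape2d


def _signal_prefilter(table: np.ndarray, floor_frac: float) -> np.ndarray:
    """Voxels worth fitting: peak signal above a fraction of the image peak.

    Excludes all-zero voxels always; with ``floor_frac > 0`` it also skips
    background voxels whose magnitude is pure noise.
    """
    peak = table.max(axis=1)
    ref = np.percentile(peak, 99)
    thresh = floor_frac * ref if ref > 0 else 0.0
    return peak > max(thresh, 0.0)


class InversionRecoveryT1Model:
    """Voxel-wise magnitude inversion-recovery T1 model."""

    def __init__(
        self,
        series: AcquisitionSeries,
        r2_floor: float = 0.9,
        bounds_ms: tuple[float, float] = T1_BOUNDS_MS,
        grid_size: int = 96,
        refine_iters: int = 40,
        signal_floor_frac: float = 0.05,
        compute_stderr: bool = True,
    ):
        if series.kind != "IR_T1":
            raise ValueError(f"expected an IR_T1 series, got {series.kind}")
        if series.n_meas < 4:
            raise ValueError("T1 fitting needs at least 4 inversion times")
        self.series = series
        self.r2_floor = r2_floor
        self.bounds_ms = bounds_ms
        self.grid_size = grid_size
        self.refine_iters = refine_iters
        self.signal_floor_frac = signal_floor_frac
        self.compute_stderr = compute_stderr

    @staticmethod
    def _linear_amplitudes(y: np.ndarray, e: np.ndarray):
        """Profile out (a, b) of y = a - b*e for fixed exponentials e.

        ``y``: (N, n) signed data, ``e``: (N, n) or (n,) exponentials.
        Returns (a, b, sse) with sse the per-voxel residual sum of squares.
        """
        n = y.shape[-1]
        if e.ndim == 1:
            s1e, see = e.sum(), (e * e).sum()
            sey = y @ e
        else:
            s1e, see = e.sum(axis=1), (e * e).sum(axis=1)
            sey = (y * e).sum(axis=1)
        s1y = y.sum(axis=1)
        syy = (y * y).sum(axis=1)
        det = s1e**2 - n * see  # strictly negative unless e is constant
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (-see * s1y + s1e * sey) / det
            b = (n * sey - s1e * s1y) / det
            sse = syy - a * s1y + b * sey
        return a, b, np.maximum(sse, 0.0)

    def fit(self) -> ParameterMap:
        tis = self.series.param_axis
        table, shape2d = _as_voxel_table(self.series)
        candidates = _signal_prefilter(table, self.signal_floor_frac)
        y_mag = table[candidates]
        n_vox, n = y_mag.shape
        lo_b, hi_b = self.bounds_ms

        values = np.zeros(np.prod(shape2d))
        quality = np.full(np.prod(shape2d), -np.inf)
        stderr = np.full(np.prod(shape2d), np.nan)
        mask = np.zeros(np.prod(shape2d), dtype=bool)

        if n_vox:
            t1_grid = np.geomspace(lo_b, hi_b, self.grid_size)
            e_grid = np.exp(-tis[None, :] / t1_grid[:, None])  # (G, n)
            s1e = e_grid.sum(axis=1)
            see = (e_grid * e_grid).sum(axis=1)
            det = s1e**2 - n * see

            # candidate null indices: the magnitude minimum locates the
            # zero crossing to within one sample, so a window around the
            # per-voxel argmin covers the true polarity split
            argmin = np.argmin(y_mag, axis=1)
            win_lo = np.maximum(argmin - 1, 0)
            win_hi = np.minimum(argmin + 2, n)

            best_sse = np.full(n_vox, np.inf)
            best_k = np.zeros(n_vox, dtype=np.int64)
            best_g = np.zeros(n_vox, dtype=np.int64)
            for k in range(int(win_lo.min()), int(win_hi.max()) + 1):
                rows = np.flatnonzero((win_lo <= k) & (k <= win_hi))
                if rows.size == 0:
                    continue
                y = y_mag[rows] * np.where(np.arange(n) < k, -1.0, 1.0)
                s1y = y.sum(axis=1)
                syy = (y * y).sum(axis=1)
                sey = y @ e_grid.T  # (rows, G)
                a = (-see[None, :] * s1y[:, None] + s1e[None, :] * sey) / det[None, :]
                b = (n * sey - s1e[None, :] * s1y[:, None]) / det[None, :]
                sse = syy[:, None] - a * s1y[:, None] + b * sey
                g = np.argmin(sse, axis=1)
                s = sse[np.arange(rows.size), g]
                better = s < best_sse[rows]
                upd = rows[better]
                best_sse[upd] = s[better]
                best_k[upd] = k
                best_g[upd] = g[better]

            # polarity-restored signed data for the winning candidate
            y_signed = y_mag * np.where(np.arange(n)[None, :] < best_k[:, None], -1.0, 1.0)

            # classic golden-section refinement, vectorized over voxels
            lo = t1_grid[np.maximum(best_g - 1, 0)]
            hi = t1_grid[np.minimum(best_g + 1, self.grid_size - 1)]

            def f(t):
                return self._linear_amplitudes(y_signed, np.exp(-tis[None, :] / t[:, None]))[2]

            x1 = hi - _GOLDEN * (hi - lo)
            x2 = lo + _GOLDEN * (hi - lo)
            f1, f2 = f(x1), f(x2)
            for _ in range(self.refine_iters):
                take1 = f1 < f2  # keep [lo, x2], else keep [x1, hi]
                hi = np.where(take1, x2, hi)
                lo = np.where(take1, lo, x1)
                x_new = np.where(take1, hi - _GOLDEN * (hi - lo), lo + _GOLDEN * (hi - lo))
                f_new = f(x_new)
                x1, f1, x2, f2 = (
                    np.where(take1, x_new, x2),
                    np.where(take1, f_new, f2),
                    np.where(take1, x1, x_new),
                    np.where(take1, f1, f_new),
                )
            t1 = 0.5 * (lo + hi)

            e_fin = np.exp(-tis[None, :] / t1[:, None])
            a, b, sse = self._linear_amplitudes(y_signed, e_fin)
            ybar = y_signed.mean(axis=1, keepdims=True)
            ss_tot = ((y_signed - ybar) ** 2).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = 1.0 - sse / ss_tot
            good = (
                np.isfinite(t1)
                & np.isfinite(r2)
                & (t1 > lo_b * (1 + 1e-9))
                & (t1 < hi_b * (1 - 1e-9))
                & (r2 >= self.r2_floor)
            )

            se = np.full(n_vox, np.nan)
            if self.compute_stderr and n > 3:
                # delta-method stderr from the Jacobian of (a, b, T1)
                jac = np.empty((n_vox, n, 3))
                jac[:, :, 0] = 1.0
                jac[:, :, 1] = -e_fin
                jac[:, :, 2] = -(b[:, None]) * e_fin * tis[None, :] / (t1[:, None] ** 2)
                jtj = np.einsum("vni,vnj->vij", jac, jac)
                # tiny ridge keeps the batched inverse defined on degenerate voxels
                tr = np.trace(jtj, axis1=1, axis2=2)
                jtj += (1e-12 * np.maximum(tr, 1.0))[:, None, None] * np.eye(3)[None]
                s2 = sse / (n - 3)
                with np.errstate(all="ignore"):
                    cov = np.linalg.inv(jtj)
                    se = np.sqrt(np.maximum(cov[:, 2, 2] * s2, 0.0))

            idx = np.flatnonzero(candidates)
            values[idx] = t1
            quality[idx] = r2
            stderr[idx] = se
            mask[idx] = good

        meta = {
            "model": "magnitude IR |a - b*exp(-TI/T1)| (variable projection)",
            "n_meas": int(n),
            "snr": self.series.snr,
            "seed": self.series.seed,
            "r2_floor": self.r2_floor,
        }
        return ParameterMap(
            kind="T1_ms",
            values=values.reshape(shape2d),
            mask=mask.reshape(shape2d),
            quality=quality.reshape(shape2d),
            stderr=stderr.reshape(shape2d) if self.compute_stderr else None,
            meta=meta,
        )


class _LogLinearDecayModel:
    """Shared weighted log-linear machinery for T2 and ADC maps."""

    kind: str
    min_points: int

    def __init__(
        self,
        series: AcquisitionSeries,
        r2_floor: float = 0.9,
        nls_refine: bool = False,
        signal_floor_frac: float = 0.05,
    ):
        self.series = series
        self.r2_floor = r2_floor
        self.nls_refine = nls_refine
        self.signal_floor_frac = signal_floor_frac

    # subclasses map the fitted decay rate to the reported parameter
    def _rate_to_value(self, rate: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _value_bounds(self) -> tuple[float, float]:
        raise NotImplementedError

    def fit(self) -> ParameterMap:
        x = self.series.param_axis
        table, shape2d = _as_voxel_table(self.series)
        candidates = _signal_prefilter(table, self.signal_floor_frac)
        data = table[candidates]
        n_vox = data.shape[0]

        values = np.zeros(np.prod(shape2d))
        quality = np.full(np.prod(shape2d), -np.inf)
        stderr = np.full(np.prod(shape2d), np.nan)
        mask = np.zeros(np.prod(shape2d), dtype=bool)

        if n_vox:
            usable = data > 0
            n_used = usable.sum(axis=1)
            w = np.where(usable, data**2, 0.0)
            logy = np.where(usable, np.log(np.where(usable, data, 1.0)), 0.0)
            wsum = w.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                xw = (w * x).sum(axis=1) / wsum
                yw = (w * logy).sum(axis=1) / wsum
                dx = x[None, :] - xw[:, None]
                dy = logy - yw[:, None]
                sxx = (w * dx * dx).sum(axis=1)
                slope = (w * dx * dy).sum(axis=1) / sxx
                intercept = yw - slope * xw
                resid = np.where(usable, dy - slope[:, None] * dx, 0.0)
                ss_res = (w * resid**2).sum(axis=1)
                ss_tot = (w * dy * dy).sum(axis=1)
                r2 = 1.0 - ss_res / ss_tot
                dof = n_used - 2
                slope_se = np.sqrt(np.where(dof > 0, ss_res / np.maximum(dof, 1), np.nan) / sxx)

            if self.nls_refine:
                slope, intercept = self._nls_refine(data, usable, x, slope, intercept)
                pred = np.exp(intercept[:, None] + slope[:, None] * x[None, :])
                resid = np.where(usable, data - pred, 0.0)
                dbar = (np.where(usable, data, 0.0)).sum(axis=1) / np.maximum(n_used, 1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    r2 = 1.0 - (resid**2).sum(axis=1) / (
                        np.where(usable, (data - dbar[:, None]) ** 2, 0.0).sum(axis=1)
                    )

            val, val_se, in_bounds = self._finalize(slope, slope_se)
            good = (
                (n_used >= self.min_points)
                & np.isfinite(val)
                & np.isfinite(r2)
                & in_bounds
                & (r2 >= self.r2_floor)
            )

            idx = np.flatnonzero(candidates)
            values[idx] = np.where(np.isfinite(val), val, 0.0)
            quality[idx] = r2
            stderr[idx] = val_se
            mask[idx] = good

        meta = {
            "model": self._model_name(),
            "estimator": "weighted log-linear (weights = signal^2)"
            + (" + NLS refinement" if self.nls_refine else ""),
            "n_meas": self.series.n_meas,
            "snr": self.series.snr,
            "seed": self.series.seed,
            "r2_floor": self.r2_floor,
        }
        return ParameterMap(
            kind=self.kind,
            values=values.reshape(shape2d),
            mask=mask.reshape(shape2d),
            quality=quality.reshape(shape2d),
            stderr=stderr.reshape(shape2d),
            meta=meta,
        )

    def _nls_refine(self, data, usable, x, slope, intercept):
        """Per-voxel Levenberg-Marquardt polish of s0*exp(slope*x)."""
        out_s = slope.copy()
        out_i = intercept.copy()
        for v in range(data.shape[0]):
            if not (np.isfinite(slope[v]) and np.isfinite(intercept[v])):
                continue
            m = usable[v]
            if m.sum() < self.min_points:
                continue

            def f(xx, lns0, sl):
                return np.exp(lns0 + sl * xx)

            try:
                popt, _ = optimize.curve_fit(
                    f, x[m], data[v, m], p0=(intercept[v], slope[v]), maxfev=200
                )
                out_i[v], out_s[v] = popt
            except RuntimeError:
                pass
        return out_s, out_i

    def _model_name(self) -> str:
        raise NotImplementedError

    def _finalize(self, slope, slope_se):
        raise NotImplementedError


class MultiEchoT2Model(_LogLinearDecayModel):
    """Voxel-wise mono-exponential T2 decay model, m0 * exp(-TE/T2)."""

    kind = "T2_ms"
    min_points = 3
    #: non-decaying voxels are clipped here and masked out
    t2_clip_ms = 500.0

    def __init__(self, series: AcquisitionSeries, **kwargs):
        if series.kind != "ME_T2":
            raise ValueError(f"expected an ME_T2 series, got {series.kind}")
        if series.n_meas < 3:
            raise ValueError("T2 fitting needs at least 3 echoes")
        super().__init__(series, **kwargs)

    def _model_name(self) -> str:
        return "mono-exponential T2 decay m0*exp(-TE/T2)"

    def _finalize(self, slope, slope_se):
        lo, hi = T2_BOUNDS_MS
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = -1.0 / slope
            se = slope_se / slope**2  # delta method for 1/|slope|
        flat = ~np.isfinite(t2) | (t2 <= 0) | (t2 >= self.t2_clip_ms)
        t2 = np.where(flat, self.t2_clip_ms, t2)
        in_bounds = ~flat & (t2 > lo) & (t2 < hi)
        return t2, se, in_bounds


class MonoExponentialADCModel(_LogLinearDecayModel):
    """Voxel-wise mono-exponential diffusion model, s0 * exp(-b * ADC)."""

    kind = "ADC_e3mm2s"
    min_points = 2

    def __init__(self, series: AcquisitionSeries, **kwargs):
        if series.kind != "DWI":
            raise ValueError(f"expected a DWI series, got {series.kind}")
        if series.n_meas < 2 or series.param_axis[0] != 0:
            raise ValueError("ADC fitting needs at least 2 b-values including b = 0")
        super().__init__(series, **kwargs)

    def _model_name(self) -> str:
        return "mono-exponential diffusion decay s0*exp(-b*ADC)"

    def _finalize(self, slope, slope_se):
        lo, hi = ADC_BOUNDS_E3
        adc = -slope * 1e3  # slope in mm^2/s -> 1e-3 mm^2/s
        se = slope_se * 1e3
        in_bounds = np.isfinite(adc) & (adc > lo) & (adc < hi)
        return adc, se, in_bounds


def fit_t1_ir(series: AcquisitionSeries, **kwargs) -> ParameterMap:
    """Fit a T1 map from an inversion-recovery series."""
    return InversionRecoveryT1Model(series, **kwargs).fit()


def fit_t2(series: AcquisitionSeries, **kwargs) -> ParameterMap:
    """Fit a T2 map from a multi-echo series."""
    return MultiEchoT2Model(series, **kwargs).fit()


def fit_adc(series: AcquisitionSeries, **kwargs) -> ParameterMap:
    """Fit an ADC map (1e-3 mm^2/s) from a DWI series."""
    return MonoExponentialADCModel(series, **kwargs).fit()


def predict_adc_fit_sd(adc_e3: float, b_s_per_mm2, snr: float) -> float:
    """Per-voxel standard deviation of the weighted log-linear ADC estimate.

    First-order (delta-method) noise floor of the estimator at a given true
    ADC: log-magnitude noise at point i has variance (sigma/s_i)^2 with
    sigma = S0/SNR, and the inverse-variance-weighted slope then has
    variance 1 / sum_i w_i (b_i - b_w)^2.  Returned in 1e-3 mm^2/s; used to
    deconvolve printed map dispersion into ground-truth tissue dispersion
    when calibrating phantoms.
    """
    b = np.asarray(b_s_per_mm2, dtype=float)
    s = np.exp(-b * adc_e3 * 1e-3)  # relative to S0
    w = (s * snr) ** 2
    bw = (w * b).sum() / w.sum()
    return float(1e3 / np.sqrt((w * (b - bw) ** 2).sum()))
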