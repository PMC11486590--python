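"""Per-pixel mono-exponential relaxation-time mapping.

A magnetization-prepared series is modelled per pixel as

    S(t) = S0 * exp(-t / T)

with preparation time ``t`` (ms) and relaxation time ``T`` (ms). Maps are
fitted either by ordinary least squares on the log-signal (``log_linear``)
or by nonlinear least squares on the exponential model seeded from the
log-linear solution (``nonlinear_ls``, the default — magnitude-MRI noise
biases log-domain fits).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CONTRAST_LABELS",
    "MapSeries",
    "RelaxationMap",
    "FitConfig",
    "fit_monoexponential",
    "interpolate_map",
]

CONTRAST_LABELS = ("T2", "T1rho", "aT1rho", "aT2rho")

# decay rates with |R| below this (1/ms) are treated as "no decay"
_FLAT_RATE_TOL = 1e-12


@dataclass(frozen=True)
class MapSeries:
    """Stack of prepared images with their preparation times.

    Parameters
    ----------
    images
        Array of shape ``(n_prep, H, W)``, one 2D image per preparation
        time, arbitrary signal units.
    prep_times
        Preparation times in ms, strictly increasing, non-negative.
    pixel_spacing
        In-plane isotropic pixel size in mm.
    contrast_label
        One of :data:`CONTRAST_LABELS`.
    """

    images: np.ndarray
    prep_times: np.ndarray
    pixel_spacing: float
    contrast_label: str

    def __post_init__(self) -> None:
        images = np.asarray(self.images, dtype=float)
        prep = np.asarray(self.prep_times, dtype=float)
        if images.ndim == 2:
            images = images[np.newaxis]
        if images.ndim != 3:
            raise ValueError("images must be a stack of 2D arrays")
        if prep.ndim != 1 or len(prep) != images.shape[0]:
            raise ValueError(
                f"number of images ({images.shape[0]}) must equal number of "
                f"prep times ({prep.size})"
            )
        if np.any(prep < 0) or np.any(np.diff(prep) <= 0):
            raise ValueError("prep_times must be non-negative and strictly increasing")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        if self.contrast_label not in CONTRAST_LABELS:
            raise ValueError(
                f"contrast_label must be one of {CONTRAST_LABELS}, "
                f"got {self.contrast_label!r}"
            )
        object.__setattr__(self, "images", images)
        object.__setattr__(self, "prep_times", prep)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    @property
    def n_prep(self) -> int:
        return self.images.shape[0]


@dataclass(frozen=True)
class RelaxationMap:
    """Fitted relaxation-time map with fit diagnostics.

    ``values`` holds the relaxation time in ms (NaN where the fit failed),
    ``s0`` the fitted zero-prep-time signal and ``rsq`` the coefficient of
    determination of the signal-domain residuals.
    """

    values: np.ndarray
    s0: np.ndarray
    rsq: np.ndarray
    pixel_spacing: float
    contrast_label: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        s0 = np.asarray(self.s0, dtype=float)
        rsq = np.asarray(self.rsq, dtype=float)
        if values.ndim != 2 or s0.shape != values.shape or rsq.shape != values.shape:
            raise ValueError("values, s0 and rsq must be 2D arrays of equal shape")
        finite = np.isfinite(values)
        if np.any(values[finite] <= 0):
            raise ValueError("finite relaxation times must be positive")
        frsq = rsq[finite]
        if np.any((frsq < 0) | (frsq > 1)):
            raise ValueError("rsq must lie in [0, 1] where values are finite")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        if self.contrast_label not in CONTRAST_LABELS:
            raise ValueError(f"unknown contrast_label {self.contrast_label!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "s0", s0)
        object.__setattr__(self, "rsq", rsq)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class FitConfig:
    """Fitting options.

    ``min_signal`` — samples at or below this floor are excluded;
    ``max_T`` — cap on the reported relaxation time (ms), guards flat decay;
    ``min_valid_samples`` — minimum number of included prep-time points per
    pixel for a fit to be attempted.
    """

    method: str = "nonlinear_ls"
    min_signal: float = 0.0
    max_T: float = 1000.0
    min_valid_samples: int = 2

    def __post_init__(self) -> None:
        if self.method not in ("log_linear", "nonlinear_ls"):
            raise ValueError("method must be 'log_linear' or 'nonlinear_ls'")
        if self.min_valid_samples < 2:
            raise ValueError("min_valid_samples must be >= 2")
        if not self.max_T > 0:
            raise ValueError("max_T must be positive")


def _loglinear(t: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Masked per-pixel OLS of log-signal; returns (decay rate R, S0)."""
    ly = np.where(w > 0, np.log(np.where(y > 0, y, 1.0)), 0.0)
    n = w.sum(axis=0)
    st = (w * t).sum(axis=0)
    sy = (w * ly).sum(axis=0)
    stt = (w * t * t).sum(axis=0)
    sty = (w * t * ly).sum(axis=0)
    denom = n * stt - st * st
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sty - st * sy) / denom
        intercept = (sy - slope * st) / n
    slope = np.where(denom > _FLAT_RATE_TOL, slope, np.nan)
    return -slope, np.exp(intercept)


def _model_sse(t, y, w, s0, rate):
    resid = (s0 * np.exp(-rate * t) - y) * w
    return (resid * resid).sum(axis=0)


def _lm_refine(t, y, w, s0, rate, n_iter: int = 80):
    """Vectorized Levenberg–Marquardt on (S0, R) for every pixel at once."""
    lam = np.full(s0.shape, 1e-3)
    sse = _model_sse(t, y, w, s0, rate)
    for _ in range(n_iter):
        e = np.exp(-rate * t) * w
        f = s0 * e
        r = f - y * w
        j2 = -s0 * t * e
        a11 = (e * e).sum(axis=0)
        a12 = (e * j2).sum(axis=0)
        a22 = (j2 * j2).sum(axis=0)
        g1 = (e * r).sum(axis=0)
        g2 = (j2 * r).sum(axis=0)
        d11 = a11 * (1.0 + lam) + 1e-30
        d22 = a22 * (1.0 + lam) + 1e-30
        det = d11 * d22 - a12 * a12
        with np.errstate(divide="ignore", invalid="ignore"):
            ds0 = (d22 * g1 - a12 * g2) / det
            drate = (d11 * g2 - a12 * g1) / det
        s0_new = s0 - np.where(np.isfinite(ds0), ds0, 0.0)
        rate_new = np.clip(rate - np.where(np.isfinite(drate), drate, 0.0), 0.0, None)
        sse_new = _model_sse(t, y, w, s0_new, rate_new)
        improve = sse_new < sse
        s0 = np.where(improve, s0_new, s0)
        rate = np.where(improve, rate_new, rate)
        sse = np.where(improve, sse_new, sse)
        lam = np.clip(np.where(improve, lam * 0.3, lam * 5.0), 1e-10, 1e10)
    return s0, rate


def fit_monoexponential(series: MapSeries, config: FitConfig | None = None) -> RelaxationMap:
    """Fit ``S(t) = S0 exp(-t/T)`` on a pixel basis.

    Pixels with fewer than ``config.min_valid_samples`` samples above
    ``config.min_signal``, or with a non-positive fitted relaxation time,
    are marked NaN. Flat (non-decaying) pixels are capped at
    ``config.max_T``.
    """
    config = config or FitConfig()
    if series.n_prep < config.min_valid_samples:
        raise ValueError(
            f"series has {series.n_prep} prep times but at least "
            f"{config.min_valid_samples} are required"
        )
    shape = series.shape
    n_pix = shape[0] * shape[1]
    y = series.images.reshape(series.n_prep, n_pix)
    t = series.prep_times[:, np.newaxis]
    w = (np.isfinite(y) & (y > config.min_signal)).astype(float)
    y = np.where(w > 0, y, 0.0)
    enough = w.sum(axis=0) >= config.min_valid_samples

    rate, s0 = _loglinear(t, y, w)
    # growth (R < 0 beyond tolerance) cannot be a decay; flat R snaps to 0
    growing = rate < -_FLAT_RATE_TOL
    rate = np.where(np.abs(rate) < _FLAT_RATE_TOL, 0.0, rate)
    valid = enough & np.isfinite(rate) & ~growing & np.isfinite(s0) & (s0 > 0)

    if config.method == "nonlinear_ls":
        rate_init = np.clip(np.where(valid, rate, 1.0 / config.max_T), 1.0 / config.max_T, None)
        s0_init = np.where(valid & np.isfinite(s0), s0, 1.0)
        s0_fit, rate_fit = _lm_refine(t, y, w, s0_init, rate_init)
        s0 = np.where(valid, s0_fit, np.nan)
        rate = np.where(valid, rate_fit, np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(rate > 1.0 / config.max_T, 1.0 / rate, config.max_T)
    values = np.where(valid, values, np.nan)
    s0 = np.where(valid, s0, np.nan)

    # signal-domain R^2 over the included samples
    with np.errstate(invalid="ignore"):
        pred = s0 * np.exp(-t / values)
    n = np.maximum(w.sum(axis=0), 1.0)
    ybar = (w * y).sum(axis=0) / n
    ss_res = _model_sse(t, y, w, s0, np.where(valid, 1.0 / values, 0.0))
    ss_tot = (w * (y - ybar) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsq = 1.0 - ss_res / ss_tot
    rsq = np.where(ss_tot > 0, rsq, np.where(ss_res < 1e-12, 1.0, 0.0))
    rsq = np.clip(np.where(valid, rsq, np.nan), 0.0, 1.0)

    return RelaxationMap(
        values=values.reshape(shape),
        s0=s0.reshape(shape),
        rsq=rsq.reshape(shape),
        pixel_spacing=series.pixel_spacing,
        contrast_label=series.contrast_label,
    )


def _fill_nearest(a: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    if not invalid.any():
        return a
    idx = ndimage.distance_transform_edt(invalid, return_distances=False, return_indices=True)
    return a[tuple(idx)]


def _resample(a: np.ndarray, coords: np.ndarray, order: int) -> np.ndarray:
    return ndimage.map_coordinates(a, coords, order=order, mode="mirror")


def interpolate_map(rmap: RelaxationMap, factor: int) -> RelaxationMap:
    """Bicubic upsampling of a map to ``pixel_spacing / factor``.

    Output grid point ``j`` sits at input index ``j / factor``, so physical
    positions are preserved and the output shape is ``(n - 1) * factor + 1``
    per axis. Any output pixel whose bicubic stencil touches a failed-fit
    (NaN) input pixel is itself NaN — values are never invented inside
    failed regions.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return dataclasses.replace(rmap)

    h, w = rmap.shape
    rows = np.arange((h - 1) * factor + 1) / factor
    cols = np.arange((w - 1) * factor + 1) / factor
    coords = np.stack(np.meshgrid(rows, cols, indexing="ij"))

    invalid = ~rmap.finite_mask
    # bicubic stencil spans 2 input pixels in every direction
    touched = ndimage.grey_dilation(invalid.astype(np.uint8), size=(5, 5)) > 0
    out_invalid = _resample(touched.astype(float), coords, order=0) > 0

    planes = {}
    for name in ("values", "s0", "rsq"):
        a = getattr(rmap, name)
        bad = ~np.isfinite(a)
        filled = _fill_nearest(np.where(bad, 0.0, a), bad)
        out = _resample(filled, coords, order=3)
        out[out_invalid] = np.nan
        planes[name] = out
    planes["values"] = np.clip(planes["values"], 1e-9, None)
    planes["rsq"] = np.clip(planes["rsq"], 0.0, 1.0)

    return RelaxationMap(
        values=planes["values"],
        s0=planes["s0"],
        rsq=planes["rsq"],
        pixel_spacing=rmap.pixel_spacing / factor,
        contrast_label=rmap.contrast_label,
    )
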