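"""Synthetic femoral-head phantoms and paired cohorts.

Phantoms stack the banded anatomy seen on prepared images of the proximal
femur — epiphysis, growth plate, primary spongiosa, secondary spongiosa,
mature metaphysis — either as straight bands or concentric arcs, assign a
relaxation time and equilibrium signal per band, blur band transitions,
and emit magnitude images with Rician noise at each preparation time.
Ground truth (band label image, boundary polyline, true thicknesses and
band relaxation times) is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .morphometry import GrowthPlateBoundary
from .relaxometry import CONTRAST_LABELS, MapSeries

__all__ = [
    "BAND_ORDER",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "generate_phantom",
    "generate_paired_cohort",
    "control_phantom_spec",
    "ischemic_phantom_spec",
]

BAND_ORDER = (
    "epiphysis",
    "growth_plate",
    "primary_spongiosa",
    "secondary_spongiosa",
    "mature_metaphysis",
)

PREP_TIMES_MS = {
    "T2": (0.0, 20.0, 40.0, 60.0, 80.0),
    "T1rho": (0.0, 20.0, 40.0, 60.0, 80.0),
    "aT1rho": (0.0, 24.0, 48.0, 72.0, 96.0),
    "aT2rho": (0.0, 24.0, 48.0, 72.0, 96.0),
}

# Control-pattern band relaxation times (ms). Spongiosa and mature-metaphysis
# values follow measured control means; epiphysis and growth-plate values are
# not measured quantities — they are qualitative choices (cartilage long,
# epiphysis moderate) that only shape the proximal end of the profile.
CONTROL_BAND_T_MS = {
    "T2": {
        "epiphysis": 70.0,
        "growth_plate": 150.0,
        "primary_spongiosa": 57.9,
        "secondary_spongiosa": 92.0,
        "mature_metaphysis": 65.4,
    },
    "T1rho": {
        "epiphysis": 110.0,
        "growth_plate": 230.0,
        "primary_spongiosa": 87.3,
        "secondary_spongiosa": 145.0,
        "mature_metaphysis": 103.1,
    },
    "aT1rho": {
        "epiphysis": 250.0,
        "growth_plate": 430.0,
        "primary_spongiosa": 176.8,
        "secondary_spongiosa": 300.0,
        "mature_metaphysis": 245.0,
    },
    "aT2rho": {
        "epiphysis": 95.0,
        "growth_plate": 190.0,
        "primary_spongiosa": 75.1,
        "secondary_spongiosa": 125.0,
        "mature_metaphysis": 88.0,
    },
}

# Ischemic-pattern overrides (measured ischemic means); epiphysis and growth
# plate kept at control values.
ISCHEMIC_BAND_T_MS = {
    "T2": {"primary_spongiosa": 64.6, "secondary_spongiosa": 78.5, "mature_metaphysis": 64.9},
    "T1rho": {"primary_spongiosa": 86.5, "secondary_spongiosa": 113.0, "mature_metaphysis": 102.3},
    "aT1rho": {"primary_spongiosa": 183.0, "secondary_spongiosa": 258.0, "mature_metaphysis": 249.0},
    "aT2rho": {"primary_spongiosa": 78.0, "secondary_spongiosa": 99.0, "mature_metaphysis": 86.9},
}

CONTROL_WIDTHS_MM = {
    "epiphysis": 3.0,
    "growth_plate": 1.4,
    "primary_spongiosa": 1.12,
    "secondary_spongiosa": 1.90,
}
ISCHEMIC_WIDTHS_MM = {
    "epiphysis": 3.0,
    "growth_plate": 1.4,
    "primary_spongiosa": 0.91,
    "secondary_spongiosa": 1.13,
}

DEFAULT_BAND_S0 = {
    "epiphysis": 400.0,
    "growth_plate": 550.0,
    "primary_spongiosa": 350.0,
    "secondary_spongiosa": 520.0,
    "mature_metaphysis": 420.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue parameters and noise model of one phantom.

    ``band_widths_mm`` covers the first four bands; the mature metaphysis
    fills the remaining image extent. ``snr`` is the ratio of the mean
    equilibrium signal to the Rician noise sigma (``inf`` disables noise).
    """

    band_widths_mm: dict = field(default_factory=lambda: dict(CONTROL_WIDTHS_MM))
    band_T_ms: dict = field(default_factory=lambda: {k: dict(v) for k, v in CONTROL_BAND_T_MS.items()})
    band_S0: dict = field(default_factory=lambda: dict(DEFAULT_BAND_S0))
    geometry: str = "straight_bands"
    transition_sigma_mm: float = 0.3
    image_shape: tuple[int, int] = (30, 36)
    pixel_spacing_mm: float = 0.52
    snr: float = 50.0
    seed: int = 0
    contrasts: tuple[str, ...] = CONTRAST_LABELS
    arc_radius_mm: float = 25.0
    arc_span_deg: float = 40.0

    def __post_init__(self) -> None:
        if self.geometry not in ("straight_bands", "arc_bands"):
            raise ValueError("geometry must be 'straight_bands' or 'arc_bands'")
        for band in BAND_ORDER[:4]:
            if band not in self.band_widths_mm or not self.band_widths_mm[band] > 0:
                raise ValueError(f"band_widths_mm must give a positive width for {band!r}")
        for contrast in self.contrasts:
            if contrast not in CONTRAST_LABELS:
                raise ValueError(f"unknown contrast {contrast!r}")
            bt = self.band_T_ms[contrast]
            for band in BAND_ORDER:
                if not bt[band] > 0:
                    raise ValueError(f"band_T_ms[{contrast!r}][{band!r}] must be positive")
            if not bt["growth_plate"] > bt["primary_spongiosa"]:
                raise ValueError("control pattern requires growth-plate T > primary-spongiosa T")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if not self.transition_sigma_mm >= 0:
            raise ValueError("transition_sigma_mm must be >= 0")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    region_mask: np.ndarray
    boundary: GrowthPlateBoundary
    true_ps_thickness: float
    true_ss_thickness: float
    true_band_T: dict


def _band_edges(spec: PhantomSpec) -> np.ndarray:
    widths = [spec.band_widths_mm[b] for b in BAND_ORDER[:4]]
    return np.concatenate([[0.0], np.cumsum(widths)])


def _distance_field(spec: PhantomSpec) -> np.ndarray:
    """Signed distance (mm) of each pixel centre along the band axis."""
    h, w = spec.image_shape
    sp = spec.pixel_spacing_mm
    yy, xx = np.meshgrid(np.arange(h) * sp, np.arange(w) * sp, indexing="ij")
    if spec.geometry == "straight_bands":
        return yy
    # arc bands: concentric around a centre above the image
    cx = (w - 1) * sp / 2.0
    cy = -spec.arc_radius_mm
    return np.hypot(yy - cy, xx - cx) - spec.arc_radius_mm


def _truth_boundary(spec: PhantomSpec) -> GrowthPlateBoundary:
    h, w = spec.image_shape
    sp = spec.pixel_spacing_mm
    d0 = spec.band_widths_mm["epiphysis"]
    margin = 2.0 * sp
    if spec.geometry == "straight_bands":
        xs = np.arange(margin, (w - 1) * sp - margin, sp / 2.0)
        pts = np.column_stack([xs, np.full_like(xs, d0)])
        hint = np.array([0.0, 1.0])
    else:
        cx = (w - 1) * sp / 2.0
        cy = -spec.arc_radius_mm
        r = spec.arc_radius_mm + d0
        half = np.deg2rad(spec.arc_span_deg) / 2.0
        theta = np.linspace(np.pi / 2 - half, np.pi / 2 + half, 181)
        pts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        hint = np.array([0.0, 1.0])
    return GrowthPlateBoundary(points=pts, distal_hint=hint)


def generate_phantom(spec: PhantomSpec) -> tuple[dict[str, MapSeries], PhantomTruth]:
    """Build the banded phantom and its prepared image series per contrast.

    For each prep time ``t`` the magnitude image is
    ``Rician(S0 * exp(-t / T), sigma = mean(S0) / snr)`` with a seeded
    generator, so identical specs produce bit-identical outputs.
    """
    edges = _band_edges(spec)
    h, w = spec.image_shape
    sp = spec.pixel_spacing_mm
    extent = (h - 1) * sp
    if edges[-1] >= extent:
        raise ValueError(
            f"bands span {edges[-1]:.1f} mm but the image extent is only {extent:.1f} mm"
        )
    dist = _distance_field(spec)
    label = np.searchsorted(edges[1:], dist, side="right")
    label = np.clip(label, 0, len(BAND_ORDER) - 1)

    rng = np.random.default_rng(spec.seed)
    series: dict[str, MapSeries] = {}

    def banded_field(per_band: dict) -> np.ndarray:
        # Gaussian-blurred band steps evaluated on the continuous distance
        # field (an erf ramp per transition): equivalent to blurring an
        # infinitely resolved label image, free of pixel-quantization jitter
        vals = [per_band[b] for b in BAND_ORDER]
        out = np.full((h, w), vals[0], dtype=float)
        for edge, (v0, v1) in zip(edges[1:], zip(vals[:-1], vals[1:])):
            if spec.transition_sigma_mm > 0:
                ramp = 0.5 * (1.0 + erf((dist - edge) / (spec.transition_sigma_mm * np.sqrt(2.0))))
            else:
                ramp = (dist >= edge).astype(float)
            out += (v1 - v0) * ramp
        return out

    s0_field = banded_field(spec.band_S0)

    for contrast in spec.contrasts:
        t_field = banded_field(spec.band_T_ms[contrast])
        prep = np.array(PREP_TIMES_MS[contrast])
        clean = s0_field[np.newaxis] * np.exp(-prep[:, np.newaxis, np.newaxis] / t_field)
        if np.isinf(spec.snr):
            images = clean
        else:
            noise_sigma = float(np.mean(list(spec.band_S0.values()))) / spec.snr
            n1 = rng.normal(0.0, noise_sigma, clean.shape)
            n2 = rng.normal(0.0, noise_sigma, clean.shape)
            images = np.hypot(clean + n1, n2)
        series[contrast] = MapSeries(
            images=images,
            prep_times=prep,
            pixel_spacing=sp,
            contrast_label=contrast,
        )

    truth = PhantomTruth(
        region_mask=label,
        boundary=_truth_boundary(spec),
        true_ps_thickness=spec.band_widths_mm["primary_spongiosa"],
        true_ss_thickness=spec.band_widths_mm["secondary_spongiosa"],
        true_band_T={c: dict(spec.band_T_ms[c]) for c in spec.contrasts},
    )
    return series, truth


def control_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Phantom with the control-pattern band parameters."""
    return PhantomSpec(seed=seed, **overrides)


def ischemic_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Phantom preset with thinned, lower-T spongiosa bands."""
    band_t = {c: dict(CONTROL_BAND_T_MS[c]) for c in CONTRAST_LABELS}
    for contrast, upd in ISCHEMIC_BAND_T_MS.items():
        band_t[contrast].update(upd)
    kwargs = dict(band_widths_mm=dict(ISCHEMIC_WIDTHS_MM), band_T_ms=band_t, seed=seed)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling model for a synthetic paired cohort.

    Per subject and metric: ``control ~ Normal(control_mean, control_sd)``
    and ``ischemic = control + delta`` with
    ``delta ~ Normal(diff_mean, diff_sd)``, all draws independent.
    """

    n_subjects: int
    control_means: dict
    control_sds: dict
    diff_means: dict
    diff_sds: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        keys = set(self.control_means)
        for name in ("control_sds", "diff_means", "diff_sds"):
            if set(getattr(self, name)) != keys:
                raise ValueError(f"{name} must cover the same metrics as control_means")
        for sds in (self.control_sds, self.diff_sds):
            if any(v < 0 for v in sds.values()):
                raise ValueError("standard deviations must be >= 0")


def generate_paired_cohort(spec: CohortSpec, rng: np.random.Generator | None = None):
    """Tidy table of paired control/ischemic values, one row per subject x metric."""
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_subjects):
        sid = f"s{i + 1:03d}"
        for metric in spec.control_means:
            control = rng.normal(spec.control_means[metric], spec.control_sds[metric])
            delta = rng.normal(spec.diff_means[metric], spec.diff_sds[metric])
            rows.append(
                {
                    "subject_id": sid,
                    "metric": metric,
                    "control": control,
                    "ischemic": control + delta,
                }
            )
    return pd.DataFrame(rows)
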