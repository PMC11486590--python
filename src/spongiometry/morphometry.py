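"""Growth-plate-anchored line-profile morphometry of the metaphyseal spongiosa.

Line profiles start on the proximal growth-plate boundary and run distally
along the local boundary normal. Profiles are combined per depth with an
iteratively sigma-clipped mean, and six measurements are read off the
average profile:

* value and depth of the first qualifying minimum (primary spongiosa),
* value and depth of the first qualifying maximum after it (secondary
  spongiosa),
* mean value over a short window placed several inter-landmark distances
  further down (mature metaphysis),
* primary-spongiosa thickness — distance between the inflection points
  flanking the minimum,
* secondary-spongiosa thickness — twice the distance from the inflection
  point between the two landmarks to the maximum,
* total thickness — their sum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from shapely.geometry import LineString

from .relaxometry import RelaxationMap

__all__ = [
    "GrowthPlateBoundary",
    "LineProfileSet",
    "AverageProfile",
    "MorphometryResult",
    "MorphometryConfig",
    "LandmarkError",
    "extract_line_profiles",
    "average_profiles",
    "locate_landmarks",
    "measure_femoral_head",
    "sigma_clipped_mean",
]


class LandmarkError(RuntimeError):
    """A required profile landmark could not be located."""

    def __init__(self, landmark: str, message: str):
        self.landmark = landmark
        super().__init__(f"{landmark}: {message}")


@dataclass(frozen=True)
class GrowthPlateBoundary:
    """Polyline tracing the proximal growth-plate boundary, physical mm.

    ``distal_hint`` is a 2-vector pointing (roughly) toward the metaphysis;
    it orients the profile direction at every boundary point.
    """

    points: np.ndarray
    distal_hint: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        hint = np.asarray(self.distal_hint, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("boundary needs >= 3 (x, y) points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise ValueError("consecutive boundary points must be distinct")
        if not LineString(pts).is_simple:
            raise ValueError("boundary polyline must not self-intersect")
        norm = np.linalg.norm(hint)
        if hint.shape != (2,) or norm < 1e-12:
            raise ValueError("distal_hint must be a nonzero 2-vector")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "distal_hint", hint / norm)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable parameters of the profile analysis (lengths in mm)."""

    profile_length: float = 10.0
    sample_step: float = 0.17
    smoothing_window: float = 0.51
    min_prominence: float = 0.02
    clip_sigma: float = 3.0
    mm_window: float = 0.7
    mm_offset_factor: float = 4.0
    n_lines_range: tuple[int, int] = (10, 5000)

    def __post_init__(self) -> None:
        for name in (
            "profile_length",
            "sample_step",
            "smoothing_window",
            "min_prominence",
            "clip_sigma",
            "mm_window",
            "mm_offset_factor",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.smoothing_window < self.profile_length / 4:
            raise ValueError("smoothing_window must be < profile_length / 4")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class LineProfileSet:
    """Per-line relaxation values on a common depth grid (NaN past truncation)."""

    depths: np.ndarray
    profiles: np.ndarray
    line_origins: np.ndarray
    truncated: np.ndarray

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        profiles = np.asarray(self.profiles, dtype=float)
        if profiles.ndim != 2 or profiles.shape[1] != depths.size:
            raise ValueError("profiles must be (n_lines, n_depths)")
        if depths[0] != 0 or np.any(np.diff(depths) <= 0):
            raise ValueError("depths must start at 0 and increase")
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "profiles", profiles)
        object.__setattr__(self, "line_origins", np.asarray(self.line_origins, dtype=float))
        object.__setattr__(self, "truncated", np.asarray(self.truncated, dtype=bool))

    @property
    def n_lines(self) -> int:
        return self.profiles.shape[0]


@dataclass(frozen=True)
class AverageProfile:
    """Robust mean relaxation time versus depth from the boundary."""

    depths: np.ndarray
    values: np.ndarray
    n_contributing: np.ndarray


@dataclass(frozen=True)
class MorphometryResult:
    """The six per-femoral-head measurements (values ms, lengths mm)."""

    ps_value: float
    ps_depth: float
    ss_value: float
    ss_depth: float
    mm_value: float
    ps_thickness: float
    ss_thickness: float
    total_thickness: float
    contrast_label: str
    provenance: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.ps_depth < self.ss_depth:
            raise ValueError("expected 0 < ps_depth < ss_depth")
        if not self.ps_value < self.ss_value:
            raise ValueError("expected ps_value < ss_value")
        if not (self.ps_thickness > 0 and self.ss_thickness > 0):
            raise ValueError("thicknesses must be positive")
        if self.total_thickness != self.ps_thickness + self.ss_thickness:
            raise ValueError("total_thickness must equal ps_thickness + ss_thickness")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("provenance")
        return d


METRICS = (
    "ps_value",
    "ss_value",
    "mm_value",
    "ps_thickness",
    "ss_thickness",
    "total_thickness",
)


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Arc-length resampling at ``step`` spacing over the half-open polyline.

    The number of samples is ``round(length / step)`` so a boundary of
    length ``n * step`` yields exactly ``n`` lines.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(round(total / step)), 2)
    targets = np.arange(n) * step
    x = np.interp(targets, s, points[:, 0])
    y = np.interp(targets, s, points[:, 1])
    return np.column_stack([x, y])


def _smoothed_normals(origins: np.ndarray, hint: np.ndarray, sigma_samples: float) -> np.ndarray:
    tang = np.gradient(origins, axis=0)
    if sigma_samples > 0 and origins.shape[0] > 4:
        tang = ndimage.gaussian_filter1d(tang, sigma_samples, axis=0, mode="nearest")
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = tang / np.clip(norms, 1e-12, None)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    flip = normals @ hint < 0
    normals[flip] *= -1
    return normals


def extract_line_profiles(
    rmap: RelaxationMap,
    boundary: GrowthPlateBoundary,
    config: MorphometryConfig | None = None,
) -> LineProfileSet:
    """Sample one profile per resampled boundary point, distally oriented.

    Each line starts on the boundary and follows the locally smoothed
    boundary normal (oriented by ``distal_hint``) for ``profile_length`` mm,
    sampled every ``sample_step`` mm by bilinear interpolation. Lines that
    leave the finite region of the map are truncated (NaN) and flagged.
    """
    config = config or MorphometryConfig()
    sp = rmap.pixel_spacing
    origins = _resample_polyline(boundary.points, config.sample_step)
    normals = _smoothed_normals(
        origins, boundary.distal_hint, config.smoothing_window / config.sample_step
    )
    depths = np.arange(0.0, config.profile_length + 1e-9, config.sample_step)

    # physical (x, y) mm -> array (row, col) index; pixel centre (0,0) at origin
    pts = origins[:, np.newaxis, :] + depths[np.newaxis, :, np.newaxis] * normals[:, np.newaxis, :]
    rows = pts[..., 1] / sp
    cols = pts[..., 0] / sp
    coords = np.stack([rows.ravel(), cols.ravel()])

    invalid = ~rmap.finite_mask
    filled = np.where(invalid, 0.0, rmap.values)
    if invalid.any():
        idx = ndimage.distance_transform_edt(invalid, return_distances=False, return_indices=True)
        filled = filled[tuple(idx)]
    vals = ndimage.map_coordinates(filled, coords, order=1, mode="constant", cval=np.nan)
    bad = ndimage.map_coordinates(
        invalid.astype(float), coords, order=1, mode="constant", cval=1.0
    )
    vals = np.where(bad > 1e-9, np.nan, vals).reshape(pts.shape[:2])

    if np.any(~np.isfinite(vals[:, 0])):
        raise ValueError("boundary lies outside the finite region of the map")

    # truncate each line at its first invalid sample
    finite = np.isfinite(vals)
    first_bad = np.where(finite.all(axis=1), vals.shape[1], np.argmin(finite, axis=1))
    col_idx = np.arange(vals.shape[1])
    vals = np.where(col_idx[np.newaxis, :] < first_bad[:, np.newaxis], vals, np.nan)
    truncated = first_bad < vals.shape[1]

    usable = np.isfinite(vals).mean(axis=1) >= 0.5
    if usable.sum() < config.n_lines_range[0]:
        raise ValueError(
            f"only {int(usable.sum())} usable lines "
            f"(need >= {config.n_lines_range[0]}): degenerate geometry"
        )
    if vals.shape[0] > config.n_lines_range[1]:
        raise ValueError(f"{vals.shape[0]} lines exceeds configured maximum")

    return LineProfileSet(depths=depths, profiles=vals, line_origins=origins, truncated=truncated)


def sigma_clipped_mean(
    x: np.ndarray, clip_sigma: float = 3.0, max_iter: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise iteratively sigma-clipped mean of ``x`` (NaN-aware).

    Values beyond ``clip_sigma`` sample standard deviations from the
    current mean are dropped and the mean re-estimated, until convergence
    or ``max_iter`` rounds. Returns (mean, n_contributing) per column.
    """
    x = np.asarray(x, dtype=float)
    keep = np.isfinite(x)
    for _ in range(max_iter):
        n = keep.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(keep, x, 0.0).sum(axis=0) / np.maximum(n, 1)
            var = (np.where(keep, x - mean, 0.0) ** 2).sum(axis=0) / np.maximum(n - 1, 1)
        sd = np.sqrt(var)
        with np.errstate(invalid="ignore"):
            new_keep = keep & (np.abs(x - mean) <= clip_sigma * np.maximum(sd, 1e-300))
        # never clip to nothing; a zero-spread column keeps all members
        new_keep |= keep & (sd[np.newaxis, :] == 0)
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    n = keep.sum(axis=0)
    mean = np.where(keep, x, 0.0).sum(axis=0) / np.maximum(n, 1)
    mean = np.where(n > 0, mean, np.nan)
    return mean, n


def average_profiles(
    profile_set: LineProfileSet, config: MorphometryConfig | None = None
) -> AverageProfile:
    """Combine lines per depth with the iteratively sigma-clipped mean."""
    config = config or MorphometryConfig()
    if profile_set.n_lines < 10:
        raise ValueError("need at least 10 profiles to average")
    mean, n = sigma_clipped_mean(profile_set.profiles, config.clip_sigma)
    sparse = n < 3
    if sparse.any():
        mean = np.where(sparse, np.nan, mean)
        warnings.warn(
            f"{int(sparse.sum())} depth(s) have < 3 contributing lines; set to NaN",
            stacklevel=2,
        )
    return AverageProfile(depths=profile_set.depths, values=mean, n_contributing=n)


def _odd_window(width_mm: float, step: float, n: int) -> int:
    w = max(int(round(width_mm / step)), 3)
    if w % 2 == 0:
        w += 1
    return min(w, n - 1 if (n - 1) % 2 == 1 else n - 2)


def _parabolic_refine(s: np.ndarray, depths: np.ndarray, i: int) -> tuple[float, float]:
    if i <= 0 or i >= len(s) - 1:
        return float(depths[i]), float(s[i])
    denom = s[i - 1] - 2 * s[i] + s[i + 1]
    if abs(denom) < 1e-300:
        return float(depths[i]), float(s[i])
    offset = 0.5 * (s[i - 1] - s[i + 1]) / denom
    offset = float(np.clip(offset, -1.0, 1.0))
    step = depths[1] - depths[0]
    value = s[i] - 0.25 * (s[i - 1] - s[i + 1]) * offset
    return float(depths[i] + offset * step), float(value)


def _refine_extremum(
    s: np.ndarray, depths: np.ndarray, i: int, sign: float, prominence: float
) -> tuple[float, float]:
    """Quadratic refinement of a discrete extremum.

    The quadratic is fitted over the contiguous samples within a small
    tolerance (a quarter of the prominence threshold) of the extremal
    value, so flat-topped extrema resolve to their apex instead of an
    arbitrary sample of the plateau; for sharp extrema this reduces to the
    3-point parabola.
    """
    tol = 0.25 * prominence
    val = s[i]
    lo = i
    while lo > 0 and sign * (val - s[lo - 1]) <= tol:
        lo -= 1
    hi = i
    while hi < len(s) - 1 and sign * (val - s[hi + 1]) <= tol:
        hi += 1
    lo, hi = max(lo - 1, 0), min(hi + 1, len(s) - 1)
    if hi - lo < 2:
        return _parabolic_refine(s, depths, i)
    xs = depths[lo : hi + 1] - depths[i]
    coef = np.polyfit(xs, s[lo : hi + 1], 2)
    if sign * coef[0] >= 0:  # wrong curvature — fall back to 3-point parabola
        return _parabolic_refine(s, depths, i)
    v = float(np.clip(-coef[1] / (2 * coef[0]), xs[0], xs[-1]))
    return float(depths[i] + v), float(np.polyval(coef, v))


def _crossing_near(d2: np.ndarray, depths: np.ndarray, j: int) -> float | None:
    """Second-derivative zero crossing nearest sample ``j`` (linear interp)."""
    sgn = np.sign(d2)
    idx = np.where(sgn[:-1] * sgn[1:] < 0)[0]
    if idx.size == 0:
        return None
    k = idx[np.argmin(np.abs(idx - j))]
    frac = d2[k] / (d2[k] - d2[k + 1])
    return float(depths[k] + frac * (depths[k + 1] - depths[k]))


def locate_landmarks(
    profile: AverageProfile, config: MorphometryConfig | None = None, contrast_label: str = "T2"
) -> MorphometryResult:
    """Read the six measurements off a finite average profile.

    The profile is smoothed with an order-2 moving polynomial filter; the
    landmarks are the first prominent minimum and the first prominent
    maximum after it, each refined by a quadratic through the three samples
    around the discrete extremum. Inflection points are zero crossings of
    the smoothed second derivative.
    """
    config = config or MorphometryConfig()
    depths = profile.depths
    v = profile.values
    if not np.all(np.isfinite(v)):
        raise ValueError("average profile must be finite over the full depth grid")
    step = float(depths[1] - depths[0])
    win = _odd_window(config.smoothing_window, step, len(v))
    s = signal.savgol_filter(v, win, polyorder=2)
    prominence = config.min_prominence * (s.max() - s.min())
    if prominence <= 0:
        raise LandmarkError("primary spongiosa", "profile has no dynamic range")

    minima, _ = signal.find_peaks(-s, prominence=prominence)
    if minima.size == 0:
        raise LandmarkError("primary spongiosa", "no qualifying first minimum found")
    ps_idx = int(minima[0])

    maxima, _ = signal.find_peaks(s, prominence=prominence)
    maxima = maxima[maxima > ps_idx]
    if maxima.size == 0:
        raise LandmarkError(
            "secondary spongiosa", "no qualifying maximum after the first minimum"
        )
    ss_idx = int(maxima[0])

    ps_depth, ps_value = _refine_extremum(s, depths, ps_idx, -1.0, prominence)
    ss_depth, ss_value = _refine_extremum(s, depths, ss_idx, +1.0, prominence)

    # inflection points: zero crossings of the smoothed second derivative,
    # anchored at the dominant slope extremum on each flank of the minimum
    # so that small oscillations cannot hijack the crossing choice
    d1 = signal.savgol_filter(s, win, polyorder=2, deriv=1, delta=step)
    d2 = signal.savgol_filter(s, win, polyorder=2, deriv=2, delta=step)
    infl_left = infl_mid = None
    if ps_idx > 1:
        j_left = int(np.argmin(d1[:ps_idx]))
        infl_left = _crossing_near(d2[: ps_idx + 1], depths[: ps_idx + 1], j_left)
    if ss_idx - ps_idx > 1:
        j_mid = ps_idx + int(np.argmax(d1[ps_idx : ss_idx + 1]))
        infl_mid = _crossing_near(
            d2[ps_idx : ss_idx + 1], depths[ps_idx : ss_idx + 1], j_mid - ps_idx
        )
    if infl_left is None or not infl_left < ps_depth:
        raise LandmarkError("primary spongiosa inflection", "no inflection proximal to the minimum")
    if infl_mid is None or not ps_depth < infl_mid < ss_depth:
        raise LandmarkError(
            "spongiosa boundary inflection", "no inflection between minimum and maximum"
        )

    ps_thickness = infl_mid - infl_left
    ss_thickness = 2.0 * (ss_depth - infl_mid)

    centre = ps_depth + config.mm_offset_factor * (ss_depth - ps_depth)
    lo, hi = centre - config.mm_window / 2, centre + config.mm_window / 2
    if hi > depths[-1] + 1e-9:
        raise ValueError(
            f"mature-metaphysis window [{lo:.2f}, {hi:.2f}] mm exceeds the profile "
            f"end ({depths[-1]:.2f} mm); increase profile_length"
        )
    in_win = (depths >= lo - 1e-9) & (depths <= hi + 1e-9)
    mm_value = float(v[in_win].mean())

    return MorphometryResult(
        ps_value=ps_value,
        ps_depth=ps_depth,
        ss_value=ss_value,
        ss_depth=ss_depth,
        mm_value=mm_value,
        ps_thickness=ps_thickness,
        ss_thickness=ss_thickness,
        total_thickness=ps_thickness + ss_thickness,
        contrast_label=contrast_label,
    )


def measure_femoral_head(
    rmap: RelaxationMap,
    boundary: GrowthPlateBoundary,
    config: MorphometryConfig | None = None,
) -> MorphometryResult:
    """extract -> average -> locate, with provenance attached."""
    config = config or MorphometryConfig()
    profile_set = extract_line_profiles(rmap, boundary, config)
    profile = average_profiles(profile_set, config)
    result = locate_landmarks(profile, config, contrast_label=rmap.contrast_label)
    provenance = {
        "n_lines": profile_set.n_lines,
        "n_truncated": int(profile_set.truncated.sum()),
        "config_hash": config.hash(),
    }
    return dataclasses.replace(result, provenance=provenance)
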