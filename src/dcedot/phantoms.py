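"""Synthetic phantoms, contrast series and ICG-like uptake curves.

Everything the pipeline consumes is generated here with known ground truth:
arbitrarily shaped 2-D phantom geometries (stand-ins for MR-imaged agar
phantoms), the B-series of absorption contrasts (background mu_a = 0.01 mm^-1,
mu_s' = 0.6 mm^-1, 10 mm inclusions at object-to-background contrasts 1-8),
the homogeneous epoxy calibration phantom (mu_a = 0.006, mu_s' = 1.0 mm^-1),
a 32-frame indocyanine-green bolus series with injection during the 7th frame
at 16 s per frame, and measurement frames corrupted by optode coupling
factors and instrument noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage.draw import polygon2mask

from dcedot.forward import ForwardConfig, MeasurementFrame, OpticalMap, forward_measurements
from dcedot.meshgen import DEFAULT_PIXEL_MM, Mesh2D, OptodeLayout, mm_to_pixels, polygon_area

BACKGROUND_MUA = 0.01      # mm^-1
BACKGROUND_MUSP = 0.6      # mm^-1
CALIBRATION_MUA = 0.006    # mm^-1
CALIBRATION_MUSP = 1.0     # mm^-1
B_SERIES_OBC = (1, 2, 4, 6, 8)


@dataclass
class PhantomSpec:
    """Geometry and optical make-up of one contrast phantom series."""

    boundary_polygon: np.ndarray
    inclusion_center: np.ndarray
    inclusion_diameter: float = 10.0
    background_mua: float = BACKGROUND_MUA
    background_musp: float = BACKGROUND_MUSP
    contrast_levels: tuple = B_SERIES_OBC

    def __post_init__(self):
        self.boundary_polygon = np.asarray(self.boundary_polygon, dtype=float)
        self.inclusion_center = np.asarray(self.inclusion_center, dtype=float)
        if self.inclusion_diameter <= 0:
            raise ValueError("inclusion diameter must be positive")
        if any(c < 1 for c in self.contrast_levels):
            raise ValueError("contrast levels must all be >= 1")
        from shapely.geometry import Point, Polygon
        shp = Polygon(self.boundary_polygon)
        if not shp.contains(Point(*self.inclusion_center).buffer(self.inclusion_diameter / 2)):
            raise ValueError("inclusion must lie strictly inside the boundary polygon")

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as f:
            json.dump({"boundary_polygon": self.boundary_polygon.tolist(),
                       "inclusion_center": self.inclusion_center.tolist(),
                       "inclusion_diameter": self.inclusion_diameter,
                       "background_mua": self.background_mua,
                       "background_musp": self.background_musp,
                       "contrast_levels": list(self.contrast_levels)}, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        import json
        with open(path) as f:
            doc = json.load(f)
        doc["contrast_levels"] = tuple(doc["contrast_levels"])
        return cls(**{k: np.array(v) if k in ("boundary_polygon", "inclusion_center")
                      else v for k, v in doc.items()})

    def inclusion_polygon(self, n: int = 48) -> np.ndarray:
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = self.inclusion_diameter / 2
        return self.inclusion_center + r * np.stack([np.cos(th), np.sin(th)], axis=1)

    def inclusion_nodes(self, mesh: Mesh2D) -> np.ndarray:
        d = np.linalg.norm(mesh.nodes - self.inclusion_center, axis=1)
        return d <= self.inclusion_diameter / 2


@dataclass
class NoiseModel:
    """Multiplicative Gaussian amplitude noise, additive Gaussian phase noise.

    Defaults (1% amplitude, 0.1 degree phase) are a conventional
    frequency-domain instrument model.
    """

    amplitude_cv: float = 0.01
    phase_sd: float = np.deg2rad(0.1)
    seed: int = 0

    def __post_init__(self):
        if self.amplitude_cv < 0 or self.phase_sd < 0:
            raise ValueError("noise levels must be non-negative")

    def apply(self, frame: MeasurementFrame) -> MeasurementFrame:
        rng = np.random.default_rng(self.seed)
        amp = frame.amplitude * (1.0 + self.amplitude_cv * rng.standard_normal(frame.amplitude.shape))
        amp = np.maximum(amp, 1e-300)
        ph = frame.phase + self.phase_sd * rng.standard_normal(frame.phase.shape)
        return MeasurementFrame(amplitude=amp, phase=ph, frame_time=frame.frame_time)


@dataclass
class KineticProfile:
    """Gamma-variate bolus profile for the contrast-agent uptake.

    The enhancement is exactly zero before the injection frame (1-based,
    default the 7th frame) and follows (dt/tp)^alpha * exp(alpha(1 - dt/tp))
    afterwards with tp = rise_time and alpha = rise_time/decay_time, peaking
    at peak_delta_mua.
    """

    n_frames: int = 32
    frame_interval: float = 16.0        # s
    injection_frame: int = 7            # 1-based, matching frame numbering
    peak_delta_mua: float = 0.06        # mm^-1
    rise_time: float = 48.0             # s, time from onset to peak
    decay_time: float = 120.0           # s, exponential tail constant

    def __post_init__(self):
        if not (1 <= self.injection_frame <= self.n_frames):
            raise ValueError("injection_frame must lie within the series")
        if self.peak_delta_mua < 0:
            raise ValueError("peak_delta_mua must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def onset_time(self) -> float:
        return (self.injection_frame - 1) * self.frame_interval

    def delta_at(self, t) -> np.ndarray:
        """Inclusion absorption enhancement (mm^-1) at time t (s)."""
        t = np.asarray(t, dtype=float)
        dt = t - self.onset_time
        alpha = self.rise_time / self.decay_time
        with np.errstate(invalid="ignore"):
            shape = np.where(dt > 0,
                             (np.maximum(dt, 1e-12) / self.rise_time) ** alpha
                             * np.exp(alpha * (1 - np.maximum(dt, 1e-12) / self.rise_time)),
                             0.0)
        return self.peak_delta_mua * shape

    def curve(self) -> np.ndarray:
        return self.delta_at(self.times)


# ---------------------------------------------------------------------------
# shape library

def _radius_profile(shape_id: str, theta: np.ndarray) -> np.ndarray:
    if shape_id == "circle":
        return np.ones_like(theta)
    if shape_id == "ellipse":
        a, b = 1.0, 0.72
        return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if shape_id == "bean":
        return 0.92 + 0.15 * np.cos(theta) - 0.20 * np.cos(2 * theta)
    if shape_id == "triround":
        return 1.0 + 0.16 * np.cos(3 * theta)
    if shape_id == "pear":
        return 0.90 + 0.18 * np.cos(theta) + 0.08 * np.cos(2 * theta)
    if shape_id == "peanut":
        return 0.85 + 0.25 * np.cos(2 * theta)
    if shape_id == "dshape":
        r = np.ones_like(theta)
        cut = np.cos(theta) < -0.55
        r[cut] = -0.55 / np.cos(theta[cut])
        return r
    if shape_id == "blob":
        return 0.90 + 0.12 * np.cos(2 * theta) + 0.10 * np.sin(3 * theta) + 0.06 * np.cos(5 * theta)
    raise KeyError(shape_id)


SHAPE_IDS = ("circle", "ellipse", "bean", "triround", "pear", "peanut", "dshape", "blob")


def make_shape(shape_id: str, scale: float = 25.0, n_points: int = 144,
               pixel_mm: float = DEFAULT_PIXEL_MM):
    """Generate a named phantom outline and its binary mask.

    Parameters
    ----------
    shape_id : one of :data:`SHAPE_IDS`.
    scale : characteristic radius in mm (the circle's radius equals scale).

    Returns
    -------
    (polygon, mask) : CCW open polygon in mm (origin at image centre, y up)
        and the rasterised 2-D boolean mask at ``pixel_mm`` per pixel.
    """
    if shape_id not in SHAPE_IDS:
        raise KeyError(f"unknown shape {shape_id!r}; valid ids: {', '.join(SHAPE_IDS)}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    r = scale * _radius_profile(shape_id, theta)
    poly = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    if polygon_area(poly) < 0:
        poly = poly[::-1]

    extent = np.abs(poly).max()
    half = int(np.ceil(extent / pixel_mm)) + 4
    side = 2 * half + 1
    rc = mm_to_pixels(poly, (side, side), pixel_mm)
    mask = polygon2mask((side, side), rc)
    return poly, mask


def save_mask(mask: np.ndarray, path: str) -> None:
    """Write a mask as an 8-bit PNG/TIFF (0/255)."""
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def load_mask(path: str) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127


# ---------------------------------------------------------------------------
# optical-property series

def _require_inclusion_nodes(spec: PhantomSpec, mesh: Mesh2D) -> np.ndarray:
    inside = spec.inclusion_nodes(mesh)
    if not inside.any():
        raise ValueError(
            "no mesh node falls inside the inclusion; use a target edge length "
            f"below ~{spec.inclusion_diameter / 2:.1f} mm so the inclusion is resolvable")
    return inside


def make_phantom_series(spec: PhantomSpec, mesh: Mesh2D) -> list:
    """One OpticalMap per contrast level (inclusion mu_a = OBC x background)."""
    if list(spec.contrast_levels) != sorted(spec.contrast_levels):
        raise ValueError("contrast levels must be sorted ascending")
    inside = _require_inclusion_nodes(spec, mesh)
    maps = []
    for obc in spec.contrast_levels:
        m = OpticalMap.homogeneous(mesh, spec.background_mua, spec.background_musp)
        m.mua[inside] = obc * spec.background_mua
        maps.append(m)
    return maps


def make_calibration_phantom(mesh: Mesh2D) -> OpticalMap:
    """Homogeneous epoxy calibration phantom (mu_a 0.006, mu_s' 1.0 mm^-1)."""
    return OpticalMap.homogeneous(mesh, CALIBRATION_MUA, CALIBRATION_MUSP)


def make_icg_series(spec: PhantomSpec, profile: KineticProfile, mesh: Mesh2D,
                    background_fraction: float = 0.10) -> list:
    """Time series of OpticalMap frames following the bolus profile.

    The inclusion enhancement follows the gamma-variate curve; the background
    receives a scaled-down copy (default 10%) so difference images carry a
    realistic non-zero background.
    """
    inside = _require_inclusion_nodes(spec, mesh)
    deltas = profile.curve()
    frames = []
    for d in deltas:
        m = OpticalMap.homogeneous(mesh, spec.background_mua, spec.background_musp)
        m.mua += background_fraction * d
        m.mua[inside] = spec.background_mua + d
        frames.append(m)
    return frames


# ---------------------------------------------------------------------------
# measurement corruption

def simulate_measurements(mesh: Mesh2D, omap: OpticalMap, layout: OptodeLayout,
                          cfg: ForwardConfig = None, noise: NoiseModel = None,
                          coupling=None, frame_time: float = 0.0) -> MeasurementFrame:
    """Forward-model measurements with optional coupling factors and noise.

    amplitude(i, j) = s_i * d_j * |flux| * (1 + noise);  phase = lag + noise.
    """
    frame = forward_measurements(mesh, omap, layout, cfg, frame_time=frame_time)
    if coupling is not None:
        frame = coupling.apply(frame)
    if noise is not None:
        frame = noise.apply(frame)
    return frame
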