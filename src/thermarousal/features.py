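"""ROI geometry and the 11-dimensional per-frame feature vector.

Three rectangular regions of interest are placed from facial landmarks on
every registered frame — the nasal ridge (10×30 px, nostrils excluded) and
the two cheeks below the eyes (20×20 px each) — and rotated about the
inter-nostril reference point to follow head roll.  From them the pipeline
computes, per thermal frame:

* 3 luminance temperatures (LT), one per ROI;
* 3 pairwise LT differences (nose−right cheek, nose−left cheek,
  right−left cheek);
* 3 amounts of temperature change (ATC): the smoothed LT minus its value
  one second (30 frames) earlier;
* 2 eye-opening degrees (EOD): upper-to-lower eyelid distance per eye,
  low-pass filtered at the visible frame rate to suppress blink transients.

That makes 11 features, assembled into a :class:`FeatureMatrix` with a
per-frame validity mask (detector failures, out-of-bounds ROIs and the
first second, where the ATC lag is undefined, are masked).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .io_streams import AlignmentMap, LandmarkStream, ThermalSequence
from .preprocess import (ThermalNormalization, luminance_temperature,
                         temperature_to_luminance)

FRAME_WIDTH, FRAME_HEIGHT = 640, 480

FEATURE_COLUMNS = (
    "lt_nose", "lt_rcheek", "lt_lcheek",
    "dlt_nose_rcheek", "dlt_nose_lcheek", "dlt_rcheek_lcheek",
    "atc_nose", "atc_rcheek", "atc_lcheek",
    "eod_left", "eod_right",
)

ROI_NAMES = ("nose", "right_cheek", "left_cheek")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkScheme:
    """Named indices into the 106-point landmark convention.

    Defaults follow a common 106-point layout; remap them to whatever
    convention your detector emits.  "left"/"right" are image-side (left =
    smaller x in the registered frame).
    """

    left_eye_outer: int = 33
    left_eye_inner: int = 38
    left_eye_upper: int = 36
    left_eye_lower: int = 41
    right_eye_outer: int = 87
    right_eye_inner: int = 92
    right_eye_upper: int = 90
    right_eye_lower: int = 95
    nose_root: int = 51
    nose_apex: int = 54
    nostril_center: int = 60


@dataclass(frozen=True)
class ROISpec:
    """ROI rectangle sizes (width, height) in pixels and the cheek anchor.

    The cheek rectangle is centred on the eye's horizontal midpoint at a
    fraction ``cheek_drop`` of the vertical distance from the lower eyelid
    down to the nose apex — below the eye, clear of eye, nose and mouth.
    """

    nose_size: tuple[int, int] = (10, 30)
    cheek_size: tuple[int, int] = (20, 20)
    cheek_drop: float = 0.6

    def __post_init__(self) -> None:
        if min(self.nose_size) <= 0 or min(self.cheek_size) <= 0:
            raise ValueError("ROI sizes must be positive")


@dataclass(frozen=True)
class FilterConfig:
    """Temporal filtering parameters.

    ``smooth_window`` is the centred moving-average length for LT (3 frames:
    the target ±1); ``atc_lag`` the ATC lag in thermal frames (30 = one
    second at 30 fps); ``eod_cutoff_hz``/``eod_order`` the zero-phase
    low-pass applied to EOD at the visible rate (blink transients live well
    above 2 Hz, so a 0.5 Hz cutoff removes them while passing slow
    arousal-linked changes in lid aperture).
    """

    smooth_window: int = 3
    atc_lag: int = 30
    eod_cutoff_hz: float = 0.5
    eod_order: int = 2

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.atc_lag < 1:
            raise ValueError("atc_lag must be >= 1")
        if self.eod_cutoff_hz <= 0:
            raise ValueError("eod_cutoff_hz must be positive")


@dataclass
class FeatureMatrix:
    """Per-thermal-frame feature vectors with a validity mask."""

    values: np.ndarray  # (n_frames, 11)
    valid: np.ndarray   # (n_frames,) bool
    columns: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError(
                f"expected {len(self.columns)} feature columns, "
                f"got shape {self.values.shape}")
        if self.valid.shape != (self.values.shape[0],):
            raise ValueError("valid mask length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "frame", np.arange(self.n_frames))
        df["valid"] = self.valid.astype(int)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c not in ("frame", "valid")]
        return cls(values=df[cols].to_numpy(float),
                   valid=df["valid"].to_numpy(bool),
                   columns=tuple(cols))


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

def _rotate(points: np.ndarray, angle: float, center: np.ndarray) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return (points - center) @ rot.T + center


def _rect_corners(center: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    w, h = size
    dx, dy = w / 2.0, h / 2.0
    return center + np.array([[-dx, -dy], [dx, -dy], [dx, dy], [-dx, dy]])


def face_roll_angle(points: np.ndarray,
                    scheme: LandmarkScheme | None = None) -> float:
    """Head roll: angle of the line through the two eye outer corners."""
    scheme = scheme or LandmarkScheme()
    left = points[scheme.left_eye_outer]
    right = points[scheme.right_eye_outer]
    return float(np.arctan2(right[1] - left[1], right[0] - left[0]))


def place_rois(points: np.ndarray,
               scheme: LandmarkScheme | None = None,
               spec: ROISpec | None = None,
               frame_size: tuple[int, int] = (FRAME_WIDTH, FRAME_HEIGHT),
               ) -> dict[str, np.ndarray] | None:
    """Position the three ROIs from one 106-point landmark frame.

    All anchor geometry is evaluated in the de-rotated (upright) face frame
    and the axis-aligned rectangles are then rotated back by the roll angle
    about the inter-nostril point, so the returned polygons are exactly the
    upright ROIs rigidly rotated with the face.  Returns ``None`` when any
    ROI corner leaves the frame (the frame is then flagged invalid, not an
    error: transient head motion should not abort a run).
    """
    scheme = scheme or LandmarkScheme()
    spec = spec or ROISpec()
    pts = np.asarray(points, dtype=float)
    pivot = pts[scheme.nostril_center]
    roll = face_roll_angle(pts, scheme)
    up = _rotate(pts, -roll, pivot)  # upright-face coordinates

    nose_center = (up[scheme.nose_root] + up[scheme.nose_apex]) / 2.0

    def cheek_center(outer: int, inner: int, lower: int) -> np.ndarray:
        eye_x = (up[outer, 0] + up[inner, 0]) / 2.0
        lid_y = up[lower, 1]
        drop = spec.cheek_drop * (up[scheme.nose_apex, 1] - lid_y)
        return np.array([eye_x, lid_y + drop])

    centers = {
        "nose": nose_center,
        "right_cheek": cheek_center(scheme.right_eye_outer,
                                    scheme.right_eye_inner,
                                    scheme.right_eye_lower),
        "left_cheek": cheek_center(scheme.left_eye_outer,
                                   scheme.left_eye_inner,
                                   scheme.left_eye_lower),
    }
    sizes = {"nose": spec.nose_size, "right_cheek": spec.cheek_size,
             "left_cheek": spec.cheek_size}

    w, h = frame_size
    rois: dict[str, np.ndarray] = {}
    for name in ROI_NAMES:
        corners = _rotate(_rect_corners(centers[name], sizes[name]),
                          roll, pivot)
        if (corners[:, 0].min() < 0 or corners[:, 0].max() > w - 1
                or corners[:, 1].min() < 0 or corners[:, 1].max() > h - 1):
            return None
        rois[name] = corners
    return rois


def roi_mean_luminance(frame: np.ndarray, polygon: np.ndarray) -> float:
    """Mean of the pixel values whose centres fall inside a convex ROI.

    Pixel centres sit at integer (x, y) = (column, row).  A centre counts
    as inside when it is on the interior side of (or on, to 1e-9) every
    edge of the polygon, whose vertices must be in consistent order.
    """
    poly = np.asarray(polygon, dtype=float)
    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())), frame.shape[1] - 1)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())), frame.shape[0] - 1)
    if x1 < x0 or y1 < y0:
        raise ValueError("polygon covers no pixel centres")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = np.ones(xs.shape, dtype=bool)
    n = len(poly)
    # orientation from the shoelace signed area; a point inside a convex
    # polygon has edge cross products of that same sign on every edge
    area2 = sum(poly[i, 0] * poly[(i + 1) % n, 1]
                - poly[(i + 1) % n, 0] * poly[i, 1] for i in range(n))
    sign = 1.0 if area2 >= 0 else -1.0
    for i in range(n):
        ax, ay = poly[i]
        bx, by = poly[(i + 1) % n]
        cross = (bx - ax) * (ys - ay) - (by - ay) * (xs - ax)
        inside &= sign * cross >= -1e-9
    if not inside.any():
        raise ValueError("polygon covers no pixel centres")
    return float(frame[ys[inside], xs[inside]].mean())


# ---------------------------------------------------------------------------
# temporal feature operators
# ---------------------------------------------------------------------------

def lt_differences(lt_nose: np.ndarray, lt_rcheek: np.ndarray,
                   lt_lcheek: np.ndarray) -> tuple[np.ndarray, ...]:
    """Pairwise LT differences: nose−right, nose−left, right−left."""
    a, b, c = (np.asarray(x, dtype=float) for x in
               (lt_nose, lt_rcheek, lt_lcheek))
    if not (a.shape == b.shape == c.shape):
        raise ValueError("LT series must share one length")
    return a - b, a - c, b - c


def smooth_lt(lt: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Centred moving average over ``smooth_window`` frames; the window
    truncates to the available frames at the sequence edges."""
    cfg = cfg or FilterConfig()
    x = np.asarray(lt, dtype=float)
    if x.size == 0:
        return x.copy()
    k = cfg.smooth_window // 2
    kernel = np.ones(cfg.smooth_window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def atc(lt_smoothed: np.ndarray,
        cfg: FilterConfig | None = None) -> np.ndarray:
    """Amount of temperature change: smoothed LT minus its value
    ``atc_lag`` frames (one second) earlier.  The first ``atc_lag`` frames
    are undefined and returned as NaN."""
    cfg = cfg or FilterConfig()
    x = np.asarray(lt_smoothed, dtype=float)
    out = np.full_like(x, np.nan)
    if x.size > cfg.atc_lag:
        out[cfg.atc_lag:] = x[cfg.atc_lag:] - x[:-cfg.atc_lag]
    return out


def eod_raw(points: np.ndarray, eye: str,
            scheme: LandmarkScheme | None = None) -> float:
    """Eye-opening degree: Euclidean distance between the mid-upper-lid and
    mid-lower-lid landmarks of one eye, in pixels."""
    scheme = scheme or LandmarkScheme()
    if eye == "left":
        upper, lower = scheme.left_eye_upper, scheme.left_eye_lower
    elif eye == "right":
        upper, lower = scheme.right_eye_upper, scheme.right_eye_lower
    else:
        raise ValueError("eye must be 'left' or 'right'")
    pts = np.asarray(points, dtype=float)
    return float(np.linalg.norm(pts[upper] - pts[lower]))


def eod_filter(eod: np.ndarray, fps: float,
               cfg: FilterConfig | None = None) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth low-pass on an EOD series.

    Unit DC gain, so slow lid-aperture trends pass unchanged while blink
    transients are attenuated.
    """
    cfg = cfg or FilterConfig()
    if cfg.eod_cutoff_hz >= fps / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    x = np.asarray(eod, dtype=float)
    if x.size <= 3 * (2 * cfg.eod_order + 1):
        raise ValueError("series too short for zero-phase filtering")
    b, a = butter(cfg.eod_order, cfg.eod_cutoff_hz, btype="low", fs=fps)
    return filtfilt(b, a, x)


def interpolate_invalid(series: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly bridge invalid samples (held at the edges) so that temporal
    filters can run; the validity mask still excludes them downstream."""
    x = np.asarray(series, dtype=float).copy()
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise ValueError("no valid samples to interpolate from")
    idx = np.arange(x.size)
    x[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return x


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _assemble(lt: dict[str, np.ndarray], frame_valid: np.ndarray,
              eod_left: np.ndarray, eod_right: np.ndarray,
              cfg: FilterConfig) -> FeatureMatrix:
    """Shared tail of feature assembly from per-ROI LT and per-frame EOD
    already on the thermal timeline."""
    n = frame_valid.size
    filled = {k: interpolate_invalid(v, frame_valid) for k, v in lt.items()}
    d1, d2, d3 = lt_differences(filled["nose"], filled["right_cheek"],
                                filled["left_cheek"])
    cols = [filled["nose"], filled["right_cheek"], filled["left_cheek"],
            d1, d2, d3]
    for name in ROI_NAMES:
        cols.append(atc(smooth_lt(filled[name], cfg), cfg))
    cols.extend([eod_left, eod_right])
    values = np.column_stack(cols)
    valid = frame_valid & (np.arange(n) >= cfg.atc_lag)
    values[:cfg.atc_lag, 6:9] = np.nan  # ATC undefined inside the lag
    return FeatureMatrix(values=values, valid=valid)


def _eod_tracks(landmarks: LandmarkStream, amap: AlignmentMap,
                cfg: FilterConfig, scheme: LandmarkScheme,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Filtered EOD at the visible rate, sampled onto the thermal timeline."""
    nv = landmarks.n_frames
    raw = {eye: np.full(nv, np.nan) for eye in ("left", "right")}
    for i in range(nv):
        if landmarks.valid[i]:
            for eye in ("left", "right"):
                raw[eye][i] = eod_raw(landmarks.points[i], eye, scheme)
    out = []
    for eye in ("left", "right"):
        filled = interpolate_invalid(raw[eye], landmarks.valid)
        out.append(eod_filter(filled, landmarks.fps, cfg)[amap.indices])
    return out[0], out[1]


def assemble_features(thermal: ThermalSequence,
                      landmarks: LandmarkStream,
                      amap: AlignmentMap,
                      cfg: FilterConfig | None = None,
                      norm: ThermalNormalization | None = None,
                      scheme: LandmarkScheme | None = None,
                      spec: ROISpec | None = None) -> FeatureMatrix:
    """Full image-path feature extraction for one participant.

    For every thermal frame the temporally matched landmark frame positions
    the ROIs, the mean ROI luminance is converted to LT, and the temporal
    operators produce the 11 columns of :data:`FEATURE_COLUMNS`.  A frame is
    valid when the landmark frame is valid, all ROIs stay inside the frame
    and the ATC lag is satisfied.
    """
    cfg = cfg or FilterConfig()
    norm = norm or ThermalNormalization()
    scheme = scheme or LandmarkScheme()
    spec = spec or ROISpec()
    if thermal.n_frames == 0 or landmarks.n_frames == 0:
        raise ValueError("empty input streams")
    if amap.n_thermal != thermal.n_frames or amap.n_visible != landmarks.n_frames:
        raise ValueError("alignment map does not match the streams")

    if thermal.mode == "temperature":
        lum = temperature_to_luminance(thermal.frames, norm)
    else:
        lum = thermal.frames

    n = thermal.n_frames
    lt = {name: np.full(n, np.nan) for name in ROI_NAMES}
    frame_valid = np.zeros(n, dtype=bool)
    for t in range(n):
        v = amap.indices[t]
        if not landmarks.valid[v]:
            continue
        rois = place_rois(landmarks.points[v], scheme, spec)
        if rois is None:
            continue
        frame_valid[t] = True
        for name in ROI_NAMES:
            g = roi_mean_luminance(lum[t], rois[name])
            lt[name][t] = luminance_temperature(g, norm)

    if not frame_valid.any():
        raise ValueError("no valid frames: landmark or ROI placement failed")
    eod_left, eod_right = _eod_tracks(landmarks, amap, cfg, scheme)
    return _assemble(lt, frame_valid, eod_left, eod_right, cfg)


def features_from_tracks(roi_temps: dict[str, np.ndarray],
                         landmarks: LandmarkStream,
                         amap: AlignmentMap,
                         cfg: FilterConfig | None = None,
                         norm: ThermalNormalization | None = None,
                         scheme: LandmarkScheme | None = None,
                         ) -> FeatureMatrix:
    """Feature extraction from per-ROI temperature tracks.

    Equivalent to :func:`assemble_features` on frames whose ROIs are
    uniformly at the given temperatures (the tracks pass through the same
    8-bit luminance quantization), but without materialising full 640×480
    frames — the scale at which multi-participant simulations run.
    """
    cfg = cfg or FilterConfig()
    norm = norm or ThermalNormalization()
    scheme = scheme or LandmarkScheme()
    n = next(iter(roi_temps.values())).size
    if amap.n_thermal != n or amap.n_visible != landmarks.n_frames:
        raise ValueError("alignment map does not match the streams")
    frame_valid = landmarks.valid[amap.indices].copy()
    lt = {}
    for name in ROI_NAMES:
        g = temperature_to_luminance(np.asarray(roi_temps[name], float), norm)
        track = luminance_temperature(g.astype(float), norm)
        track = np.where(frame_valid, track, np.nan)
        lt[name] = track
    eod_left, eod_right = _eod_tracks(landmarks, amap, cfg, scheme)
    return _assemble(lt, frame_valid, eod_left, eod_right, cfg)
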