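"""Thermal normalization and visible-to-thermal registration.

The thermography exports per-pixel temperatures; the pipeline works on
8-bit "thermal grayscale" frames obtained by mapping a fixed band of skin
temperatures (29.0–37.0 °C by default) onto luminance 0–255.  The inverse
affine map recovers the *luminance temperature* (LT) of a region from its
mean luminance:

    T_color = (G_avg / 255) * (T_max − T_min) + T_min

Visible frames are registered onto the 640×480 thermal geometry with a
projective transformation fitted to four fiducial markers placed around
the face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

THERMAL_SIZE = (640, 480)  # (width, height) of the registered geometry


@dataclass(frozen=True)
class ThermalNormalization:
    """Fixed temperature band mapped onto the 8-bit luminance range."""

    t_min: float = 29.0
    t_max: float = 37.0

    def __post_init__(self) -> None:
        if not self.t_max > self.t_min:
            raise ValueError("t_max must exceed t_min")

    @property
    def span(self) -> float:
        return self.t_max - self.t_min

    @property
    def quantization_step(self) -> float:
        """Temperature resolution of one luminance level, ≈0.0314 °C."""
        return self.span / 255.0


@dataclass(frozen=True)
class MarkerQuad:
    """Four fiducial marker positions in the visible frame, ordered
    TL, TR, BR, BL, mapped to the corners of the 640×480 rectangle."""

    source: np.ndarray
    target_size: tuple[int, int] = THERMAL_SIZE

    def __post_init__(self) -> None:
        src = np.asarray(self.source, dtype=float)
        if src.shape != (4, 2):
            raise ValueError("source must be four (x, y) points")
        object.__setattr__(self, "source", src)
        # no three points collinear: every triangle has non-zero area
        for skip in range(4):
            tri = np.delete(src, skip, axis=0)
            u, v = tri[1] - tri[0], tri[2] - tri[0]
            area = u[0] * v[1] - u[1] * v[0]
            if abs(area) < 1e-9:
                raise ValueError("degenerate marker quad: collinear points")

    @property
    def target(self) -> np.ndarray:
        w, h = self.target_size
        return np.array([[0.0, 0.0], [w - 1, 0.0], [w - 1, h - 1],
                         [0.0, h - 1]])


def temperature_to_luminance(t, norm: ThermalNormalization | None = None):
    """Quantize temperature (°C) to 8-bit luminance, saturating outside the
    normalization band.  Rounding is round-half-to-even."""
    norm = norm or ThermalNormalization()
    t = np.asarray(t, dtype=float)
    frac = np.clip((t - norm.t_min) / norm.span, 0.0, 1.0)
    return np.rint(255.0 * frac).astype(np.uint8)[()]


def luminance_temperature(g_avg, norm: ThermalNormalization | None = None):
    """Luminance temperature: invert the normalization for a mean luminance.

    ``T_color = (G_avg/255)·(T_max − T_min) + T_min``; strictly increasing
    in ``g_avg`` and affine, so it commutes with averaging.
    """
    norm = norm or ThermalNormalization()
    g = np.asarray(g_avg, dtype=float)
    if np.any(g < 0) or np.any(g > 255):
        raise ValueError("mean luminance must lie in [0, 255]")
    return (g / 255.0 * norm.span + norm.t_min)[()]


def fit_projective(markers: MarkerQuad) -> np.ndarray:
    """Fit the 3×3 homography sending each marker to its target corner.

    Direct linear transform on exactly four correspondences (the markers
    are fixed in the scene, so there is nothing to make robust against);
    normalized so the bottom-right element is 1.
    """
    src, dst = markers.source, markers.target
    # unknowns: 8 homography entries with h22 = 1
    a = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(src, dst)):
        a[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        b[2 * i] = u
        a[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i + 1] = v
    try:
        h = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError("degenerate marker configuration") from exc
    hmat = np.append(h, 1.0).reshape(3, 3)
    return hmat / hmat[2, 2]


def apply_homography(h: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map (n, 2) points through a homography."""
    pts = np.asarray(points, dtype=float)
    ones = np.ones((pts.shape[0], 1))
    mapped = np.hstack([pts, ones]) @ h.T
    return mapped[:, :2] / mapped[:, 2:3]


def warp_visible(frame: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Resample a visible frame onto the 640×480 thermal geometry.

    ``h`` maps source (visible) coordinates to target coordinates; sampling
    is bilinear and pixels outside the source footprint are zero.
    """
    w, hgt = THERMAL_SIZE
    inv = ProjectiveTransform(matrix=np.linalg.inv(h))  # target → source
    out = warp(np.asarray(frame, dtype=float), inv,
               output_shape=(hgt, w), order=1, cval=0.0,
               preserve_range=True)
    return out
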