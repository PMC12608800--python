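"""Stream containers and I/O for the thermal / landmark / label pipeline.

The pipeline consumes three temporally ordered streams per participant:

* a thermal video at a nominal 30 fps, either as per-frame temperature
  matrices (°C) or as already-normalized 8-bit grayscale frames,
* a 106-point facial-landmark stream detected on the registered visible
  video at a nominal 60 fps, and
* an interval label file marking emotional-arousal stretches.

Because the two cameras run at different rates, every thermal frame is
matched to a visible (landmark) frame by linear interpolation of frame
indices; :func:`align_streams` builds that correspondence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

THERMAL_SHAPE = (480, 640)  # rows, cols of the registered geometry

#: per-frame label codes
AROUSAL = 0
NON_AROUSAL = 1
INVALID = -1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ThermalSequence:
    """Ordered stack of thermal frames with acquisition metadata.

    ``frames`` has shape ``(n_frames, height, width)``.  In ``"temperature"``
    mode values are °C; in ``"luminance"`` mode values are 8-bit integers in
    ``[0, 255]`` produced by the fixed-band normalization.
    """

    frames: np.ndarray
    fps: float = 30.0
    mode: str = "temperature"
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) stack")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.mode not in ("temperature", "luminance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "luminance":
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("luminance frames must lie in [0, 255]")
        elif not np.all(np.isfinite(self.frames)):
            raise ValueError("temperature frames must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class LandmarkStream:
    """Per-visible-frame 106-point facial coordinates.

    ``points`` has shape ``(n_frames, 106, 2)`` with (x, y) pixel coordinates
    in the registered 640×480 visible frame.  ``valid[i]`` is False where the
    detector failed; such frames carry NaN points and propagate a validity
    mask downstream instead of aborting the run.
    """

    points: np.ndarray
    fps: float = 60.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1:] != (106, 2):
            raise ValueError("points must have shape (n, 106, 2)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.valid is None:
            self.valid = np.all(np.isfinite(self.points), axis=(1, 2))
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (self.points.shape[0],):
            raise ValueError("valid mask length must match frame count")
        ok = self.valid
        if ok.any() and not np.all(np.isfinite(self.points[ok])):
            raise ValueError("valid frames must have finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]


@dataclass
class LabelTrack:
    """Per-thermal-frame class labels: 0 arousal, 1 non-arousal, −1 invalid."""

    labels: np.ndarray
    n_frames: int = field(default=0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.n_frames == 0:
            self.n_frames = self.labels.size
        if self.labels.size != self.n_frames:
            raise ValueError("label track length must equal n_frames")
        bad = ~np.isin(self.labels, (AROUSAL, NON_AROUSAL, INVALID))
        if bad.any():
            raise ValueError("labels must be in {-1, 0, 1}")


@dataclass
class AlignmentMap:
    """Thermal-frame → visible-frame correspondence by linear interpolation.

    ``indices[t]`` is the visible frame matched to thermal frame ``t``; the
    mapping is monotone non-decreasing and endpoint-exact (0→0 and last→last).
    """

    n_visible: int
    n_thermal: int
    indices: np.ndarray

    def __call__(self, t: int | np.ndarray) -> np.ndarray:
        return self.indices[t]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def align_streams(n_visible: int, n_thermal: int) -> AlignmentMap:
    """Match every thermal frame to its temporally nearest visible frame.

    Thermal index ``t`` maps to ``round(t * (n_visible-1)/(n_thermal-1))``
    with round-half-to-even, which is linear interpolation of frame counts
    expressed on the thermal timeline (features live on the thermal clock,
    so one landmark frame is chosen per thermal frame).
    """
    if n_visible < 2 or n_thermal < 2:
        raise ValueError("both streams need at least 2 frames to align")
    t = np.arange(n_thermal, dtype=float)
    idx = np.rint(t * (n_visible - 1) / (n_thermal - 1)).astype(int)
    return AlignmentMap(n_visible=n_visible, n_thermal=n_thermal, indices=idx)


def read_labels(path: str | Path, n_frames: int,
                medium_weak_invalid: bool = True) -> LabelTrack:
    """Expand an interval CSV into a per-frame label track.

    The CSV has header ``start_frame,end_frame,class`` with 0-based inclusive
    frame intervals and class ∈ {arousal, nonarousal, invalid}.  Only
    "strong"-rated intervals appear as ``arousal`` rows; everything not
    covered by any row defaults to non-arousal.  Overlaps resolve in favour
    of arousal.  ``invalid`` rows mark excluded stretches (e.g. medium/weak
    ratings) with −1; set ``medium_weak_invalid=False`` to fold them into
    the non-arousal default instead.
    """
    df = pd.read_csv(path)
    labels = np.full(n_frames, NON_AROUSAL, dtype=int)
    # paint invalid first, then arousal on top so arousal always wins
    for cls_name, code in (("invalid", INVALID), ("nonarousal", NON_AROUSAL),
                           ("arousal", AROUSAL)):
        for _, row in df[df["class"] == cls_name].iterrows():
            s, e = int(row["start_frame"]), int(row["end_frame"])
            if s < 0 or e >= n_frames or s > e:
                raise ValueError(
                    f"interval ({s}, {e}) outside track of {n_frames} frames")
            if cls_name == "invalid" and not medium_weak_invalid:
                continue
            labels[s:e + 1] = code
    unknown = set(df["class"]) - {"arousal", "nonarousal", "invalid"}
    if unknown:
        raise ValueError(f"unknown label classes: {sorted(unknown)}")
    return LabelTrack(labels=labels, n_frames=n_frames)


def write_labels(track: LabelTrack, path: str | Path) -> None:
    """Write a label track back to the interval CSV format."""
    rows = []
    names = {AROUSAL: "arousal", NON_AROUSAL: "nonarousal", INVALID: "invalid"}
    lab = track.labels
    start = 0
    for i in range(1, lab.size + 1):
        if i == lab.size or lab[i] != lab[start]:
            if lab[start] != NON_AROUSAL:  # non-arousal is the default
                rows.append((start, i - 1, names[int(lab[start])]))
            start = i
    pd.DataFrame(rows, columns=["start_frame", "end_frame", "class"]).to_csv(
        path, index=False)


def read_thermal(path: str | Path, mode: str = "temperature",
                 fps: float | None = None,
                 participant_id: str = "") -> ThermalSequence:
    """Read a thermal sequence from any supported container.

    Containers (no raw IRT vendor format is decoded):

    * ``<path>.npy`` single array file, optional ``<path>.json`` sidecar
      holding ``{"fps": ..., "mode": ..., "participant_id": ...}``;
    * directory of per-frame ``frame_*.csv`` matrices (temperature mode);
    * directory of numbered 8-bit ``frame_*.png`` frames (luminance mode).
    """
    path = Path(path)
    sidecar: dict = {}
    if path.is_dir():
        csvs = sorted(path.glob("frame_*.csv"))
        pngs = sorted(path.glob("frame_*.png"))
        meta = path / "meta.json"
        if meta.exists():
            sidecar = json.loads(meta.read_text())
        if csvs:
            frames = [np.loadtxt(f, delimiter=",") for f in csvs]
        elif pngs:
            import imageio.v3 as iio
            frames = [iio.imread(f) for f in pngs]
            mode = "luminance"
        else:
            raise FileNotFoundError(f"no frame_*.csv or frame_*.png in {path}")
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"ragged frame shapes: {sorted(shapes)}")
        frames = np.stack(frames)
    elif path.suffix == ".npy":
        frames = np.load(path)
        side = path.with_suffix(".json")
        if side.exists():
            sidecar = json.loads(side.read_text())
    else:
        raise FileNotFoundError(f"unsupported or missing container: {path}")
    return ThermalSequence(
        frames=frames,
        fps=float(fps if fps is not None else sidecar.get("fps", 30.0)),
        mode=sidecar.get("mode", mode),
        participant_id=sidecar.get("participant_id", participant_id),
    )


def write_thermal(seq: ThermalSequence, path: str | Path,
                  container: str = "npy") -> None:
    """Write a thermal sequence (``npy`` array + JSON sidecar, ``csv`` or
    ``png`` frame directory)."""
    path = Path(path)
    meta = {"fps": seq.fps, "mode": seq.mode,
            "participant_id": seq.participant_id}
    if container == "npy":
        np.save(path.with_suffix(".npy"), seq.frames)
        path.with_suffix(".json").write_text(json.dumps(meta))
    elif container == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(seq.frames):
            np.savetxt(path / f"frame_{i:06d}.csv", frame, delimiter=",")
        (path / "meta.json").write_text(json.dumps(meta))
    elif container == "png":
        import imageio.v3 as iio
        if seq.mode != "luminance":
            raise ValueError("png container requires luminance mode")
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(seq.frames):
            iio.imwrite(path / f"frame_{i:06d}.png",
                        frame.astype(np.uint8))
        (path / "meta.json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unknown container {container!r}")


def read_landmarks(path: str | Path, fps: float = 60.0) -> LandmarkStream:
    """Read a landmark stream from JSON Lines.

    One record per visible frame:
    ``{"frame": i, "valid": true, "points": [[x, y] × 106]}``.  Records for
    failed detections carry ``"valid": false`` and may omit points.  An
    external 106-point detector (e.g. insightface) can populate this file;
    the adapter is outside the tested core.
    """
    records = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            records[int(rec["frame"])] = rec
    n = max(records) + 1 if records else 0
    points = np.full((n, 106, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, rec in records.items():
        if rec.get("valid", True) and rec.get("points") is not None:
            pts = np.asarray(rec["points"], dtype=float)
            if pts.shape != (106, 2):
                raise ValueError(
                    f"frame {i}: expected 106 (x, y) points, got {pts.shape}")
            points[i] = pts
            valid[i] = True
    return LandmarkStream(points=points, fps=fps, valid=valid)


def write_landmarks(stream: LandmarkStream, path: str | Path) -> None:
    """Write a landmark stream as JSON Lines (see :func:`read_landmarks`)."""
    with open(path, "w") as fh:
        for i in range(stream.n_frames):
            if stream.valid[i]:
                rec = {"frame": i, "valid": True,
                       "points": np.round(stream.points[i], 6).tolist()}
            else:
                rec = {"frame": i, "valid": False, "points": None}
            fh.write(json.dumps(rec) + "\n")
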