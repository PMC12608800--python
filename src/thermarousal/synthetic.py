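"""Synthetic participants with the statistical structure the method assumes.

The study's dataset (nine participants watching digital content under
paired thermal/visible cameras) is private, so this module generates
stand-in participants end to end: per-ROI facial skin-temperature tracks
(slow random-walk baseline drift, arousal-episode-locked nasal cooling and
mild cheek warming with a trapezoidal onset/offset ramp, white measurement
noise), a 106-point landmark stream built from a parametric face template
(blinking eyelids, optional head-roll wobble), interval labels locked to
the episode process, and — when the full image pipeline is under test —
rendered 640×480 temperature frames whose ROI means reproduce the tracks.

Everything is deterministic given ``(seed, participant_index)``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .features import LandmarkScheme, ROI_NAMES, ROISpec, place_rois
from .io_streams import (AROUSAL, NON_AROUSAL, AlignmentMap, LabelTrack,
                         LandmarkStream, ThermalSequence, align_streams)

TEMP_CLIP = (25.0, 40.0)  # physiological plausibility clamp, °C


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for a simulated cohort.

    Defaults describe a 10-minute recording per participant with four
    arousal episodes of 60–90 s (expected arousal prevalence ≈ 0.5),
    nasal cooling of −0.5 °C and mild cheek warming of +0.1 °C ramping
    over 10 s, a 20% increase in eye opening during episodes, 18
    blinks/min of 150 ms, white temperature noise of 0.05 °C and a
    0.005 °C/√s random-walk baseline drift.
    """

    n_participants: int = 9
    duration_s: float = 600.0
    thermal_fps: float = 30.0
    visible_fps: float = 60.0
    baseline_temp: dict[str, float] = field(default_factory=lambda: {
        "nose": 33.5, "right_cheek": 34.0, "left_cheek": 34.0})
    drift_sd: float = 0.005          # °C per sqrt(second)
    n_episodes: int = 4
    episode_duration_s: tuple[float, float] = (60.0, 90.0)
    refractory_s: float = 30.0
    nose_effect_c: float = -0.5      # negative = arousal-locked cooling
    cheek_effect_c: float = 0.1
    onset_ramp_s: float = 10.0
    eod_baseline_px: float = 12.0
    eod_effect: float = 0.2          # fractional change during episodes
    blink_rate_per_min: float = 18.0
    blink_duration_ms: float = 150.0
    noise_sd_c: float = 0.05
    roll_wobble_deg: float = 2.0
    background_temp_c: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.visible_fps / self.thermal_fps - 2.0) > 1e-9:
            raise ValueError("visible fps must be twice the thermal fps")
        if self.episode_duration_s[0] <= 0:
            raise ValueError("episode durations must be positive")
        if min(self.drift_sd, self.noise_sd_c) < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def n_thermal(self) -> int:
        return int(round(self.duration_s * self.thermal_fps))

    @property
    def n_visible(self) -> int:
        return int(round(self.duration_s * self.visible_fps))


@dataclass
class SyntheticParticipant:
    participant_id: str
    roi_temps: dict[str, np.ndarray]   # °C on the thermal timeline
    landmarks: LandmarkStream
    labels: LabelTrack
    truth: list[tuple[int, int]]       # inclusive episode frame intervals
    eod_true: np.ndarray               # blink-free lid distance, visible rate


# ---------------------------------------------------------------------------
# episode process
# ---------------------------------------------------------------------------

def _sample_episodes(scn: SyntheticScenario,
                     rng: np.random.Generator) -> list[tuple[float, float]]:
    """Episode (start_s, end_s) intervals separated by the refractory gap."""
    if scn.n_episodes == 0:
        return []
    durs = rng.uniform(*scn.episode_duration_s, size=scn.n_episodes)
    occupied = durs.sum() + scn.refractory_s * (scn.n_episodes - 1)
    free = scn.duration_s - occupied
    if free < 0:
        raise ValueError("episodes and refractory gaps exceed the duration")
    cuts = np.sort(rng.uniform(0.0, 1.0, size=scn.n_episodes))
    slack = np.diff(np.concatenate([[0.0], cuts])) * free
    episodes = []
    t = 0.0
    for d, s in zip(durs, slack):
        start = t + s
        episodes.append((start, start + d))
        t = start + d + scn.refractory_s
    return episodes


def _episode_profile(times: np.ndarray,
                     episodes: list[tuple[float, float]],
                     ramp_s: float) -> np.ndarray:
    """Trapezoidal 0→1 activation: linear onset/offset ramps inside each
    episode, full effect on the plateau."""
    prof = np.zeros_like(times)
    for start, end in episodes:
        ramp = min(ramp_s, (end - start) / 2.0)
        up = np.clip((times - start) / max(ramp, 1e-9), 0.0, 1.0)
        down = np.clip((end - times) / max(ramp, 1e-9), 0.0, 1.0)
        prof = np.maximum(prof, np.minimum(up, down))
    return prof


def _blink_train(scn: SyntheticScenario, n_vis: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lid-closure profile in [0, 1] at the visible rate
    (1 = fully closed at blink centre), from a Poisson blink process."""
    closure = np.zeros(n_vis)
    rate = scn.blink_rate_per_min / 60.0
    if rate <= 0:
        return closure
    half = scn.blink_duration_ms / 1000.0 / 2.0
    t = 0.0
    times = []
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= scn.duration_s:
            break
        times.append(t)
    grid = np.arange(n_vis) / scn.visible_fps
    for bt in times:
        span = (grid >= bt - half) & (grid <= bt + half)
        phase = (grid[span] - bt) / half  # −1 … 1 across the blink
        closure[span] = np.maximum(closure[span],
                                   0.97 * 0.5 * (1 + np.cos(np.pi * phase)))
    return closure


# ---------------------------------------------------------------------------
# landmark template
# ---------------------------------------------------------------------------

def _face_template(scheme: LandmarkScheme) -> np.ndarray:
    """Neutral 106-point template centred in the 640×480 frame.  Only the
    indices named by the scheme carry meaning; the rest sit on a face oval
    so streams are well-formed for any consumer."""
    pts = np.zeros((106, 2))
    theta = np.linspace(0.0, 2.0 * np.pi, 106, endpoint=False)
    pts[:, 0] = 320.0 + 110.0 * np.cos(theta)
    pts[:, 1] = 240.0 + 140.0 * np.sin(theta)
    pts[scheme.left_eye_outer] = (270.0, 200.0)
    pts[scheme.left_eye_inner] = (300.0, 200.0)
    pts[scheme.left_eye_upper] = (285.0, 194.0)
    pts[scheme.left_eye_lower] = (285.0, 206.0)
    pts[scheme.right_eye_outer] = (370.0, 200.0)
    pts[scheme.right_eye_inner] = (340.0, 200.0)
    pts[scheme.right_eye_upper] = (355.0, 194.0)
    pts[scheme.right_eye_lower] = (355.0, 206.0)
    pts[scheme.nose_root] = (320.0, 210.0)
    pts[scheme.nose_apex] = (320.0, 260.0)
    pts[scheme.nostril_center] = (320.0, 270.0)
    return pts


def _landmark_stream(scn: SyntheticScenario, eod: np.ndarray,
                     rng: np.random.Generator,
                     scheme: LandmarkScheme) -> LandmarkStream:
    """Animate the template: per-frame eyelid aperture and slow head roll."""
    n = eod.size
    base = _face_template(scheme)
    pts = np.repeat(base[None, :, :], n, axis=0)
    for side in ("left", "right"):
        up = getattr(scheme, f"{side}_eye_upper")
        lo = getattr(scheme, f"{side}_eye_lower")
        cx = base[up, 0]
        cy = (base[up, 1] + base[lo, 1]) / 2.0
        pts[:, up] = np.column_stack([np.full(n, cx), cy - eod / 2.0])
        pts[:, lo] = np.column_stack([np.full(n, cx), cy + eod / 2.0])
    if scn.roll_wobble_deg > 0:
        grid = np.arange(n) / scn.visible_fps
        phase = rng.uniform(0.0, 2.0 * np.pi)
        roll = np.deg2rad(scn.roll_wobble_deg) * np.sin(
            2.0 * np.pi * grid / 20.0 + phase)
        pivot = base[scheme.nostril_center]
        c, s = np.cos(roll), np.sin(roll)
        rel = pts - pivot
        pts = np.stack([c[:, None] * rel[..., 0] - s[:, None] * rel[..., 1],
                        s[:, None] * rel[..., 0] + c[:, None] * rel[..., 1]],
                       axis=-1) + pivot
    return LandmarkStream(points=pts, fps=scn.visible_fps,
                          valid=np.ones(n, dtype=bool))


# ---------------------------------------------------------------------------
# participants and cohorts
# ---------------------------------------------------------------------------

def simulate_participant(scn: SyntheticScenario, index: int = 0,
                         scheme: LandmarkScheme | None = None,
                         ) -> SyntheticParticipant:
    """Generate one participant, deterministic given (scenario seed, index)."""
    scheme = scheme or LandmarkScheme()
    rng = np.random.default_rng(np.random.SeedSequence((scn.seed, index)))
    n_th, n_vis = scn.n_thermal, scn.n_visible
    t_thermal = np.arange(n_th) / scn.thermal_fps
    t_visible = np.arange(n_vis) / scn.visible_fps

    episodes = _sample_episodes(scn, rng)
    prof_th = _episode_profile(t_thermal, episodes, scn.onset_ramp_s)
    prof_vis = _episode_profile(t_visible, episodes, scn.onset_ramp_s)

    step_sd = scn.drift_sd / np.sqrt(scn.thermal_fps)
    effects = {"nose": scn.nose_effect_c, "right_cheek": scn.cheek_effect_c,
               "left_cheek": scn.cheek_effect_c}
    roi_temps = {}
    for name in ROI_NAMES:
        walk = np.cumsum(rng.normal(0.0, step_sd, n_th)) if step_sd > 0 \
            else np.zeros(n_th)
        noise = rng.normal(0.0, scn.noise_sd_c, n_th) \
            if scn.noise_sd_c > 0 else np.zeros(n_th)
        track = (scn.baseline_temp[name] + walk
                 + effects[name] * prof_th + noise)
        roi_temps[name] = np.clip(track, *TEMP_CLIP)

    eod_true = scn.eod_baseline_px * (1.0 + scn.eod_effect * prof_vis)
    closure = _blink_train(scn, n_vis, rng)
    eod = eod_true * (1.0 - closure)
    landmarks = _landmark_stream(scn, eod, rng, scheme)

    labels = np.full(n_th, NON_AROUSAL, dtype=int)
    truth = []
    for start_s, end_s in episodes:
        s = int(np.ceil(start_s * scn.thermal_fps))
        e = min(int(np.floor(end_s * scn.thermal_fps)), n_th - 1)
        labels[s:e + 1] = AROUSAL
        truth.append((s, e))

    return SyntheticParticipant(
        participant_id=f"S{index:02d}",
        roi_temps=roi_temps,
        landmarks=landmarks,
        labels=LabelTrack(labels=labels, n_frames=n_th),
        truth=truth,
        eod_true=eod_true,
    )


def render_thermal_frames(roi_temps: dict[str, np.ndarray],
                          landmarks: LandmarkStream,
                          background_c: float = 30.0,
                          scheme: LandmarkScheme | None = None,
                          spec: ROISpec | None = None,
                          fps: float = 30.0,
                          participant_id: str = "") -> ThermalSequence:
    """Paint per-ROI temperatures into landmark-positioned polygons on a
    constant background, so the full image pipeline (normalize → place
    ROIs → mean luminance) recovers the tracks up to 8-bit quantization."""
    scheme = scheme or LandmarkScheme()
    spec = spec or ROISpec()
    n_th = next(iter(roi_temps.values())).size
    amap = align_streams(landmarks.n_frames, n_th)
    frames = np.full((n_th, 480, 640), background_c, dtype=float)
    for t in range(n_th):
        v = amap.indices[t]
        if not landmarks.valid[v]:
            continue
        rois = place_rois(landmarks.points[v], scheme, spec)
        if rois is None:
            continue
        for name in ROI_NAMES:
            poly = rois[name]
            x0, x1 = int(np.floor(poly[:, 0].min())), int(np.ceil(poly[:, 0].max()))
            y0, y1 = int(np.floor(poly[:, 1].min())), int(np.ceil(poly[:, 1].max()))
            xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
            inside = np.ones(xs.shape, dtype=bool)
            area2 = sum(poly[i, 0] * poly[(i + 1) % 4, 1]
                        - poly[(i + 1) % 4, 0] * poly[i, 1] for i in range(4))
            sign = 1.0 if area2 >= 0 else -1.0
            for i in range(4):
                ax, ay = poly[i]
                bx, by = poly[(i + 1) % 4]
                cross = (bx - ax) * (ys - ay) - (by - ay) * (xs - ax)
                inside &= sign * cross >= -1e-9
            frames[t, ys[inside], xs[inside]] = roi_temps[name][t]
    return ThermalSequence(frames=frames, fps=fps, mode="temperature",
                           participant_id=participant_id)


def generate_cohort(scn: SyntheticScenario,
                    scheme: LandmarkScheme | None = None,
                    ) -> tuple[list[SyntheticParticipant], dict]:
    """Simulate the full cohort plus a manifest that reproduces it exactly."""
    if scn.n_participants < 1:
        raise ValueError("need at least one participant")
    participants = [simulate_participant(scn, i, scheme)
                    for i in range(scn.n_participants)]
    manifest = {"scenario": asdict(scn),
                "participants": [p.participant_id for p in participants]}
    return participants, manifest
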