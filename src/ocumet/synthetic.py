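"""Synthetic ocular-signal simulator.

Generates ground-truth binocular traces (blinks, fixation plateaus,
pupil oscillation), pre/post sessions with group-dependent effects,
whole cohorts, and rendered grayscale frames with pixel-exact masks.

Every stochastic draw flows from a single seed so that identical
parameters reproduce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .segeval import FrameMasks
from .trace import GroundTruthEvents, OcularTrace, TracePair, traces_to_csv

GROUPS = ("deteriorated", "nondeteriorated")

# detection conventions shared with ocumet.metrics: a frame counts as
# "closed" below 20% of the open aperture baseline; fixations need
# >= 100 ms of centroid stability
_CLOSED_FACTOR = 0.05
_RAMP_FACTOR = 0.55
_CLOSURE_THRESHOLD = 0.2
_MIN_FIXATION_MS = 100.0


@dataclass
class TraceParams:
    """Knobs for one simulated 1-minute recording."""

    frame_rate: float = 30.0
    n_frames: int = 1800
    blink_rate: float = 15.0  # events per minute
    blink_duration_mean: float = 130.0  # ms; physiological blinks last ~100-150 ms
    blink_duration_sd: float = 30.0
    open_fissure_mean: float = 36.0  # px
    open_fissure_sd: float = 1.2
    pupil_mean: float = 24.0  # px
    pupil_osc_amplitude: float = 1.0
    pupil_osc_period: float = 4.0  # s
    pupil_noise_sd: float = 0.4
    fixation_duration_mean: float = 280.0  # ms
    saccade_amplitude_mean: float = 40.0  # px
    centroid_noise_sd: float = 0.6
    pupil_x0: float = 160.0
    pupil_y0: float = 90.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in (
            "blink_rate",
            "blink_duration_mean",
            "blink_duration_sd",
            "open_fissure_sd",
            "pupil_osc_amplitude",
            "pupil_noise_sd",
            "fixation_duration_mean",
            "saccade_amplitude_mean",
            "centroid_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class EffectProfile:
    """Post-minus-pre shifts applied to the post-task recording of a group."""

    group: str
    delta_blink_rate: float = 0.0  # events/min
    delta_blink_duration: float = 0.0  # ms
    delta_variability_scale_midwindow: float = 1.0  # multiplier, frames 600-1200
    delta_cff: float = 0.0  # Hz
    cvsq_change_mean: float = 0.0
    cvsq_change_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


def default_effects() -> dict[str, EffectProfile]:
    """Default group effects reproducing the observed sign pattern.

    Deteriorated sessions show a blink-duration change <= 0, no increase
    in mid-window variability and a larger CFF drop; non-deteriorated
    sessions blink more, longer, and show elevated mid-window variability.
    """
    return {
        "deteriorated": EffectProfile(
            group="deteriorated",
            delta_blink_rate=0.0,
            delta_blink_duration=-5.0,
            delta_variability_scale_midwindow=0.9,
            delta_cff=-2.97,
            cvsq_change_mean=5.0,
            cvsq_change_sd=2.0,
        ),
        "nondeteriorated": EffectProfile(
            group="nondeteriorated",
            delta_blink_rate=4.0,
            delta_blink_duration=12.0,
            delta_variability_scale_midwindow=1.8,
            delta_cff=-2.14,
            cvsq_change_mean=1.0,
            cvsq_change_sd=1.0,
        ),
    }


@dataclass
class SessionRecord:
    """One participant session: pre/post traces plus questionnaire values."""

    participant_id: str
    pre_trace: TracePair
    post_trace: TracePair
    cvsq_pre: int
    cvsq_post: int
    cff_pre: float
    cff_post: float
    truth_group: str

    def __post_init__(self) -> None:
        if self.cvsq_pre < 0 or self.cvsq_post < 0:
            raise ValueError("CVS-Q scores must be non-negative")


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------


def _blink_schedule(params: TraceParams, rng: np.random.Generator):
    """Place blink events in equal bins so they never overlap.

    Returns (aperture_factor, blink_events) where events are inclusive
    frame bounds of the fully-closed run.
    """
    n, fps = params.n_frames, params.frame_rate
    factor = np.ones(n)
    events: list[tuple[int, int]] = []
    minutes = n / fps / 60.0
    n_blinks = int(round(params.blink_rate * minutes))
    if n_blinks <= 0:
        return factor, events
    bin_edges = np.linspace(0, n, n_blinks + 1)
    for b in range(n_blinks):
        dur_ms = rng.normal(params.blink_duration_mean, params.blink_duration_sd)
        closed = max(2, int(round(dur_ms * fps / 1000.0)))
        footprint = closed + 2  # one ramp frame each side
        lo, hi = bin_edges[b], bin_edges[b + 1]
        slack = (hi - lo) - footprint - 2
        if slack <= 0:
            # bin too tight (very high rate / short recording): shrink
            closed = max(2, int(hi - lo) - 4)
            footprint = closed + 2
            slack = max(1.0, (hi - lo) - footprint - 2)
        start = int(lo + 1 + rng.uniform(0, slack))
        start = min(start, n - footprint)
        if start < 0:
            continue
        factor[start] = _RAMP_FACTOR
        factor[start + 1 : start + 1 + closed] = _CLOSED_FACTOR
        if start + 1 + closed < n:
            factor[start + 1 + closed] = _RAMP_FACTOR
        events.append((start + 1, start + closed))
    return factor, events


def _fixation_schedule(params: TraceParams, valid: np.ndarray, rng: np.random.Generator):
    """Chop valid runs into centroid plateaus separated by saccadic jumps."""
    fps = params.frame_rate
    min_frames = max(3, int(round(0.12 * fps)))
    plateaus: list[tuple[int, int]] = []  # inclusive bounds
    centroids: list[tuple[float, float]] = []
    x, y = params.pupil_x0, params.pupil_y0
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1]:
            j += 1
        # chop run [i, j]
        pos = i
        while pos <= j:
            dur_ms = rng.normal(params.fixation_duration_mean, 0.25 * params.fixation_duration_mean)
            dur = max(min_frames, int(round(dur_ms * fps / 1000.0)))
            end = min(pos + dur - 1, j)
            if j - end < min_frames:
                end = j
            # saccadic jump: horizontal-dominant (reading-like) and always
            # larger than the I-DT dispersion radius, else the detector
            # would merge consecutive plateaus; vertical wander is kept
            # small so the pupil stays inside the rendered aperture
            amp = max(25.0, rng.normal(params.saccade_amplitude_mean, 0.2 * params.saccade_amplitude_mean))
            direction = 1.0 if rng.random() < 0.5 else -1.0
            nx = x + direction * amp
            if abs(nx - params.pupil_x0) > 80.0:
                nx = x - direction * amp
            ny = params.pupil_y0 + _reflect(y + rng.normal(0, 3.0) - params.pupil_y0, 8.0)
            x, y = nx, ny
            plateaus.append((pos, end))
            centroids.append((x, y))
            pos = end + 1
        i = j + 1
    return plateaus, centroids


def _reflect(v: float, bound: float) -> float:
    if v > bound:
        return 2 * bound - v
    if v < -bound:
        return -2 * bound - v
    return v


def _skeleton(params: TraceParams, rng: np.random.Generator) -> dict:
    """Event structure shared between the two eyes of one recording."""
    factor, blink_events = _blink_schedule(params, rng)
    valid = factor > _CLOSURE_THRESHOLD
    plateaus, centroids = _fixation_schedule(params, valid, rng)
    phase = rng.uniform(0, 2 * math.pi)
    fps = params.frame_rate
    fixation_events = [
        (s, e) for (s, e) in plateaus if (e - s + 1) * 1000.0 / fps >= _MIN_FIXATION_MS
    ]
    return {
        "factor": factor,
        "valid": valid,
        "blinks": blink_events,
        "plateaus": plateaus,
        "centroids": centroids,
        "fixations": fixation_events,
        "phase": phase,
    }


def _realize_eye(
    params: TraceParams,
    skel: dict,
    eye: str,
    rng: np.random.Generator,
    noise_scale: np.ndarray | None = None,
) -> OcularTrace:
    n, fps = params.n_frames, params.frame_rate
    scale = np.ones(n) if noise_scale is None else np.asarray(noise_scale, dtype=float)
    t = np.arange(n) / fps

    fissure = params.open_fissure_mean + rng.normal(0, 1, n) * params.open_fissure_sd * scale
    fissure = np.clip(fissure, 0, None) * skel["factor"]

    pupil = (
        params.pupil_mean
        + params.pupil_osc_amplitude * np.sin(2 * math.pi * t / params.pupil_osc_period + skel["phase"])
        + rng.normal(0, 1, n) * params.pupil_noise_sd * scale
    )
    valid = skel["valid"].copy()
    pupil = np.where(valid, np.clip(pupil, 1.0, None), np.nan)

    px = np.full(n, np.nan)
    py = np.full(n, np.nan)
    for (s, e), (cx, cy) in zip(skel["plateaus"], skel["centroids"]):
        px[s : e + 1] = cx
        py[s : e + 1] = cy
    jitter = rng.normal(0, params.centroid_noise_sd, (2, n))
    px = np.where(valid, px + jitter[0], np.nan)
    py = np.where(valid, py + jitter[1], np.nan)

    return OcularTrace(
        eye=eye,
        frame_rate=fps,
        fissure_length=fissure,
        pupil_diameter=pupil,
        pupil_x=px,
        pupil_y=py,
        valid=valid,
        truth=GroundTruthEvents(blinks=list(skel["blinks"]), fixations=list(skel["fixations"])),
    )


def simulate_trace(
    params: TraceParams,
    eye: str = "left",
    noise_scale: np.ndarray | None = None,
) -> OcularTrace:
    """Simulate a single-eye recording.

    Blinks are trapezoidal aperture drops (ramp, fully-closed plateau,
    ramp); fixations are centroid plateaus separated by saccadic jumps;
    the pupil diameter is mean + sinusoid + Gaussian noise, undefined
    during closure.  The injected event log is attached as ``trace.truth``.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    skel = _skeleton(params, rng)
    return _realize_eye(params, skel, eye, rng, noise_scale)


def simulate_binocular(
    params: TraceParams, noise_scale: np.ndarray | None = None
) -> TracePair:
    """Simulate both eyes with shared events and independent pixel noise."""
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    skel = _skeleton(params, rng)
    return {
        "left": _realize_eye(params, skel, "left", rng, noise_scale),
        "right": _realize_eye(params, skel, "right", rng, noise_scale),
    }


# ---------------------------------------------------------------------------
# sessions and cohorts
# ---------------------------------------------------------------------------

_MID_WINDOW = (600, 1200)


def _post_params(params: TraceParams, effect: EffectProfile, seed: int) -> TraceParams:
    return replace(
        params,
        blink_rate=max(0.0, params.blink_rate + effect.delta_blink_rate),
        blink_duration_mean=max(70.0, params.blink_duration_mean + effect.delta_blink_duration),
        rng_seed=seed,
    )


def simulate_session(
    params: TraceParams,
    effect: EffectProfile,
    participant_id: str = "P000",
    seed: int | None = None,
) -> SessionRecord:
    """Simulate one pre/post session under a group effect profile.

    The post-task recording gets shifted blink parameters and its
    pupil/fissure noise scaled by ``delta_variability_scale_midwindow``
    inside frames 600-1200.  The CVS-Q change is a rounded Gaussian
    clipped at zero.
    """
    params.validate()
    master = np.random.default_rng(params.rng_seed if seed is None else seed)
    pre_seed, post_seed = (int(s) for s in master.integers(0, 2**31 - 1, 2))

    pre = simulate_binocular(replace(params, rng_seed=pre_seed))

    scale = np.ones(params.n_frames)
    lo, hi = _MID_WINDOW
    scale[lo : min(hi, params.n_frames)] = effect.delta_variability_scale_midwindow
    post = simulate_binocular(_post_params(params, effect, post_seed), noise_scale=scale)

    cvsq_pre = int(round(np.clip(master.normal(6.76, 3.76), 0, 30)))
    change = int(round(master.normal(effect.cvsq_change_mean, effect.cvsq_change_sd)))
    change = max(0, change)
    cff_pre = float(master.normal(40.0, 1.5))
    cff_post = float(cff_pre + effect.delta_cff + master.normal(0, 0.5))

    return SessionRecord(
        participant_id=participant_id,
        pre_trace=pre,
        post_trace=post,
        cvsq_pre=cvsq_pre,
        cvsq_post=cvsq_pre + change,
        cff_pre=cff_pre,
        cff_post=cff_post,
        truth_group=effect.group,
    )


def simulate_cohort(
    n: int,
    prevalence: float,
    params: TraceParams | None = None,
    effects: dict[str, EffectProfile] | None = None,
    seed: int = 0,
) -> list[SessionRecord]:
    """Simulate ``round(n * prevalence)`` deteriorated sessions plus the rest.

    Deterministic under ``seed``; group order is shuffled.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    params = params or TraceParams()
    effects = effects or default_effects()
    n_det = int(round(n * prevalence))
    groups = ["deteriorated"] * n_det + ["nondeteriorated"] * (n - n_det)
    master = np.random.default_rng(seed)
    master.shuffle(groups)
    records = []
    for i, group in enumerate(groups):
        sid = int(master.integers(0, 2**31 - 1))
        records.append(
            simulate_session(params, effects[group], participant_id=f"P{i + 1:03d}", seed=sid)
        )
    return records


def cohort_metadata(records: list[SessionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "cvsq_pre": [r.cvsq_pre for r in records],
            "cvsq_post": [r.cvsq_post for r in records],
            "cff_pre": [r.cff_pre for r in records],
            "cff_post": [r.cff_post for r in records],
            "truth_group": [r.truth_group for r in records],
        }
    )


def write_cohort(records: list[SessionRecord], out_dir: str | Path) -> None:
    """Write one trace CSV per session phase plus a cohort metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r in records:
        traces_to_csv(r.pre_trace, out / f"{r.participant_id}_pre.csv")
        traces_to_csv(r.post_trace, out / f"{r.participant_id}_post.csv")
    cohort_metadata(records).to_csv(out / "cohort.csv", index=False)


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


@dataclass
class EyeGeometry:
    """Layout of one rendered eye within a grayscale frame."""

    image_shape: tuple[int, int] = (180, 320)
    eye_half_width: float = 140.0
    iris_radius: float = 55.0
    background_level: int = 180
    sclera_level: int = 245
    iris_level: int = 120
    pupil_level: int = 30

    def validate(self, trace: OcularTrace) -> None:
        h, w = self.image_shape
        if self.iris_radius >= min(h, w) / 2 + max(h, w):
            raise ValueError("iris radius inconsistent with image size")
        if self.eye_half_width > w:
            raise ValueError("eye width exceeds image width")
        max_pupil = np.nanmax(trace.pupil_diameter) if np.any(trace.valid) else 0.0
        if max_pupil / 2 > self.iris_radius:
            raise ValueError("pupil larger than iris radius")


def render_frames_and_masks(
    trace: OcularTrace, geometry: EyeGeometry | None = None
) -> tuple[np.ndarray, list[FrameMasks]]:
    """Rasterize a trace into grayscale frames plus exact ground-truth masks.

    The palpebral aperture is an ellipse whose vertical extent equals the
    frame's fissure length; sclera is bright, the iris disk mid-gray and
    the pupil disk dark.  Iris and pupil masks are clipped to the aperture,
    and the pupil mask is contained in the iris mask by construction.
    """
    geometry = geometry or EyeGeometry()
    geometry.validate(trace)
    h, w = geometry.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    frames = np.full((trace.n_frames, h, w), geometry.background_level, dtype=np.uint8)
    masks: list[FrameMasks] = []
    for k in range(trace.n_frames):
        fissure = trace.fissure_length[k]
        if fissure >= 1.0:
            a, b = geometry.eye_half_width / 2.0, fissure / 2.0
            aperture = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        else:
            aperture = np.zeros((h, w), dtype=bool)
        if trace.valid[k] and np.isfinite(trace.pupil_x[k]):
            px, py = trace.pupil_x[k], trace.pupil_y[k]
        else:
            px, py = cx, cy
        d2 = (xx - px) ** 2 + (yy - py) ** 2
        if trace.valid[k] and np.isfinite(trace.pupil_diameter[k]):
            iris = (d2 <= geometry.iris_radius**2) & aperture
            pr = trace.pupil_diameter[k] / 2.0
            pupil = (d2 <= pr**2) & aperture
        else:  # closed eye: only the eyelid slit, no visible iris/pupil
            iris = np.zeros((h, w), dtype=bool)
            pupil = np.zeros((h, w), dtype=bool)
        img = frames[k]
        img[aperture] = geometry.sclera_level
        img[iris] = geometry.iris_level
        img[pupil] = geometry.pupil_level
        masks.append(
            FrameMasks(
                frame_index=k,
                masks={
                    ("palpebral_fissure", trace.eye): aperture,
                    ("iris", trace.eye): iris,
                    ("pupil", trace.eye): pupil,
                },
            )
        )
    return frames, masks
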