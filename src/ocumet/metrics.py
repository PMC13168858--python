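"""Objective ocular metrics from traces or mask stacks.

Blink statistics, PERCLOS, I-DT fixations, cumulative eye movement,
pupil constriction speeds and windowed variability features, assembled
into post-minus-pre difference vectors per session.

Conventions
-----------
* Analysis window: frames [200, 1800) — the initial 200 frames carry
  eye-opening transients and are discarded.
* Closure criterion: fissure length <= 20% of the 95th-percentile open
  baseline (aligned with the 80%-closed PERCLOS definition); blinks are
  runs of >= 2 such frames.
* Variability uses sample (n-1) statistics; CV is reported in percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segeval import FrameMasks
from .trace import OcularTrace, TracePair

ANALYSIS_START = 200
ANALYSIS_STOP = 1800

#: Half-open frame windows used for variability features.
WINDOWS: dict[str, tuple[int, int]] = {
    "early": (200, 600),
    "mid": (600, 1200),
    "late": (1200, 1800),
    "all": (200, 1800),
}

VARIABILITY_SIGNALS = ("pupil_size", "fissure_length")


@dataclass
class WindowSpec:
    name: str
    start_frame: int
    end_frame: int  # exclusive

    @classmethod
    def named(cls, name: str) -> "WindowSpec":
        start, stop = WINDOWS[name]
        return cls(name, start, stop)


@dataclass
class BlinkEvent:
    start_frame: int
    end_frame: int  # inclusive
    duration: float  # ms

    @classmethod
    def from_bounds(cls, start: int, end: int, frame_rate: float) -> "BlinkEvent":
        return cls(start, end, (end - start + 1) * 1000.0 / frame_rate)


@dataclass
class FixationEvent:
    start_frame: int
    end_frame: int  # inclusive
    centroid: tuple[float, float]
    duration: float  # ms


# ---------------------------------------------------------------------------
# masks -> trace
# ---------------------------------------------------------------------------


def trace_from_masks(
    mask_stack: list[FrameMasks], frame_rate: float, eye: str = "left"
) -> OcularTrace:
    """Derive a per-frame trace from a segmentation mask stack.

    Fissure length is the vertical extent of the fissure mask; pupil
    diameter is that of the circle with the pupil mask's area; the
    centroid is the pupil mask centroid.  Frames with an empty pupil
    mask are marked invalid.
    """
    if not mask_stack:
        raise ValueError("mask stack is empty")
    shapes = set()
    n = len(mask_stack)
    fissure = np.zeros(n)
    diam = np.full(n, np.nan)
    px = np.full(n, np.nan)
    py = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for k, fm in enumerate(mask_stack):
        for m in fm.masks.values():
            shapes.add(m.shape)
        if len(shapes) > 1:
            raise ValueError("inconsistent image shapes in mask stack")
        fmask = fm.get("palpebral_fissure", eye)
        if fmask is not None and fmask.any():
            rows = np.nonzero(fmask.any(axis=1))[0]
            fissure[k] = rows.max() - rows.min() + 1
        pmask = fm.get("pupil", eye)
        if pmask is not None and pmask.any():
            area = int(pmask.sum())
            diam[k] = 2.0 * math.sqrt(area / math.pi)
            ys, xs = np.nonzero(pmask)
            px[k], py[k] = xs.mean(), ys.mean()
            valid[k] = True
    return OcularTrace(
        eye=eye,
        frame_rate=frame_rate,
        fissure_length=fissure,
        pupil_diameter=diam,
        pupil_x=px,
        pupil_y=py,
        valid=valid,
    )


# ---------------------------------------------------------------------------
# blinks and PERCLOS
# ---------------------------------------------------------------------------


def _closure_mask(trace: OcularTrace, closure_fraction: float) -> tuple[np.ndarray, float]:
    baseline = float(np.percentile(trace.fissure_length, 95))
    return trace.fissure_length <= (1.0 - closure_fraction) * baseline, baseline


def detect_blinks(trace: OcularTrace, closure_fraction: float = 0.8) -> list[BlinkEvent]:
    """Blinks = maximal runs of >= 2 frames at or below the closure threshold."""
    closed, baseline = _closure_mask(trace, closure_fraction)
    if baseline <= 0:
        warnings.warn("trace never opens (flat-zero fissure); no blinks", stacklevel=2)
        return []
    events: list[BlinkEvent] = []
    i = 0
    n = trace.n_frames
    while i < n:
        if not closed[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and closed[j + 1]:
            j += 1
        if j - i + 1 >= 2:  # reject single-frame segmentation noise
            events.append(BlinkEvent.from_bounds(i, j, trace.frame_rate))
        i = j + 1
    return events


def blink_metrics(
    events: list[BlinkEvent], analyzed_duration: float, frame_rate: float = 30.0
) -> tuple[float, float, float]:
    """Return ``(blinks/min, mean duration ms, mean offset-to-onset interval ms)``.

    Duration and interval are NaN when undefined (0 events / < 2 events).
    """
    if analyzed_duration <= 0:
        raise ValueError("analyzed_duration must be positive")
    rate = len(events) / (analyzed_duration / 60.0)
    if not events:
        return rate, float("nan"), float("nan")
    avg_duration = float(np.mean([e.duration for e in events]))
    if len(events) < 2:
        return rate, avg_duration, float("nan")
    gaps = [
        (events[i + 1].start_frame - events[i].end_frame) * 1000.0 / frame_rate
        for i in range(len(events) - 1)
    ]
    return rate, avg_duration, float(np.mean(gaps))


def perclos(trace: OcularTrace, closure_fraction: float = 0.8) -> float:
    """Percentage of analyzed frames with the eye at least 80% closed."""
    closed, _ = _closure_mask(trace, closure_fraction)
    return 100.0 * float(closed.sum()) / trace.n_frames


# ---------------------------------------------------------------------------
# fixations and movement
# ---------------------------------------------------------------------------


def detect_fixations(
    trace: OcularTrace, dispersion_px: float = 15.0, min_duration_ms: float = 100.0
) -> list[FixationEvent]:
    """Dispersion-threshold (I-DT) fixation detection on valid frames.

    A fixation is a maximal window whose centroid bounding box satisfies
    ``max(dx, dy) <= dispersion_px`` for at least ``min_duration_ms``;
    invalid (blink) frames terminate windows.
    """
    fps = trace.frame_rate
    min_frames = max(1, math.ceil(min_duration_ms * fps / 1000.0))
    x, y, valid = trace.pupil_x, trace.pupil_y, trace.valid
    events: list[FixationEvent] = []
    n = trace.n_frames
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        run_end = i
        while run_end + 1 < n and valid[run_end + 1]:
            run_end += 1
        pos = i
        while pos + min_frames - 1 <= run_end:
            end = pos + min_frames - 1
            if _dispersion(x, y, pos, end) > dispersion_px:
                pos += 1
                continue
            while end + 1 <= run_end and _dispersion(x, y, pos, end + 1) <= dispersion_px:
                end += 1
            events.append(
                FixationEvent(
                    start_frame=pos,
                    end_frame=end,
                    centroid=(float(np.mean(x[pos : end + 1])), float(np.mean(y[pos : end + 1]))),
                    duration=(end - pos + 1) * 1000.0 / fps,
                )
            )
            pos = end + 1
        i = run_end + 1
    return events


def _dispersion(x: np.ndarray, y: np.ndarray, start: int, end: int) -> float:
    xs = x[start : end + 1]
    ys = y[start : end + 1]
    return max(float(xs.max() - xs.min()), float(ys.max() - ys.min()))


def movement_distance(trace: OcularTrace) -> float:
    """Cumulative Euclidean centroid distance over valid consecutive pairs."""
    valid = trace.valid
    if valid.sum() < 2:
        warnings.warn("fewer than 2 valid frames; movement distance is 0", stacklevel=2)
        return 0.0
    both = valid[:-1] & valid[1:]
    dx = np.diff(trace.pupil_x)[both]
    dy = np.diff(trace.pupil_y)[both]
    return float(np.sum(np.hypot(dx, dy)))


# ---------------------------------------------------------------------------
# pupil dynamics and variability
# ---------------------------------------------------------------------------


def constriction_speeds(trace: OcularTrace) -> tuple[float, float]:
    """Max and mean pupil constriction speed in px/s (0 when none occur).

    Only negative diameter steps between consecutive valid frames count
    as constriction; dilation steps are excluded.
    """
    valid = trace.valid
    both = valid[:-1] & valid[1:]
    v = np.diff(trace.pupil_diameter)[both] * trace.frame_rate
    con = -v[v < 0]
    if con.size == 0:
        return 0.0, 0.0
    return float(con.max()), float(con.mean())


def windowed_variability(
    trace: OcularTrace, window: WindowSpec, signal: str
) -> tuple[float, float, float]:
    """Sample SD, variance and CV (%) of a signal inside a frame window.

    Invalid frames are excluded for ``pupil_size`` (the pupil is not
    visible) but included for ``fissure_length`` (closure is real eyelid
    behaviour).  Returns NaNs with < 2 usable samples; CV is NaN for a
    non-positive mean.
    """
    if signal not in VARIABILITY_SIGNALS:
        raise ValueError(f"signal must be one of {VARIABILITY_SIGNALS}")
    start = max(0, window.start_frame)
    stop = min(trace.n_frames, window.end_frame)
    if stop <= start:
        return float("nan"), float("nan"), float("nan")
    if signal == "pupil_size":
        values = trace.pupil_diameter[start:stop]
        values = values[trace.valid[start:stop] & np.isfinite(values)]
    else:
        values = trace.fissure_length[start:stop]
    if values.size < 2:
        return float("nan"), float("nan"), float("nan")
    sd = float(np.std(values, ddof=1))
    var = sd * sd
    mean = float(np.mean(values))
    cv = 100.0 * sd / mean if mean > 0 else float("nan")
    return sd, var, cv


# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------

BASE_FEATURES = [
    "blink_times_per_min",
    "avg_blink_duration",
    "avg_blink_interval",
    "perclos",
    "fixation_number_per_min",
    "avg_fixation_duration",
    "avg_eye_movement_distance",
    "avg_pupil_diameter",
    "max_pupil_constriction_speed",
    "avg_pupil_constriction_speed",
]

VARIABILITY_FEATURES = [
    f"{sig}_{stat}_{win}"
    for sig in VARIABILITY_SIGNALS
    for stat in ("sd", "variance", "cv")
    for win in WINDOWS
]

FEATURE_NAMES = BASE_FEATURES + VARIABILITY_FEATURES + ["cff"]


@dataclass
class FeatureVector:
    """Named pre/post metric values and their post-minus-pre differences."""

    pre: dict[str, float] = field(default_factory=dict)
    post: dict[str, float] = field(default_factory=dict)
    diff: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for name in FEATURE_NAMES:
            row[f"{name}_pre"] = self.pre.get(name, float("nan"))
            row[f"{name}_post"] = self.post.get(name, float("nan"))
            row[f"{name}_diff"] = self.diff.get(name, float("nan"))
        return row


def _eye_metrics(trace: OcularTrace) -> dict[str, float]:
    analyzed = trace.window(ANALYSIS_START, min(ANALYSIS_STOP, trace.n_frames))
    duration_s = analyzed.duration_seconds
    blinks = detect_blinks(analyzed)
    rate, dur, interval = blink_metrics(blinks, duration_s, analyzed.frame_rate)
    fixations = detect_fixations(analyzed)
    fix_rate = len(fixations) / (duration_s / 60.0)
    fix_dur = float(np.mean([f.duration for f in fixations])) if fixations else float("nan")
    with np.errstate(invalid="ignore"):
        diam = trace.pupil_diameter[ANALYSIS_START : min(ANALYSIS_STOP, trace.n_frames)]
        diam = diam[np.isfinite(diam)]
    max_speed, avg_speed = constriction_speeds(analyzed)
    out = {
        "blink_times_per_min": rate,
        "avg_blink_duration": dur,
        "avg_blink_interval": interval,
        "perclos": perclos(analyzed),
        "fixation_number_per_min": fix_rate,
        "avg_fixation_duration": fix_dur,
        "avg_eye_movement_distance": movement_distance(analyzed),
        "avg_pupil_diameter": float(diam.mean()) if diam.size else float("nan"),
        "max_pupil_constriction_speed": max_speed,
        "avg_pupil_constriction_speed": avg_speed,
    }
    for win in WINDOWS:
        spec = WindowSpec.named(win)
        for sig in VARIABILITY_SIGNALS:
            sd, var, cv = windowed_variability(trace, spec, sig)
            out[f"{sig}_sd_{win}"] = sd
            out[f"{sig}_variance_{win}"] = var
            out[f"{sig}_cv_{win}"] = cv
    return out


def _combine_eyes(pair: TracePair) -> dict[str, float]:
    per_eye = [_eye_metrics(t) for t in pair.values()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            name: float(np.nanmean([m[name] for m in per_eye]))
            for name in per_eye[0]
        }


def session_feature_vector(
    pre: TracePair,
    post: TracePair,
    cff_pre: float | None = None,
    cff_post: float | None = None,
) -> FeatureVector:
    """Compute all metrics on pre and post traces and their differences.

    Metrics are computed per eye over frames [200, 1800) and averaged
    across the two eyes; the CFF difference is NaN when either value is
    missing.
    """
    pre_m = _combine_eyes(pre)
    post_m = _combine_eyes(post)
    if cff_pre is not None and cff_post is not None:
        pre_m["cff"] = float(cff_pre)
        post_m["cff"] = float(cff_post)
    else:
        pre_m["cff"] = float("nan")
        post_m["cff"] = float("nan")
    diff = {name: post_m[name] - pre_m[name] for name in pre_m}
    return FeatureVector(pre=pre_m, post=post_m, diff=diff)


def cohort_feature_table(records, per_eye: bool = False) -> pd.DataFrame:
    """One feature row per session (or per eye with ``per_eye=True``).

    Adds participant id, truth group, CVS-Q scores and the derived
    deterioration label.
    """
    from .stats import label_deterioration

    rows = []
    for rec in records:
        units = (
            [(rec.participant_id, rec.pre_trace, rec.post_trace)]
            if not per_eye
            else [
                (f"{rec.participant_id}_{eye}", {eye: rec.pre_trace[eye]}, {eye: rec.post_trace[eye]})
                for eye in sorted(rec.pre_trace)
            ]
        )
        for uid, pre, post in units:
            fv = session_feature_vector(pre, post, rec.cff_pre, rec.cff_post)
            row = {
                "participant_id": uid,
                "truth_group": rec.truth_group,
                "cvsq_pre": rec.cvsq_pre,
                "cvsq_post": rec.cvsq_post,
                "label": label_deterioration(rec.cvsq_pre, rec.cvsq_post),
            }
            row.update(fv.to_row())
            rows.append(row)
    return pd.DataFrame(rows)
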