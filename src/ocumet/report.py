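"""Per-session risk classification and JSON report assembly."""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metrics as om
from .trace import TracePair

RISK_THRESHOLD = 0.5  # boundary probability is assigned to "high"


@dataclass
class ModelBundle:
    """A fitted classifier plus everything needed to apply it."""

    estimator: object
    zscore_stats: dict
    feature_names: list[str]
    family: str
    params: dict
    seed: int
    config_hash: str = ""

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        with open(path, "rb") as fh:
            return pickle.load(fh)


class FeatureSchemaError(ValueError):
    pass


def classify_session_risk(
    features: dict[str, float] | om.FeatureVector,
    bundle: ModelBundle,
    threshold: float = RISK_THRESHOLD,
) -> tuple[str, float]:
    """Return (risk level, deteriorated-class probability).

    ``features`` maps difference-feature names to values; the names must
    cover the model's training schema.
    """
    from .model import _positive_proba

    if isinstance(features, om.FeatureVector):
        features = {f"{k}_diff": v for k, v in features.diff.items()}
    missing = [n for n in bundle.feature_names if n not in features]
    if missing:
        raise FeatureSchemaError(f"missing features: {missing}")
    x = np.array([[features[n] for n in bundle.feature_names]], dtype=float)
    sd = np.where(bundle.zscore_stats["sd"] == 0, 1.0, bundle.zscore_stats["sd"])
    xz = (x - bundle.zscore_stats["mean"]) / sd
    prob = float(_positive_proba(bundle.estimator, xz)[0])
    return ("high" if prob >= threshold else "low"), prob


@dataclass
class SessionReport:
    participant_id: str
    risk_level: str | None
    risk_probability: float | None
    summary: dict
    time_series: dict
    provenance: dict
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "risk_level": self.risk_level,
            "risk_probability": self.risk_probability,
            "summary": self.summary,
            "time_series": self.time_series,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }


def _round_list(values: np.ndarray, nd: int = 2) -> list:
    return [None if not np.isfinite(v) else round(float(v), nd) for v in values]


def build_session_report(
    participant_id: str,
    traces: TracePair,
    risk: tuple[str, float] | None = None,
    seed: int | None = None,
    model_id: str | None = None,
    config_hash: str = "",
) -> SessionReport:
    """Summarize one recording into a serializable session report.

    The "mean square error of fixation duration" is computed as the mean
    squared deviation of fixation durations about their mean (an
    interpretation, flagged in the provenance block).
    """
    warn: list[str] = []
    per_eye_summaries = []
    series: dict = {}
    for eye, trace in sorted(traces.items()):
        analyzed = trace.window(om.ANALYSIS_START, min(om.ANALYSIS_STOP, trace.n_frames))
        blinks = om.detect_blinks(analyzed)
        fixations = om.detect_fixations(analyzed)
        durations = np.array([f.duration for f in fixations])
        mse = float(np.mean((durations - durations.mean()) ** 2)) if durations.size else None
        mean_blink = float(np.mean([b.duration for b in blinks])) if blinks else None
        if not blinks:
            warn.append(f"{eye}: no blinks detected; blink duration is null")
        per_eye_summaries.append(
            {
                "blink_count": len(blinks),
                "mean_blink_duration_ms": mean_blink,
                "fixation_count": len(fixations),
                "mean_fixation_duration_ms": float(durations.mean()) if durations.size else None,
                "fixation_duration_mse_ms2": mse,
                "perclos_pct": om.perclos(analyzed),
            }
        )
        closed = analyzed.fissure_length <= 0.2 * np.percentile(analyzed.fissure_length, 95)
        series[eye] = {
            "blink_status": [int(v) for v in closed],
            "fissure_length_px": _round_list(analyzed.fissure_length),
            "pupil_size_px": _round_list(analyzed.pupil_diameter),
            "pupil_trajectory_x_px": _round_list(analyzed.pupil_x),
            "pupil_trajectory_y_px": _round_list(analyzed.pupil_y),
            "blink_durations_ms": [round(b.duration, 1) for b in blinks],
            "blink_intervals_ms": [
                round((blinks[i + 1].start_frame - blinks[i].end_frame) * 1000.0 / analyzed.frame_rate, 1)
                for i in range(len(blinks) - 1)
            ],
        }
    any_trace = next(iter(traces.values()))

    def _avg(key):
        vals = [s[key] for s in per_eye_summaries if s[key] is not None]
        return float(np.mean(vals)) if vals else None

    summary = {
        "total_time_s": any_trace.duration_seconds,
        "blink_count": _avg("blink_count"),
        "mean_blink_duration_ms": _avg("mean_blink_duration_ms"),
        "fixation_count": _avg("fixation_count"),
        "mean_fixation_duration_ms": _avg("mean_fixation_duration_ms"),
        "fixation_duration_mse_ms2": _avg("fixation_duration_mse_ms2"),
        "perclos_pct": _avg("perclos_pct"),
    }
    return SessionReport(
        participant_id=participant_id,
        risk_level=risk[0] if risk else None,
        risk_probability=risk[1] if risk else None,
        summary=summary,
        time_series=series,
        provenance={
            "seed": seed,
            "model": model_id,
            "config_hash": config_hash,
            "notes": [
                "fixation_duration_mse interpreted as variance of fixation durations",
                "summary metrics averaged across eyes",
            ],
        },
        warnings=warn,
    )


def write_report(report: SessionReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
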