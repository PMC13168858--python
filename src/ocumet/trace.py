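"""Per-frame ocular time-series data model and CSV serialization.

An :class:`OcularTrace` holds, for one eye, per-frame palpebral fissure
length, pupil diameter and pupil centroid, plus a validity flag that is
``False`` whenever the pupil is not visible (eye closure).  Frames are
0-based and contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

EYES = ("left", "right")

#: CSV schema for trace round trips.
TRACE_COLUMNS = [
    "frame",
    "eye",
    "fissure_length_px",
    "pupil_diameter_px",
    "pupil_x_px",
    "pupil_y_px",
    "valid",
]


@dataclass
class GroundTruthEvents:
    """Event log attached by the simulator (never serialized to CSV).

    ``blinks`` and ``fixations`` are lists of inclusive ``(start, end)``
    frame bounds.
    """

    blinks: list[tuple[int, int]] = field(default_factory=list)
    fixations: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class OcularTrace:
    """One eye's per-frame signal arrays at a fixed frame rate."""

    eye: str
    frame_rate: float
    fissure_length: np.ndarray
    pupil_diameter: np.ndarray
    pupil_x: np.ndarray
    pupil_y: np.ndarray
    valid: np.ndarray
    truth: GroundTruthEvents | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        self.fissure_length = np.asarray(self.fissure_length, dtype=float)
        self.pupil_diameter = np.asarray(self.pupil_diameter, dtype=float)
        self.pupil_x = np.asarray(self.pupil_x, dtype=float)
        self.pupil_y = np.asarray(self.pupil_y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.fissure_length)
        for name in ("pupil_diameter", "pupil_x", "pupil_y", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch: {name}")
        if n == 0:
            raise ValueError("trace must contain at least one frame")
        if np.any(self.fissure_length < 0):
            raise ValueError("fissure_length must be non-negative")
        # validity implies a defined pupil diameter
        self.valid = self.valid & np.isfinite(self.pupil_diameter)

    @property
    def n_frames(self) -> int:
        return len(self.fissure_length)

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.frame_rate

    def window(self, start: int, stop: int) -> "OcularTrace":
        """Return the half-open frame window ``[start, stop)`` as a new trace.

        The ground-truth event log is not carried over.
        """
        start = max(0, start)
        stop = min(self.n_frames, stop)
        if stop <= start:
            raise ValueError(f"empty window [{start}, {stop})")
        return OcularTrace(
            eye=self.eye,
            frame_rate=self.frame_rate,
            fissure_length=self.fissure_length[start:stop].copy(),
            pupil_diameter=self.pupil_diameter[start:stop].copy(),
            pupil_x=self.pupil_x[start:stop].copy(),
            pupil_y=self.pupil_y[start:stop].copy(),
            valid=self.valid[start:stop].copy(),
        )

    def copy(self) -> "OcularTrace":
        return replace(
            self,
            fissure_length=self.fissure_length.copy(),
            pupil_diameter=self.pupil_diameter.copy(),
            pupil_x=self.pupil_x.copy(),
            pupil_y=self.pupil_y.copy(),
            valid=self.valid.copy(),
        )


TracePair = dict[str, OcularTrace]  # keyed by eye


def traces_to_frame(traces: TracePair) -> pd.DataFrame:
    """Stack one or two eye traces into a long-format data frame."""
    rows = []
    for eye in sorted(traces):
        t = traces[eye]
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(t.n_frames),
                    "eye": eye,
                    "fissure_length_px": t.fissure_length,
                    "pupil_diameter_px": t.pupil_diameter,
                    "pupil_x_px": t.pupil_x,
                    "pupil_y_px": t.pupil_y,
                    "valid": t.valid.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def traces_to_csv(traces: TracePair, path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def traces_from_csv(path: str | Path, frame_rate: float = 30.0) -> TracePair:
    """Read a trace CSV back into per-eye :class:`OcularTrace` objects."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    out: TracePair = {}
    for eye, sub in df.groupby("eye"):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise ValueError(f"frames for eye {eye!r} are not contiguous from 0")
        out[str(eye)] = OcularTrace(
            eye=str(eye),
            frame_rate=frame_rate,
            fissure_length=sub["fissure_length_px"].to_numpy(),
            pupil_diameter=sub["pupil_diameter_px"].to_numpy(),
            pupil_x=sub["pupil_x_px"].to_numpy(),
            pupil_y=sub["pupil_y_px"].to_numpy(),
            valid=sub["valid"].to_numpy().astype(bool),
        )
    return out
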