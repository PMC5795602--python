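"""Motion quantification from marker trajectories.

Movement is defined as the AC component of each coordinate: for a window
of N samples, RMS = sqrt(mean((coord - mean(coord))^2)), with the mean
taken over the same window. Thorax motion averages the per-axis RMS over
markers 2, 3, 4 and 6 (head and arm markers are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    MarkerTrajectory,
    ProtocolEpisode,
    THORAX_MARKERS,
    ValidationError,
)


@dataclass
class MotionSummary:
    """Per-axis RMS displacement (mm) over one analysis window."""

    rms_x: float
    rms_y: float
    rms_z: float
    window: Tuple[float, float]
    markers_used: List[int]


def _window_slice(fs: float, n: int, window: Tuple[float, float]) -> slice:
    t0, t1 = window
    if not t0 < t1:
        raise ValidationError("window must satisfy t_start < t_end")
    i0 = max(int(round(t0 * fs)), 0)
    i1 = min(int(round(t1 * fs)), n)
    if i1 - i0 < 2:
        raise ValidationError("window must contain at least 2 samples")
    return slice(i0, i1)


def _rms_ac(v: np.ndarray) -> float:
    if np.ptp(v) == 0:  # constant: AC component is exactly zero
        return 0.0
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def rms_displacement(
    traj: MarkerTrajectory, window: Tuple[float, float]
) -> MotionSummary:
    """Per-axis RMS of the AC displacement of one marker over a window."""
    sl = _window_slice(traj.fs, traj.n, window)
    return MotionSummary(
        rms_x=_rms_ac(traj.x[sl]),
        rms_y=_rms_ac(traj.y[sl]),
        rms_z=_rms_ac(traj.z[sl]),
        window=window,
        markers_used=[traj.marker_id],
    )


def thorax_motion(
    markers: Sequence[MarkerTrajectory], window: Tuple[float, float]
) -> MotionSummary:
    """Thorax motion: mean per-axis RMS over markers 2, 3, 4 and 6."""
    by_id = {m.marker_id: m for m in markers}
    missing = [mid for mid in THORAX_MARKERS if mid not in by_id]
    if missing:
        raise ValidationError(f"missing thorax markers: {missing}")
    summaries = [rms_displacement(by_id[mid], window) for mid in THORAX_MARKERS]
    return MotionSummary(
        rms_x=float(np.mean([s.rms_x for s in summaries])),
        rms_y=float(np.mean([s.rms_y for s in summaries])),
        rms_z=float(np.mean([s.rms_z for s in summaries])),
        window=window,
        markers_used=list(THORAX_MARKERS),
    )


def per_episode_motion(
    markers: Sequence[MarkerTrajectory], episodes: Sequence[ProtocolEpisode]
) -> pd.DataFrame:
    """One thorax MotionSummary per protocol episode, as a table."""
    rows = []
    for ep in episodes:
        s = thorax_motion(markers, (ep.t_start, ep.t_end))
        rows.append(
            {
                "maneuver": ep.maneuver,
                "amplitude_class": ep.amplitude_class,
                "t_start": ep.t_start,
                "t_end": ep.t_end,
                "rms_x": s.rms_x,
                "rms_y": s.rms_y,
                "rms_z": s.rms_z,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "maneuver", "amplitude_class", "t_start", "t_end",
            "rms_x", "rms_y", "rms_z",
        ],
    )


def windowed_thorax_motion(
    markers: Sequence[MarkerTrajectory],
    centers: Sequence[float],
    win_s: float,
) -> pd.DataFrame:
    """Thorax motion in sliding windows centered on ``centers``."""
    n = markers[0].n
    fs = markers[0].fs
    rows = []
    for c in centers:
        t0 = max(c - win_s / 2, 0.0)
        t1 = min(c + win_s / 2, n / fs)
        s = thorax_motion(markers, (t0, t1))
        rows.append({"t": c, "rms_x": s.rms_x, "rms_y": s.rms_y, "rms_z": s.rms_z})
    return pd.DataFrame(rows, columns=["t", "rms_x", "rms_y", "rms_z"])
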