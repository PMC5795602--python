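"""Mixed-level interval fusion.

The self-similarity estimator (LIE) fuses channels at the signal level;
the decision rule here adds feature-level fusion with the QRS-derived
intervals from the capacitive ECG: whenever a Pan-Tompkins interval is
available near a LIE emission and the two estimators agree to within
``delta_th_ms``, the ECG-derived value (electrically locked to the
R-peak, hence more precise) replaces the LIE value. Otherwise the LIE
value stands. The rule swaps values but never adds or removes
emissions, so coverage is defined by the LIE stream throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .types import (
    BeatAnnotations,
    INTERVAL_RANGE_MS,
    IntervalEstimate,
    ValidationError,
)


@dataclass
class FusionConfig:
    """Decision-rule parameters: agreement threshold and pairing window."""

    delta_th_ms: float = 40.0
    pairing_tol_s: float = 1.0

    def __post_init__(self):
        if self.delta_th_ms < 0:
            raise ValidationError("delta_th_ms must be >= 0")
        if self.pairing_tol_s <= 0:
            raise ValidationError("pairing_tol_s must be > 0")


def pt_to_intervals(beats: BeatAnnotations, fs: float) -> List[IntervalEstimate]:
    """RR intervals (ms) from QRS detections, timestamped at midpoints.

    Intervals outside the physiologic range [333, 2000] ms are dropped.
    """
    b = beats.beat_samples
    if b.size < 2:
        return []
    out = []
    lo, hi = INTERVAL_RANGE_MS
    for b0, b1 in zip(b[:-1], b[1:]):
        interval = (b1 - b0) / fs * 1000.0
        if lo <= interval <= hi:
            out.append(IntervalEstimate((b0 + b1) / 2 / fs, interval, "PT"))
    return out


def fuse_intervals(
    lie: Sequence[IntervalEstimate],
    pt: Sequence[IntervalEstimate],
    cfg: FusionConfig = FusionConfig(),
) -> List[IntervalEstimate]:
    """Apply the delta_th decision rule to paired interval streams.

    For each LIE interval the nearest-in-time PT interval within
    ``pairing_tol_s`` is its candidate; if the candidate exists and
    |PT - LIE| < delta_th_ms, the PT value is emitted, else the LIE
    value. PT intervals without a LIE partner are never emitted.
    """
    pt_t = np.array([e.t for e in pt])
    out = []
    for est in lie:
        value, prov = est.interval_ms, "LIE"
        if pt_t.size:
            j = int(np.argmin(np.abs(pt_t - est.t)))
            if abs(pt_t[j] - est.t) <= cfg.pairing_tol_s:
                if abs(pt[j].interval_ms - est.interval_ms) < cfg.delta_th_ms:
                    value, prov = pt[j].interval_ms, "PT"
        out.append(
            IntervalEstimate(
                est.t, value, "FUSED", reliability=est.reliability, provenance=prov
            )
        )
    return out


def fraction_replaced(fused: Sequence[IntervalEstimate]) -> float:
    """Share of fused emissions whose value came from the PT estimator."""
    if not fused:
        return 0.0
    return sum(e.provenance == "PT" for e in fused) / len(fused)


def sweep_delta_th(
    lie: Sequence[IntervalEstimate],
    pt: Sequence[IntervalEstimate],
    ref_intervals: Sequence[IntervalEstimate],
    grid: Sequence[float],
    pairing_tol_s: float = 1.0,
) -> pd.DataFrame:
    """Evaluate the fusion rule over a grid of delta_th values.

    Returns a table (delta_th_ms, mae_ms, coverage_pct,
    fraction_replaced). The grid must be non-empty and include 0 (the
    LIE-only limit).
    """
    from .evaluate import score  # local import; evaluation depends on types only

    grid = list(grid)
    if not grid or 0 not in [float(g) for g in grid]:
        raise ValidationError("delta_th grid must be non-empty and include 0")
    rows = []
    for dth in grid:
        fused = fuse_intervals(
            lie, pt, FusionConfig(delta_th_ms=float(dth), pairing_tol_s=pairing_tol_s)
        )
        rep = score(fused, ref_intervals)
        rows.append(
            {
                "delta_th_ms": float(dth),
                "mae_ms": rep.mae_ms,
                "coverage_pct": rep.coverage_pct,
                "fraction_replaced": fraction_replaced(fused),
            }
        )
    return pd.DataFrame(
        rows, columns=["delta_th_ms", "mae_ms", "coverage_pct", "fraction_replaced"]
    )
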