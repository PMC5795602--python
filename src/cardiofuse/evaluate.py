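"""Scoring of interval estimates against the reference annotation.

Two figures of merit, following the evaluation convention for gated
estimators: the mean absolute beat-to-beat interval error e_abs in ms
(over matched emissions), and the coverage

    Coverage = n_emitted / n_ref * 100 %,

the share of reference intervals for which an estimate was emitted at
all. A gated estimator may trade coverage for accuracy; the moving
window curves and the motion correlations quantify exactly that
trade-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import BeatAnnotations, IntervalEstimate, ValidationError

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Summary scores of one estimate stream against the reference."""

    mae_ms: float
    coverage_pct: float
    n_emitted: int
    n_ref: int
    n_matched: int
    coverage_overrun: bool = False  # emissions exceeded references
    per_window: Optional[pd.DataFrame] = None
    correlations: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mae_ms": self.mae_ms,
            "coverage_pct": self.coverage_pct,
            "n_emitted": self.n_emitted,
            "n_ref": self.n_ref,
            "n_matched": self.n_matched,
            "coverage_overrun": self.coverage_overrun,
            "correlations": {
                ax: {"error": v[0], "coverage": v[1]}
                for ax, v in self.correlations.items()
            },
        }


def reference_intervals(
    ref_beats: BeatAnnotations, fs: float
) -> List[IntervalEstimate]:
    """Reference RR intervals in ms, timestamped at interval midpoints."""
    b = ref_beats.beat_samples
    if b.size < 2:
        return []
    return [
        IntervalEstimate((b0 + b1) / 2 / fs, (b1 - b0) / fs * 1000.0, "REF")
        for b0, b1 in zip(b[:-1], b[1:])
    ]


def match_intervals(
    estimates: Sequence[IntervalEstimate],
    refs: Sequence[IntervalEstimate],
    tol_s: float = 1.0,
) -> List[Tuple[int, int]]:
    """One-to-one nearest-in-time matching within ``tol_s``.

    Candidate (estimate, reference) pairs are ranked globally by
    |time difference| and accepted greedily, which makes the matching
    symmetric under time reversal of both lists.
    """
    cands = []
    ref_t = np.array([r.t for r in refs])
    for i, e in enumerate(estimates):
        if ref_t.size == 0:
            break
        close = np.where(np.abs(ref_t - e.t) <= tol_s)[0]
        for j in close:
            cands.append((abs(ref_t[j] - e.t), i, int(j)))
    cands.sort(key=lambda c: c[0])
    used_e, used_r, pairs = set(), set(), []
    for _, i, j in cands:
        if i in used_e or j in used_r:
            continue
        used_e.add(i)
        used_r.add(j)
        pairs.append((i, j))
    return pairs


def score(
    estimates: Sequence[IntervalEstimate],
    ref_intervals: Sequence[IntervalEstimate],
    tol_s: float = 1.0,
) -> EvalReport:
    """Mean absolute interval error and coverage of an estimate stream."""
    if not ref_intervals:
        raise ValidationError("cannot score against an empty reference")
    estimates = sorted(estimates, key=lambda e: e.t)
    refs = sorted(ref_intervals, key=lambda e: e.t)
    pairs = match_intervals(estimates, refs, tol_s)
    if pairs:
        errors = [
            abs(estimates[i].interval_ms - refs[j].interval_ms) for i, j in pairs
        ]
        mae = float(np.mean(errors))
    else:
        mae = np.nan
    n_emitted, n_ref = len(estimates), len(refs)
    coverage = n_emitted * 100.0 / n_ref
    overrun = n_emitted > n_ref
    if overrun:
        log.warning("coverage exceeds 100%% (%d emissions, %d references)",
                    n_emitted, n_ref)
    return EvalReport(
        mae_ms=mae,
        coverage_pct=coverage,
        n_emitted=n_emitted,
        n_ref=n_ref,
        n_matched=len(pairs),
        coverage_overrun=overrun,
    )


def moving_window_score(
    estimates: Sequence[IntervalEstimate],
    ref_intervals: Sequence[IntervalEstimate],
    win_s: float = 12.0,
    step_s: float = 1.0,
    tol_s: float = 1.0,
) -> pd.DataFrame:
    """Error and coverage restricted to sliding windows.

    Windows containing no reference interval are skipped; windows with
    no matched emission report NaN error but a valid coverage.
    """
    if not ref_intervals:
        raise ValidationError("cannot score against an empty reference")
    refs = sorted(ref_intervals, key=lambda e: e.t)
    ests = sorted(estimates, key=lambda e: e.t)
    t_end = refs[-1].t
    centers = np.arange(win_s / 2, t_end + step_s, step_s)
    rows = []
    for c in centers:
        t0, t1 = c - win_s / 2, c + win_s / 2
        wr = [r for r in refs if t0 <= r.t < t1]
        if not wr:
            continue
        we = [e for e in ests if t0 <= e.t < t1]
        rep = score(we, wr, tol_s) if we else None
        rows.append(
            {
                "t": float(c),
                "mae_ms": rep.mae_ms if rep else np.nan,
                "coverage_pct": rep.coverage_pct if rep else 0.0,
                "n_emitted": len(we),
                "n_ref": len(wr),
            }
        )
    return pd.DataFrame(rows, columns=["t", "mae_ms", "coverage_pct", "n_emitted", "n_ref"])


def correlate_eval_motion(
    per_window: pd.DataFrame,
    motion_per_window: pd.DataFrame,
) -> Dict[str, Tuple[float, float]]:
    """Per-axis Pearson correlations (rho_error, rho_coverage) vs motion.

    ``per_window`` comes from :func:`moving_window_score`;
    ``motion_per_window`` from
    :func:`cardiofuse.motion.windowed_thorax_motion`. Joined on window
    time ``t``. The error correlation uses only windows with a finite
    windowed error.
    """
    merged = per_window.merge(motion_per_window, on="t", how="inner")
    if len(merged) < 3:
        raise ValidationError("need at least 3 paired windows")
    out = {}
    for ax in "xyz":
        rms = merged[f"rms_{ax}"].to_numpy()
        cov = merged["coverage_pct"].to_numpy()
        err = merged["mae_ms"].to_numpy()
        ok = np.isfinite(err)
        rho_err = np.nan
        if ok.sum() >= 3 and np.std(rms[ok]) > 0 and np.std(err[ok]) > 0:
            rho_err = float(stats.pearsonr(err[ok], rms[ok]).statistic)
        rho_cov = np.nan
        if np.std(rms) > 0 and np.std(cov) > 0:
            rho_cov = float(stats.pearsonr(cov, rms).statistic)
        out[ax] = (rho_err, rho_cov)
    return out
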