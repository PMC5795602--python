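"""Shape-based signal-to-noise ratio (SNRS).

The reference segmentation (R-peaks) cuts a signal of interest into
cardiac cycles; cycles are resampled to a unit phase grid and averaged
into a template T_card(phi). Interpolating the template along the
reference segmentation yields a noise-free estimate x_tilde of the
signal, and

    SNRS = 10 log10( sum(x_tilde^2) / sum((x_tilde - x)^2) )  [dB],

with both sums over samples covered by a complete cardiac cycle. Unlike
a frequency-band SNR, SNRS rewards cycle-to-cycle shape consistency and
is therefore meaningful for band-limited sensors.

Per-episode analysis extracts the template from the artifact-free
period right after the maneuver (same 30-s slot) to accommodate
posture-induced morphology changes, and reports SNRS separately over
the maneuver window and the rest window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .motion import per_episode_motion
from .types import (
    BeatAnnotations,
    ProtocolEpisode,
    Recording,
    SignalChannel,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class CardiacTemplate:
    """One cardiac cycle on a unit phase grid [0, 1)."""

    phase_grid: np.ndarray
    values: np.ndarray
    n_cycles_used: int
    source_window: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.phase_grid = np.asarray(self.phase_grid, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.phase_grid.size < 16:
            raise ValidationError("phase resolution P must be >= 16")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("template values must be finite")
        if self.n_cycles_used < 1:
            raise ValidationError("n_cycles_used must be >= 1")

    @property
    def p(self) -> int:
        return self.phase_grid.size

    def interp(self, phi: np.ndarray) -> np.ndarray:
        """Linear interpolation at phases in [0, 1), wrapping at 1."""
        grid_ext = np.concatenate([self.phase_grid, [1.0]])
        vals_ext = np.concatenate([self.values, self.values[:1]])
        return np.interp(phi, grid_ext, vals_ext)


@dataclass
class SNRSResult:
    """SNRS in dB over one window; degenerate flags for zero sums."""

    snrs_db: float
    window: Tuple[float, float]
    modality: str
    template_ref: Tuple[float, float]
    degenerate: Optional[str] = None  # None | "zero_signal" | "zero_residual"


def segment_cycles(
    x: SignalChannel,
    ref_beats: BeatAnnotations,
    window: Tuple[float, float],
) -> List[np.ndarray]:
    """Cut the windowed signal into cardiac cycles [beat_k, beat_{k+1}).

    Only cycles fully inside the window are returned; partial leading
    and trailing cycles are dropped.
    """
    i0 = max(int(round(window[0] * x.fs)), 0)
    i1 = min(int(round(window[1] * x.fs)), x.n)
    beats = ref_beats.beat_samples
    inside = beats[(beats >= i0) & (beats <= i1)]
    if inside.size < 2:
        log.warning("fewer than 2 reference beats in window %s; no cycles", window)
        return []
    cycles = []
    for b0, b1 in zip(inside[:-1], inside[1:]):
        if b1 <= i1:
            cycles.append(x.samples[b0:b1].copy())
    return cycles


def extract_template(
    cycles: Sequence[np.ndarray],
    p: int = 200,
    source_window: Tuple[float, float] = (0.0, 0.0),
) -> CardiacTemplate:
    """Resample each cycle onto the P-point phase grid and average."""
    if not cycles:
        raise ValidationError("cannot extract a template from zero cycles")
    grid = np.arange(p) / p
    resampled = np.empty((len(cycles), p))
    for k, c in enumerate(cycles):
        phi_c = np.arange(c.size) / c.size
        resampled[k] = np.interp(grid, phi_c, c)
    return CardiacTemplate(
        phase_grid=grid,
        values=resampled.mean(axis=0),
        n_cycles_used=len(cycles),
        source_window=source_window,
    )


def approximate_signal(
    template: CardiacTemplate,
    ref_beats: BeatAnnotations,
    window: Tuple[float, float],
    fs: float,
    n_total: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free estimate x_tilde over a window via template interpolation.

    For sample n in cycle [beat_k, beat_{k+1}):
    phi = (n - beat_k) / (beat_{k+1} - beat_k); x_tilde[n] interpolates
    the template at phi. Returns ``(x_tilde, included)`` aligned to the
    window's samples; samples not covered by a complete in-window cycle
    are flagged excluded and x_tilde is 0 there.
    """
    i0 = max(int(round(window[0] * fs)), 0)
    i1 = min(int(round(window[1] * fs)), n_total)
    est = np.zeros(i1 - i0)
    included = np.zeros(i1 - i0, dtype=bool)
    beats = ref_beats.beat_samples
    inside = beats[(beats >= i0) & (beats <= i1)]
    for b0, b1 in zip(inside[:-1], inside[1:]):
        if b1 > i1:
            continue
        idx = np.arange(b0, b1)
        phi = (idx - b0) / (b1 - b0)
        est[b0 - i0 : b1 - i0] = template.interp(phi)
        included[b0 - i0 : b1 - i0] = True
    if not included.any():
        log.warning("no complete cardiac cycle inside window %s", window)
    return est, included


def compute_snrs(
    x: np.ndarray,
    x_tilde: np.ndarray,
    included: Optional[np.ndarray] = None,
    window: Tuple[float, float] = (0.0, 0.0),
    modality: str = "cECG",
    template_ref: Tuple[float, float] = (0.0, 0.0),
) -> SNRSResult:
    """SNRS = 10 log10(sum x_tilde^2 / sum (x_tilde - x)^2) over included samples."""
    x = np.asarray(x, dtype=np.float64)
    x_tilde = np.asarray(x_tilde, dtype=np.float64)
    if included is not None:
        x = x[included]
        x_tilde = x_tilde[included]
    if x.size == 0:
        raise ValidationError("SNRS needs at least one included sample")
    p_sig = float(np.sum(x_tilde**2))
    p_res = float(np.sum((x_tilde - x) ** 2))
    if p_sig == 0.0:
        return SNRSResult(-np.inf, window, modality, template_ref, "zero_signal")
    if p_res == 0.0:
        return SNRSResult(np.inf, window, modality, template_ref, "zero_residual")
    return SNRSResult(
        10.0 * np.log10(p_sig / p_res), window, modality, template_ref, None
    )


def _saturated_fraction(v: np.ndarray) -> float:
    # clipped samples sit exactly at a rail value; continuous noise
    # repeats an extreme only by clipping
    if v.size == 0:
        return 0.0
    return float(np.mean(v == v.max()) + np.mean(v == v.min())) if v.max() > v.min() else 1.0


def snrs_per_episode(
    rec: Recording,
    modality: str,
    episodes: Optional[Sequence[ProtocolEpisode]] = None,
    maneuver_s: float = 8.0,
    guard_s: float = 2.0,
    p: int = 200,
    max_saturated_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-episode SNRS table for one modality.

    For each maneuver episode a template is extracted from the rest
    window [maneuver end + guard, slot end]; SNRS is reported over both
    the maneuver window and the rest window. Episodes whose rest window
    has fewer than 2 beats or is predominantly rail-saturated are
    skipped with a warning. REST episodes are not tabulated.
    """
    ch = rec.channels[modality]
    if episodes is None:
        episodes = rec.episodes
    rows = []
    for ep in episodes:
        if ep.maneuver == "REST":
            continue
        man_win = (ep.t_start, ep.t_start + maneuver_s)
        rest_win = (ep.t_start + maneuver_s + guard_s, ep.t_end)
        i0 = int(round(rest_win[0] * ch.fs))
        i1 = int(round(rest_win[1] * ch.fs))
        if _saturated_fraction(ch.samples[i0:i1]) > max_saturated_frac:
            log.warning(
                "%s %s@%gs: rest window saturated; episode skipped",
                modality, ep.maneuver, ep.t_start,
            )
            continue
        cycles = segment_cycles(ch, rec.ref_beats, rest_win)
        if len(cycles) < 1:
            log.warning(
                "%s %s@%gs: rest window has < 2 beats; episode skipped",
                modality, ep.maneuver, ep.t_start,
            )
            continue
        template = extract_template(cycles, p=p, source_window=rest_win)
        results = {}
        for kind, win in (("maneuver", man_win), ("rest", rest_win)):
            est, inc = approximate_signal(template, rec.ref_beats, win, ch.fs, ch.n)
            j0 = max(int(round(win[0] * ch.fs)), 0)
            j1 = min(int(round(win[1] * ch.fs)), ch.n)
            if not inc.any():
                results[kind] = np.nan
                continue
            r = compute_snrs(
                ch.samples[j0:j1], est, inc, win, modality, rest_win
            )
            results[kind] = r.snrs_db
        rows.append(
            {
                "maneuver": ep.maneuver,
                "amplitude_class": ep.amplitude_class,
                "t_start": ep.t_start,
                "t_end": ep.t_end,
                "modality": modality,
                "snrs_maneuver_db": results["maneuver"],
                "snrs_rest_db": results["rest"],
                "n_cycles": template.n_cycles_used,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "maneuver", "amplitude_class", "t_start", "t_end", "modality",
            "snrs_maneuver_db", "snrs_rest_db", "n_cycles",
        ],
    )


def correlate_snrs_motion(
    snrs_table: pd.DataFrame,
    motion_table: pd.DataFrame,
    snrs_col: str = "snrs_maneuver_db",
) -> dict:
    """Pearson correlation of episode SNRS with per-axis episode RMS motion.

    Tables are joined on (maneuver, amplitude_class, t_start). Returns
    {"x": rho, "y": rho, "z": rho}; NaN marks an undefined correlation
    (zero variance or too few pairs).
    """
    merged = snrs_table.merge(
        motion_table, on=["maneuver", "amplitude_class", "t_start"], how="inner"
    )
    merged = merged[np.isfinite(merged[snrs_col])]
    out = {}
    for ax in "xyz":
        rms = merged[f"rms_{ax}"].to_numpy()
        snrs_v = merged[snrs_col].to_numpy()
        if len(merged) < 3 or np.std(rms) == 0 or np.std(snrs_v) == 0:
            log.warning("correlation undefined for axis %s", ax)
            out[ax] = np.nan
        else:
            out[ax] = float(stats.pearsonr(snrs_v, rms).statistic)
    return out


def snrs_motion_table(
    rec: Recording,
    modalities: Sequence[str],
    maneuver_s: float = 8.0,
    guard_s: float = 2.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: per-episode SNRS for several modalities + motion table."""
    motion = per_episode_motion(rec.markers, rec.episodes)
    tables = [
        snrs_per_episode(rec, m, maneuver_s=maneuver_s, guard_s=guard_s)
        for m in modalities
    ]
    return pd.concat(tables, ignore_index=True), motion
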