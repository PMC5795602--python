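"""Beat and beat-to-beat interval estimation.

Two estimators:

* :func:`pan_tompkins` — the classic QRS detector (band-pass,
  derivative, squaring, moving-window integration, adaptive dual
  thresholds with refractory period and search-back), for the ECG-type
  channels.

* the local interval estimator (LIE) — a modality-independent
  self-similarity estimator: in a sliding window, a normalized
  autocorrelation profile over the physiologic lag range scores how well
  the signal repeats at each candidate interval. The profile peak gives
  the interval; the peak-to-mean concentration ratio gates emission
  (below the threshold the segment is deemed too noisy and no interval
  is reported). Multiple channels are fused at the signal level by
  summing their profiles; an optional adaptive prior weights lags near
  the last accepted interval.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .types import (
    BeatAnnotations,
    INTERVAL_RANGE_MS,
    IntervalEstimate,
    SignalChannel,
    ValidationError,
)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Pan-Tompkins


def pan_tompkins(ecg: SignalChannel) -> BeatAnnotations:
    """Locate R-peaks with the Pan-Tompkins algorithm.

    Stages: 5-15 Hz band-pass (zero-phase), differentiation, squaring,
    150-ms moving-window integration, then adaptive dual thresholds with
    a 200-ms refractory period and search-back at 1.66x the running RR
    average. Detections are refined to the local extremum of the
    band-passed signal. The first 2 s initialize the thresholds.
    """
    fs = ecg.fs
    if fs < 50:
        raise ValidationError("pan_tompkins requires fs >= 50 Hz")
    x = ecg.samples
    learn = int(2 * fs)
    if x.size < learn:
        log.warning("signal shorter than the 2-s learning phase; no detections")
        return BeatAnnotations(np.array([], dtype=np.int64))

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(band) * fs
    sq = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return BeatAnnotations(np.array([], dtype=np.int64))

    spki = 0.6 * mwi[:learn].max()
    npki = mwi[:learn].mean()
    if spki <= npki:
        spki = npki * 2 + 1e-12
    thr1 = npki + 0.25 * (spki - npki)

    beats: List[int] = []
    rr_hist: List[float] = []
    for pk in cand:
        peak = mwi[pk]
        if peak > thr1:
            # search-back first: did we miss a beat since the last one?
            if beats and rr_hist:
                rr_avg = np.mean(rr_hist[-8:])
                if pk - beats[-1] > 1.66 * rr_avg:
                    thr2 = 0.5 * thr1
                    missed = [
                        c for c in cand
                        if beats[-1] + refractory < c < pk - refractory
                        and mwi[c] > thr2
                    ]
                    if missed:
                        mb = max(missed, key=lambda c: mwi[c])
                        rr_hist.append(mb - beats[-1])
                        beats.append(int(mb))
                        spki = 0.25 * mwi[mb] + 0.75 * spki
            if beats and pk - beats[-1] < refractory:
                continue
            if beats:
                rr_hist.append(pk - beats[-1])
            beats.append(int(pk))
            spki = 0.125 * peak + 0.875 * spki
        else:
            npki = 0.125 * peak + 0.875 * npki
        thr1 = npki + 0.25 * (spki - npki)

    # refine each detection to the band-passed local extremum
    half = int(round(0.100 * fs))
    refined = []
    for b in beats:
        lo = max(b - half, 0)
        hi = min(b + half + 1, x.size)
        refined.append(lo + int(np.argmax(np.abs(band[lo:hi]))))
    refined = np.unique(np.asarray(refined, dtype=np.int64))
    keep = np.concatenate([[True], np.diff(refined) >= refractory])
    return BeatAnnotations(refined[keep])


# --------------------------------------------------------------------------
# local interval estimator (LIE)


@dataclass
class SimilarityProfile:
    """Self-similarity score per candidate lag for one analysis window."""

    lags_ms: np.ndarray
    score: np.ndarray
    window_center: float
    unreliable: bool = False

    def __post_init__(self):
        self.lags_ms = np.asarray(self.lags_ms, dtype=np.float64)
        self.score = np.asarray(self.score, dtype=np.float64)
        if self.lags_ms.size and np.any(np.diff(self.lags_ms) <= 0):
            raise ValidationError("lag grid must be strictly increasing")
        if not np.all(np.isfinite(self.score)):
            raise ValidationError("scores must be finite")


#: Correlation noise floor: NCC values below this are statistically
#: indistinguishable from zero at the window lengths used (~3 sigma of
#: the finite-sample null) and are clamped to zero so that noise windows
#: produce near-empty profiles.
NCC_FLOOR = 0.25


def lie_similarity(
    x: SignalChannel,
    t_center: float,
    win_s: float = 3.0,
    lag_range_ms: Tuple[float, float] = INTERVAL_RANGE_MS,
    floor: float = NCC_FLOOR,
    smooth_s: float = 0.05,
) -> SimilarityProfile:
    """Normalized self-similarity profile of a window around ``t_center``.

    The profile is the geometric mean of two clamped normalized
    autocorrelation curves of the window: one of the lightly smoothed
    waveform (``smooth_s`` Hann kernel, default 50 ms — widening narrow
    QRS spikes, which would otherwise misalign completely under
    physiologic beat-to-beat jitter) and one of its amplitude envelope
    (rectified, 150-ms smoothing). Each curve is
    clip((r(tau) - floor) / (1 - floor), 0, None) with r the per-lag
    Pearson correlation of the window with itself shifted by tau. The
    waveform curve locates the repeat precisely but shows side peaks at
    the intra-beat oscillation period of multi-lobe waveforms (BCG); the
    envelope curve is blind to intra-beat structure but side-peak-free;
    only lags supported by both survive the product. A 1-s
    moving-average baseline is removed first: motion artifacts ride on
    slow baseline bumps which correlate at arbitrary lags (and a
    saturated plateau collapses to zero, so a clipped window gates
    itself out). The lag grid covers the physiologic range at sample
    resolution.
    """
    fs = x.fs
    half = int(round(win_s * fs / 2))
    c = int(round(t_center * fs))
    if c - half < 0 or c + half > x.n:
        raise ValidationError("analysis window extends beyond the signal")
    w = x.samples[c - half : c + half].astype(np.float64)
    kb = int(round(1.0 * fs))
    if kb >= 3 and w.size > kb:
        baseline = ndimage.uniform_filter1d(w, size=kb, mode="nearest")
        w = w - baseline
    n = w.size
    lag_lo = int(round(lag_range_ms[0] * fs / 1000.0))
    lag_hi = min(int(round(lag_range_ms[1] * fs / 1000.0)), n - max(int(0.3 * fs), 2))
    if lag_hi <= lag_lo:
        raise ValidationError("lag range does not fit in the analysis window")
    lags = np.arange(lag_lo, lag_hi + 1)
    lags_ms = lags * 1000.0 / fs

    if np.std(w) == 0:
        return SimilarityProfile(lags_ms, np.zeros(lags.size), t_center, True)

    wave = w
    if smooth_s > 0:
        k = int(round(smooth_s * fs))
        if k >= 3:
            kern = np.hanning(k)
            wave = np.convolve(w, kern / kern.sum(), mode="same")
    score = _clamped_ncc(wave, lags, floor)
    ke = np.hanning(max(int(round(3 * smooth_s * fs)), 3))
    env = np.convolve(np.abs(w - w.mean()), ke / ke.sum(), mode="same")
    if np.std(env) > 0:
        score = np.sqrt(score * _clamped_ncc(env, lags, floor))
    return SimilarityProfile(lags_ms, score, t_center, False)


def _clamped_ncc(w: np.ndarray, lags: np.ndarray, floor: float) -> np.ndarray:
    """Per-lag Pearson autocorrelation, noise floor subtracted and
    clamped to [0, 1]; vectorized via prefix sums and one full xcorr."""
    n = w.size
    w = w - w.mean()
    cs1 = np.concatenate([[0.0], np.cumsum(w)])
    cs2 = np.concatenate([[0.0], np.cumsum(w * w)])
    cross_full = sps.correlate(w, w, mode="full")
    m = n - lags  # overlap length per lag
    s1a = cs1[n - lags]                # sum w[0 : n-lag]
    s2a = cs2[n - lags]
    s1b = cs1[n] - cs1[lags]           # sum w[lag : n]
    s2b = cs2[n] - cs2[lags]
    cross = cross_full[n - 1 + lags]   # sum w[i] * w[i+lag]
    cov = cross - s1a * s1b / m
    va = s2a - s1a**2 / m
    vb = s2b - s1b**2 / m
    denom = np.sqrt(np.maximum(va * vb, 0.0))
    r = np.where(denom > 0, cov / np.maximum(denom, 1e-30), 0.0)
    return np.clip((r - floor) / (1.0 - floor), 0.0, None)


def lie_reliability(profile: SimilarityProfile) -> float:
    """Peak-to-mean concentration ratio of a similarity profile.

    A single-lag impulse over L lags scores L; a uniform profile scores
    1; an all-zero profile scores 0.
    """
    if profile.score.size == 0:
        return 0.0
    mean = profile.score.mean()
    if mean == 0.0:
        return 0.0
    return float(profile.score.max() / mean)


def _pick_lag(lags_ms: np.ndarray, score: np.ndarray) -> float:
    """Harmonic-summation peak picking with parabolic refinement.

    The harmonic at twice the true interval can score nearly as high as
    (under beat jitter, higher than) the fundamental. Each candidate
    peak is therefore ranked by score(tau) + score(2*tau): the
    true interval is reinforced by its own harmonic, while the harmonic
    itself finds no support at 4x. The winning peak is refined by a
    3-point parabolic fit for sub-sample lag resolution.
    """
    idx_peaks, _ = sps.find_peaks(score, height=0.25 * score.max())
    if idx_peaks.size == 0:
        idx_peaks = np.array([int(np.argmax(score))])
    # beat jitter displaces the two-beat peak from exactly 2*tau, so the
    # harmonic is sampled with a +-tolerance via a running maximum
    step = lags_ms[1] - lags_ms[0] if lags_ms.size > 1 else 10.0
    halfwidth = max(int(round(100.0 / step)), 1)
    smax = ndimage.maximum_filter1d(score, size=2 * halfwidth + 1)
    support = score + np.interp(2 * lags_ms, lags_ms, smax, left=0.0, right=0.0)
    i = int(idx_peaks[np.argmax(support[idx_peaks])])
    if 0 < i < score.size - 1:
        y0, y1, y2 = score[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            step = lags_ms[1] - lags_ms[0]
            return float(lags_ms[i] + np.clip(delta, -0.5, 0.5) * step)
    return float(lags_ms[i])


def _prior_weight(
    lags_ms: np.ndarray,
    last_interval_ms: float,
    dt_since_s: float,
    sigma0_ms: float = 120.0,
    floor: float = 0.15,
    growth_s: float = 5.0,
) -> np.ndarray:
    """Gaussian bump around the last accepted interval; widens with the
    time elapsed since the last acceptance so a stale prior fades."""
    sigma = sigma0_ms * (1.0 + dt_since_s / growth_s)
    g = np.exp(-0.5 * ((lags_ms - last_interval_ms) / sigma) ** 2)
    return floor + (1.0 - floor) * g


def lie_intervals(
    channels: Sequence[SignalChannel],
    threshold: float = 3.5,
    step_s: float = 0.5,
    win_s: float = 3.0,
    lag_range_ms: Tuple[float, float] = INTERVAL_RANGE_MS,
    prior: bool = False,
    peak_min: float = 0.5,
) -> List[IntervalEstimate]:
    """Sliding-window interval estimation with reliability gating.

    Per window, each channel's similarity profile is computed; channels
    whose own profile passes the reliability gate (peak-to-mean ratio
    >= ``threshold`` with a significant peak >= ``peak_min``) are summed
    (signal-level fusion; profiles are already on the common unit NCC
    scale). Gating each channel before the sum prevents catastrophic
    fusion: a corrupted channel would otherwise pour noise into the
    joint profile and drag down the channels that still see the heart.
    The summed profile must itself pass the same gate — channels that
    individually look reliable but disagree on the interval flatten the
    sum and are rejected. With ``prior`` enabled the profile is weighted
    by a Gaussian bump centered on the median of the recently accepted
    intervals (lag selection only; the gate always sees the unweighted
    profile, which the prior would otherwise concentrate into passing).

    Emission is beat-synchronous: after an accepted interval the window
    advances by that interval (one estimate per heartbeat, so coverage
    can reach 100% of the reference intervals); after a rejected window
    it advances by ``step_s``.
    """
    if not channels:
        raise ValidationError("lie_intervals needs at least one channel")
    fs = channels[0].fs
    n = channels[0].n
    for ch in channels[1:]:
        if ch.fs != fs or ch.n != n:
            raise ValidationError("channels must be time-aligned")
    # sensor rails per channel: a window resting on a rail for more than
    # a few percent of its samples is clipped and cannot be trusted
    rails = [(ch.samples.min(), ch.samples.max()) for ch in channels]
    duration = n / fs
    half = win_s / 2

    out: List[IntervalEstimate] = []
    recent: deque = deque(maxlen=5)  # last accepted intervals; median centers the prior
    last_interval: Optional[float] = None
    last_t: Optional[float] = None
    n_inconsistent = 0
    c = half
    while c <= duration - half + 1e-9:
        admitted = []
        i0 = int(round((c - half) * fs))
        i1 = int(round((c + half) * fs))
        for ch, (lo, hi) in zip(channels, rails):
            w = ch.samples[i0:i1]
            clipped = np.mean((w <= lo) | (w >= hi)) if hi > lo else 1.0
            if clipped > 0.05:
                continue
            prof = lie_similarity(ch, c, win_s, lag_range_ms)
            if prof.unreliable or prof.score.max() < peak_min:
                continue
            rel_ch = lie_reliability(prof)
            if rel_ch >= threshold:
                admitted.append((rel_ch, prof))
        if not admitted:
            c += step_s
            continue
        # greedy fusion in descending peak order (peak height = share of
        # window variance explained at the best lag, the steadier quality
        # proxy than the concentration ratio): keep adding profiles while
        # the joint profile still passes the gate, so one confident
        # channel is never vetoed by a disagreeing weaker one
        admitted.sort(key=lambda t: (-t[1].score.max(), -t[0]))
        rel, summed = admitted[0][0], admitted[0][1].score.copy()
        lags_ms = admitted[0][1].lags_ms
        for rel_ch, prof in admitted[1:]:
            tentative = summed + prof.score
            rel_t = lie_reliability(SimilarityProfile(lags_ms, tentative, c))
            if rel_t >= threshold and tentative.max() >= peak_min:
                summed, rel = tentative, rel_t
        weighted = summed
        if prior and recent:
            center = float(np.median(recent))  # robust to one gross error
            weighted = summed * _prior_weight(lags_ms, center, c - last_t)
        interval = _pick_lag(lags_ms, weighted)
        # trend check: an interval far off the recent median is almost
        # always a harmonic or half-lag slip (the heart does not halve
        # its rate between beats); reject it rather than report it.
        # Repeated rejections clear the history so the tracker can
        # re-lock after a genuine rate change.
        if len(recent) >= 3:
            med = float(np.median(recent))
            if not 0.75 * med <= interval <= 1.35 * med:
                n_inconsistent += 1
                if n_inconsistent >= 5:
                    recent.clear()
                    n_inconsistent = 0
                c += step_s
                continue
        n_inconsistent = 0
        out.append(IntervalEstimate(float(c), interval, "LIE", reliability=rel))
        recent.append(interval)
        last_interval, last_t = interval, c
        c += interval / 1000.0  # pace the window: one estimate per beat
    return out
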