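"""Synthetic multimodal session generator.

Emulates the armchair setup: quasi-periodic cardiac waveforms per
modality (spiky QRS train for the ECG channels, a smooth single-lobe
pulse for PPG, damped multi-lobe oscillations for the BCG variants, a
slow sinusoid for the impedance channels), heart-rate variability with
respiratory sinus arrhythmia, respiratory amplitude modulation, and
maneuver-coupled artifacts (additive noise and baseline shifts
proportional to thorax marker displacement, clipped at sensor rails).

The generator is the controlled counterfactual of the measurement
protocol: marker displacements follow the instructed amplitudes exactly
with a smooth raised-cosine profile, and every rendered cardiac cycle
onset coincides with a reference beat annotation (shifted by the
modality's mechanical delay).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .types import (
    BeatAnnotations,
    MarkerTrajectory,
    ProtocolEpisode,
    Recording,
    SignalChannel,
    THORAX_MARKERS,
    ValidationError,
)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# models


@dataclass
class HRVModel:
    """Ground-truth beat interval model.

    RR[k] = mean_rr + sd_rr * eps_k + rsa_depth * sin(2*pi*resp_freq*t_k),
    with eps_k i.i.d. standard normal. ``rsa_depth`` is the respiratory
    sinus arrhythmia amplitude in ms; ``resp_freq`` the breathing rate in
    Hz.
    """

    mean_rr: float = 900.0   # ms
    sd_rr: float = 40.0      # ms
    rsa_depth: float = 30.0  # ms
    resp_freq: float = 0.25  # Hz

    def __post_init__(self):
        if not 333.0 <= self.mean_rr <= 2000.0:
            raise ValidationError("mean_rr must lie in [333, 2000] ms")
        if self.sd_rr < 0:
            raise ValidationError("sd_rr must be >= 0")


@dataclass
class ModalityModel:
    """Per-modality waveform and artifact-coupling model.

    ``base_template`` is the unit-phase waveform (one cardiac cycle on a
    dense phase grid). ``mech_delay`` shifts the waveform after the
    R-peak (0 for the electrical modalities). ``artifact_gain`` is the
    standard deviation of the motion-coupled disturbance per mm of
    instantaneous thorax displacement; ``artifact_axes`` weights the
    displacement axes in that coupling — sensor contact geometry makes
    the coupling directional (a backrest sensor loses contact on
    left-right shifts, the seat mat responds to vertical loading);
    ``rail`` gives the saturation limits.
    """

    modality: str
    base_template: np.ndarray
    mech_delay: float = 0.0          # s
    resp_mod_depth: float = 0.0      # fraction of amplitude
    noise_sd: float = 0.05           # a.u.
    artifact_gain: float = 0.0       # a.u. per mm
    artifact_axes: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    rail: Tuple[float, float] = (-5.0, 5.0)
    amplitude: float = 1.0           # a.u.

    def __post_init__(self):
        self.base_template = np.asarray(self.base_template, dtype=np.float64)
        if self.mech_delay < 0:
            raise ValidationError("mech_delay must be >= 0")
        if not 0 <= self.resp_mod_depth < 1:
            raise ValidationError("resp_mod_depth must lie in [0, 1)")
        if not self.rail[0] < self.rail[1]:
            raise ValidationError("rail_low must be < rail_high")


def _gauss(phi: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((phi - mu) / sigma) ** 2)


def default_template(modality: str, p: int = 512) -> np.ndarray:
    """Fixed analytic unit-phase waveform for a modality.

    Shapes are deliberately simple analytic stand-ins (Gaussian QRS
    complex, gamma-like PPG pulse, damped-sine BCG, single sinusoid for
    the impedance channels); the downstream machinery is shape-agnostic.
    """
    phi = np.arange(p) / p
    if modality in ("cECG", "ECG_REF"):
        w = (
            -0.15 * _gauss(phi, 0.012, 0.008)   # Q
            + 1.00 * _gauss(phi, 0.030, 0.010)  # R
            - 0.25 * _gauss(phi, 0.055, 0.010)  # S
            + 0.30 * _gauss(phi, 0.320, 0.055)  # T
        )
    elif modality == "PPG":
        w = (phi / 0.18) ** 2 * np.exp(2 * (1 - phi / 0.18))
        w = w / w.max()
    elif modality in ("BCG_OPT", "BCG_EMFI"):
        w = np.exp(-phi / 0.12) * np.sin(2 * np.pi * 6 * phi)
    elif modality in ("HF_IMP_1", "HF_IMP_2"):
        w = 0.6 * np.sin(2 * np.pi * phi)
    elif modality == "RESP_REF":
        w = np.zeros(p)  # respiration rendered separately, not beat-locked
    else:
        raise ValidationError(f"no default template for modality {modality!r}")
    return w


def default_models() -> Dict[str, ModalityModel]:
    """Default per-modality models for the standard synthetic session.

    Artifact gains are larger for cECG and the optical BCG, the two
    modalities most disturbed by motion in the armchair setup; the
    reference sensors are not motion-coupled.
    """
    make = lambda m, **kw: ModalityModel(m, default_template(m), **kw)
    return {
        # triboelectric coupling: any relative motion of clothing
        "cECG": make("cECG", noise_sd=0.08, artifact_gain=0.25),
        # backrest optical sensor: lateral shifts break skin contact
        "PPG": make("PPG", mech_delay=0.25, resp_mod_depth=0.25,
                    noise_sd=0.05, artifact_gain=0.12,
                    artifact_axes=(1.5, 0.4, 0.3)),
        "BCG_OPT": make("BCG_OPT", mech_delay=0.20, resp_mod_depth=0.30,
                        noise_sd=0.10, artifact_gain=0.25),
        # seat mat: responds to vertical (un)loading, nearly immune to
        # horizontal slides of the torso
        "BCG_EMFI": make("BCG_EMFI", mech_delay=0.20, resp_mod_depth=0.30,
                         noise_sd=0.05, artifact_gain=0.12,
                         artifact_axes=(0.15, 0.15, 1.5)),
        "HF_IMP_1": make("HF_IMP_1", mech_delay=0.15, resp_mod_depth=0.6,
                         noise_sd=0.05, artifact_gain=0.10,
                         artifact_axes=(0.6, 1.2, 0.6)),
        "HF_IMP_2": make("HF_IMP_2", mech_delay=0.15, resp_mod_depth=0.6,
                         noise_sd=0.05, artifact_gain=0.10,
                         artifact_axes=(1.2, 0.6, 0.6)),
        "ECG_REF": make("ECG_REF", noise_sd=0.02),
        "RESP_REF": make("RESP_REF", noise_sd=0.02),
    }


#: Modalities that receive motion-coupled artifacts (the unobtrusive
#: chair sensors; the adhesive reference sensors are left clean).
ARTIFACT_COUPLED = ("cECG", "PPG", "BCG_OPT", "BCG_EMFI", "HF_IMP_1", "HF_IMP_2")


# --------------------------------------------------------------------------
# beat times and channel rendering


def sample_beat_times(duration: float, hrv: HRVModel, seed) -> np.ndarray:
    """Sample strictly increasing beat times (s) over [0, duration)."""
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    rng = np.random.default_rng(seed)
    times = [0.0]
    while True:
        t = times[-1]
        rr_ms = (
            hrv.mean_rr
            + hrv.sd_rr * rng.standard_normal()
            + hrv.rsa_depth * np.sin(2 * np.pi * hrv.resp_freq * t)
        )
        if rr_ms <= 0:
            raise ValidationError("HRV parameters produced a non-positive RR")
        t_next = t + rr_ms / 1000.0
        if t_next >= duration:
            break
        times.append(t_next)
    return np.asarray(times)


def render_channel(
    beat_times: Sequence[float],
    model: ModalityModel,
    fs: float,
    duration: float,
    seed,
    resp_freq: float = 0.25,
) -> SignalChannel:
    """Render one channel from beat times and a modality model.

    Each cardiac cycle is the base template stretched to the cycle's RR
    interval, delayed by ``mech_delay``, amplitude-modulated by the
    respiratory factor 1 + depth*sin(2*pi*f_resp*t), plus white Gaussian
    noise. RESP_REF renders the respiratory sinusoid itself instead.
    """
    beat_times = np.asarray(beat_times, dtype=np.float64)
    if beat_times.size and (beat_times.min() < 0 or beat_times.max() > duration):
        raise ValidationError("beat_times must lie within [0, duration]")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    out = rng.normal(0.0, model.noise_sd, n) if model.noise_sd > 0 else np.zeros(n)

    if model.modality == "RESP_REF":
        out += model.amplitude * np.sin(2 * np.pi * resp_freq * t)
        return SignalChannel(model.modality, out, fs)

    tmpl = model.base_template
    p = tmpl.size
    if p and np.any(tmpl):
        grid = np.arange(p + 1) / p
        tmpl_ext = np.concatenate([tmpl, tmpl[:1]])  # wrap for phase -> 1
        mod = 1.0 + model.resp_mod_depth * np.sin(2 * np.pi * resp_freq * t)
        d = model.mech_delay
        for b0, b1 in zip(beat_times[:-1], beat_times[1:]):
            i0 = int(np.ceil((b0 + d) * fs))
            i1 = min(int(np.ceil((b1 + d) * fs)), n)
            if i1 <= i0:
                continue
            phi = (t[i0:i1] - d - b0) / (b1 - b0)
            out[i0:i1] += (
                model.amplitude * mod[i0:i1] * np.interp(phi, grid, tmpl_ext)
            )
    return SignalChannel(model.modality, out, fs)


# --------------------------------------------------------------------------
# motion protocol


#: Maneuver -> (marker ids displaced, per-axis direction/fraction of the
#: instructed amplitude). Marker 1 = head, 2/3/4/6 = thorax, 5 = right
#: arm, 7 = left arm. Torsions carry a small vertical shoulder component.
MANEUVER_MAP = {
    "TSL": (tuple(range(1, 8)), {"x": -1.0}),
    "TSR": (tuple(range(1, 8)), {"x": +1.0}),
    "S/S": (tuple(range(1, 8)), {"z": +1.0}),
    "TT": ((2, 3, 4, 5, 6, 7), {"x": +0.5, "y": +1.0, "z": +0.15}),
    "TTc": ((2, 3, 4, 5, 6, 7), {"x": -0.5, "y": -1.0, "z": +0.15}),
    "HT": ((1,), {"x": +0.8, "y": +0.8}),
    "LA": ((7,), {"x": +0.3, "z": +1.0}),
    "RA": ((5,), {"x": +0.3, "z": +1.0}),
}

#: Order of the maneuver block; performed once per amplitude class.
MANEUVER_ORDER = ("TSL", "TSR", "S/S", "TT", "TTc", "HT", "LA", "RA")

#: Stand up/sit down has no instructed amplitude; fixed vertical
#: excursion in mm used for both protocol halves.
SS_AMPLITUDE_MM = 400.0


def synth_protocol(
    slot_s: float = 30.0,
    amplitudes: Tuple[float, float] = (50.0, 100.0),
    fs: float = 100.0,
    rest_s: float = 60.0,
    maneuver_s: float = 8.0,
) -> Tuple[List[ProtocolEpisode], List[MarkerTrajectory]]:
    """Build the motion-protocol episode table and marker trajectories.

    Structure: ``rest_s`` REST, the 8 maneuvers at low amplitude in 30-s
    slots, the same 8 at high amplitude, ``rest_s`` REST. Within each
    slot the displacement follows a raised-cosine out-and-back profile
    over the first ``maneuver_s`` seconds; the remainder of the slot is
    motionless (the post-motion rest used for template extraction).
    """
    low_mm, high_mm = amplitudes
    episodes: List[ProtocolEpisode] = []
    t = 0.0
    episodes.append(ProtocolEpisode("REST", "none", t, t + rest_s))
    t += rest_s
    for amp_class in ("low", "high"):
        for maneuver in MANEUVER_ORDER:
            episodes.append(ProtocolEpisode(maneuver, amp_class, t, t + slot_s))
            t += slot_s
    episodes.append(ProtocolEpisode("REST", "none", t, t + rest_s))
    duration = t + rest_s

    n = int(round(duration * fs))
    coords = {mid: {ax: np.zeros(n) for ax in "xyz"} for mid in range(1, 8)}
    for ep in episodes:
        if ep.maneuver == "REST":
            continue
        marker_ids, axes = MANEUVER_MAP[ep.maneuver]
        if ep.maneuver == "S/S":
            amp = SS_AMPLITUDE_MM
        else:
            amp = low_mm if ep.amplitude_class == "low" else high_mm
        i0 = int(round(ep.t_start * fs))
        i1 = min(int(round((ep.t_start + maneuver_s) * fs)), n)
        tt = (np.arange(i1 - i0) / fs) / maneuver_s
        profile = 0.5 * (1.0 - np.cos(2 * np.pi * tt))  # 0 -> 1 -> 0
        for mid in marker_ids:
            for ax, frac in axes.items():
                coords[mid][ax][i0:i1] += amp * frac * profile

    markers = [
        MarkerTrajectory(mid, coords[mid]["x"], coords[mid]["y"], coords[mid]["z"], fs)
        for mid in range(1, 8)
    ]
    return episodes, markers


def thorax_displacement_magnitude(
    markers: Sequence[MarkerTrajectory],
    axis_weights: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Instantaneous thorax displacement magnitude in mm.

    Per thorax marker (ids 2, 3, 4, 6): subtract the per-axis median
    (the rest baseline), weight the axes and take the Euclidean norm;
    then average over the thorax markers. ``axis_weights`` encode a
    sensor's directional coupling; (1, 1, 1) is the plain magnitude.
    """
    wx, wy, wz = axis_weights
    mags = []
    for m in markers:
        if m.marker_id not in THORAX_MARKERS:
            continue
        ac = np.stack(
            [
                wx * (m.x - np.median(m.x)),
                wy * (m.y - np.median(m.y)),
                wz * (m.z - np.median(m.z)),
            ]
        )
        mags.append(np.linalg.norm(ac, axis=0))
    if not mags:
        raise ValidationError("no thorax markers (ids 2, 3, 4, 6) present")
    return np.mean(mags, axis=0)


def inject_artifacts(
    channel: SignalChannel,
    markers: Sequence[MarkerTrajectory],
    episodes: Sequence[ProtocolEpisode],
    model: ModalityModel,
    seed,
    baseline_coef: float = 0.3,
) -> SignalChannel:
    """Add motion-coupled disturbances to a channel and clip to rails.

    The disturbance is zero-mean Gaussian with instantaneous standard
    deviation ``artifact_gain * d(t)`` plus a deterministic baseline
    shift ``baseline_coef * artifact_gain * d(t)``, where d(t) is the
    axis-weighted thorax displacement magnitude in mm (the model's
    ``artifact_axes`` encode the sensor's directional sensitivity).
    Stand up/sit down episodes force rail saturation for the episode
    duration (the subject leaves the chair entirely).
    """
    d = thorax_displacement_magnitude(markers, model.artifact_axes)
    if d.size != channel.n:
        raise ValidationError("markers not time-aligned with channel")
    out = channel.samples.copy()
    if model.artifact_gain > 0 and np.any(d > 0):
        rng = np.random.default_rng(seed)
        sd = model.artifact_gain * d
        out += baseline_coef * sd + rng.standard_normal(channel.n) * sd
    lo, hi = model.rail
    for ep in episodes:
        if ep.maneuver == "S/S":
            i0 = int(round(ep.t_start * channel.fs))
            i1 = min(int(round(ep.t_end * channel.fs)), channel.n)
            out[i0:i1] = hi
    np.clip(out, lo, hi, out=out)
    return SignalChannel(channel.modality, out, channel.fs)


# --------------------------------------------------------------------------
# full session


@dataclass
class SessionConfig:
    """Configuration of one synthetic session."""

    duration: float = 600.0          # s; forced to the protocol length if protocol
    fs: float = 100.0                # Hz
    protocol: bool = True            # motion protocol vs quiet "video" session
    hrv: HRVModel = field(default_factory=HRVModel)
    models: Dict[str, ModalityModel] = field(default_factory=default_models)
    amplitudes: Tuple[float, float] = (50.0, 100.0)  # low/high shift, mm
    slot_s: float = 30.0
    rest_s: float = 60.0
    maneuver_s: float = 8.0


def generate_session(config: SessionConfig, seed: int) -> Recording:
    """Generate a full synthetic Recording, deterministic per seed."""
    ss = np.random.SeedSequence(seed)
    names = sorted(config.models)
    streams = ss.spawn(1 + 2 * len(names))
    beat_stream = streams[0]
    render_streams = dict(zip(names, streams[1 : 1 + len(names)]))
    artifact_streams = dict(zip(names, streams[1 + len(names) :]))

    if config.protocol:
        episodes, markers = synth_protocol(
            slot_s=config.slot_s,
            amplitudes=config.amplitudes,
            fs=config.fs,
            rest_s=config.rest_s,
            maneuver_s=config.maneuver_s,
        )
        duration = episodes[-1].t_end
    else:
        duration = config.duration
        episodes = [ProtocolEpisode("REST", "none", 0.0, duration)]
        n = int(round(duration * config.fs))
        markers = [
            MarkerTrajectory(mid, np.zeros(n), np.zeros(n), np.zeros(n), config.fs)
            for mid in range(1, 8)
        ]

    beat_times = sample_beat_times(duration, config.hrv, beat_stream)
    channels = {}
    for name in names:
        model = config.models[name]
        ch = render_channel(
            beat_times,
            model,
            config.fs,
            duration,
            render_streams[name],
            resp_freq=config.hrv.resp_freq,
        )
        if config.protocol and name in ARTIFACT_COUPLED:
            ch = inject_artifacts(
                ch, markers, episodes, model, artifact_streams[name]
            )
        channels[name] = ch

    n = next(iter(channels.values())).n
    beat_samples = np.round(beat_times * config.fs).astype(np.int64)
    beat_samples = beat_samples[beat_samples < n]
    return Recording(
        channels=channels,
        ref_beats=BeatAnnotations(beat_samples),
        markers=markers,
        episodes=episodes,
        meta={
            "seed": int(seed),
            "protocol": bool(config.protocol),
            "duration_s": float(duration),
            "mean_rr_ms": float(config.hrv.mean_rr),
            "generator": "cardiofuse.synth",
        },
    )


def quiet_config(duration: float = 1800.0) -> SessionConfig:
    """Configuration of the quiet (movie-watching) scenario."""
    return SessionConfig(duration=duration, protocol=False)
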