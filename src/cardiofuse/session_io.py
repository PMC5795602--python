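"""On-disk session format: one directory per recording.

Layout::

    session/
      header.json    fs, channel names, format, free-form meta
      signals.h5     one float64 dataset per channel        (hdf5 format)
      markers.h5     x/y/z datasets per marker              (hdf5 format)
      signals.csv    columnar plain-text fallback           (csv format)
      markers.csv    columns <id>_x, <id>_y, <id>_z         (csv format)
      beats.txt      one 0-based sample index per line
      episodes.csv   maneuver, amplitude_class, t_start, t_end

HDF5 is the default numeric encoding (bit-stable float64 round trips);
the CSV fallback writes 17 significant digits, which also round-trips
float64 exactly, at the cost of file size.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Dict

import h5py
import numpy as np
import pandas as pd

from .types import (
    BeatAnnotations,
    MarkerTrajectory,
    ProtocolEpisode,
    Recording,
    SignalChannel,
    ValidationError,
)

log = logging.getLogger(__name__)

_FMT = "%.17g"  # round-trip exact for IEEE float64


class SessionFormatError(ValueError):
    """Raised when a session directory cannot be parsed."""


def write_session(rec: Recording, path: str, fmt: str = "hdf5") -> None:
    """Write a validated :class:`Recording` to ``path`` (a directory).

    ``fmt`` selects the numeric encoding: ``"hdf5"`` (default) or
    ``"csv"``. The round trip ``read_session(write_session(rec))`` is the
    identity in either encoding.
    """
    if fmt not in ("hdf5", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    rec.validate()
    os.makedirs(path, exist_ok=True)

    header = {
        "format": fmt,
        "fs": rec.fs,
        "n_samples": rec.n,
        "channels": sorted(rec.channels),
        "markers": sorted(m.marker_id for m in rec.markers),
        "has_ref_beats": rec.ref_beats is not None,
        "meta": rec.meta,
    }
    with open(os.path.join(path, "header.json"), "w") as fh:
        json.dump(header, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if fmt == "hdf5":
        with h5py.File(os.path.join(path, "signals.h5"), "w") as f:
            for name in sorted(rec.channels):
                f.create_dataset(name, data=rec.channels[name].samples)
        if rec.markers:
            with h5py.File(os.path.join(path, "markers.h5"), "w") as f:
                for m in sorted(rec.markers, key=lambda m: m.marker_id):
                    g = f.create_group(str(m.marker_id))
                    g.create_dataset("x", data=m.x)
                    g.create_dataset("y", data=m.y)
                    g.create_dataset("z", data=m.z)
    else:
        df = pd.DataFrame(
            {name: rec.channels[name].samples for name in sorted(rec.channels)}
        )
        df.to_csv(os.path.join(path, "signals.csv"), index=False, float_format=_FMT)
        if rec.markers:
            cols = {}
            for m in sorted(rec.markers, key=lambda m: m.marker_id):
                cols[f"{m.marker_id}_x"] = m.x
                cols[f"{m.marker_id}_y"] = m.y
                cols[f"{m.marker_id}_z"] = m.z
            pd.DataFrame(cols).to_csv(
                os.path.join(path, "markers.csv"), index=False, float_format=_FMT
            )

    if rec.ref_beats is not None:
        np.savetxt(
            os.path.join(path, "beats.txt"),
            rec.ref_beats.beat_samples,
            fmt="%d",
        )

    ep = pd.DataFrame(
        [
            {
                "maneuver": e.maneuver,
                "amplitude_class": e.amplitude_class,
                "t_start": e.t_start,
                "t_end": e.t_end,
            }
            for e in rec.episodes
        ],
        columns=["maneuver", "amplitude_class", "t_start", "t_end"],
    )
    ep.to_csv(os.path.join(path, "episodes.csv"), index=False, float_format=_FMT)


def read_session(path: str) -> Recording:
    """Read a session directory back into a validated :class:`Recording`."""
    header_path = os.path.join(path, "header.json")
    if not os.path.exists(header_path):
        raise SessionFormatError(f"missing header.json in {path}")
    with open(header_path) as fh:
        header = json.load(fh)
    fmt = header.get("format", "hdf5")
    fs = float(header["fs"])
    n = int(header["n_samples"])

    channels: Dict[str, SignalChannel] = {}
    markers = []
    if fmt == "hdf5":
        with h5py.File(os.path.join(path, "signals.h5"), "r") as f:
            for name in header["channels"]:
                channels[name] = SignalChannel(name, f[name][:], fs)
        mpath = os.path.join(path, "markers.h5")
        if header["markers"]:
            with h5py.File(mpath, "r") as f:
                for mid in header["markers"]:
                    g = f[str(mid)]
                    markers.append(
                        MarkerTrajectory(mid, g["x"][:], g["y"][:], g["z"][:], fs)
                    )
    elif fmt == "csv":
        df = pd.read_csv(os.path.join(path, "signals.csv"), float_precision="round_trip")
        for name in header["channels"]:
            channels[name] = SignalChannel(name, df[name].to_numpy(), fs)
        if header["markers"]:
            md = pd.read_csv(os.path.join(path, "markers.csv"), float_precision="round_trip")
            for mid in header["markers"]:
                markers.append(
                    MarkerTrajectory(
                        mid,
                        md[f"{mid}_x"].to_numpy(),
                        md[f"{mid}_y"].to_numpy(),
                        md[f"{mid}_z"].to_numpy(),
                        fs,
                    )
                )
    else:
        raise SessionFormatError(f"unknown format {fmt!r} in header")

    for name, ch in channels.items():
        if ch.n != n:
            raise SessionFormatError(
                f"channel {name}: header claims {n} samples, file has {ch.n}"
            )
    for m in markers:
        if m.n != n:
            raise SessionFormatError(
                f"marker {m.marker_id}: header claims {n} samples, file has {m.n}"
            )

    ref_beats = None
    if header.get("has_ref_beats"):
        beats = np.loadtxt(os.path.join(path, "beats.txt"), dtype=np.int64, ndmin=1)
        ref_beats = BeatAnnotations(beats)

    episodes = []
    ep_path = os.path.join(path, "episodes.csv")
    if os.path.exists(ep_path):
        ep = pd.read_csv(ep_path)
        for row in ep.itertuples(index=False):
            episodes.append(
                ProtocolEpisode(
                    row.maneuver, row.amplitude_class, row.t_start, row.t_end
                )
            )

    try:
        return Recording(
            channels=channels,
            ref_beats=ref_beats,
            markers=markers,
            episodes=episodes,
            meta=header.get("meta", {}),
        )
    except ValidationError as e:
        raise SessionFormatError(f"invalid session at {path}: {e}") from e


def import_csv_channels(path: str, fs: float, column_map: Dict[str, str]) -> Recording:
    """Build a Recording from a plain CSV of equal-length numeric columns.

    ``column_map`` maps CSV column names to modalities; unmapped columns
    are skipped with a warning. Reference beats and markers, if any, must
    be imported separately.
    """
    try:
        df = pd.read_csv(path)
        num = df.apply(pd.to_numeric)
    except (ValueError, pd.errors.ParserError) as e:
        raise SessionFormatError(f"cannot parse {path}: {e}") from e
    if num.isna().any().any():
        bad = int(np.where(num.isna().any(axis=1))[0][0])
        raise SessionFormatError(f"non-numeric cell at data row {bad} of {path}")
    channels = {}
    for col in df.columns:
        if col not in column_map:
            log.warning("column %r not in column_map; skipped", col)
            continue
        modality = column_map[col]
        channels[modality] = SignalChannel(modality, num[col].to_numpy(), fs)
    return Recording(channels=channels, meta={"imported_from": os.path.basename(path)})
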