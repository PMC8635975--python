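"""File formats: the sweep CSV dialect and the YAML parameter config.

Sweep files are plain CSV with a commented header block per sweep::

    # format_version: 1
    # sweep: 0
    # construct_label: R1C-qBBr
    # sample_rate_khz: 20.0
    # n_averaged: 4
    # holding_mV: -120.0
    # sample_interval_ms: 0.05
    # segments_json: [[40.0, -120.0], [50.0, 80.0], [20.0, -120.0]]
    time_ms,voltage_mV,fluorescence,gating_current
    0,-120,998.2,-0.001
    ...

Units are fixed (ms, mV, µA, arbitrary fluorescence units); the decimal
separator is always a point and files are UTF-8. The gating_current
column is optional; absent means "not recorded", never zero-filled.
Values round-trip at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .analysis import SweepRecording
from .quenching import QuencherGeometry
from .state_model import DEFAULT_KT_MV, KineticScheme, VoltageProtocol
from .synth import NoiseModel

__all__ = [
    "write_sweeps",
    "read_sweeps",
    "read_sweeps_with_meta",
    "write_sweeps_hdf5",
    "read_sweeps_hdf5",
    "read_config",
    "write_config",
]

FORMAT_VERSION = "1"
_MANDATORY = ("sample_rate_khz", "sample_interval_ms", "holding_mV", "segments_json")


def _fmt(x: float) -> str:
    return repr(float(x))


def write_sweeps(
    recordings: Union[SweepRecording, Sequence[SweepRecording]],
    path,
    extra: Optional[Sequence[Dict[str, str]]] = None,
) -> None:
    """Write one or more sweeps to a single CSV file (see module docstring).

    ``extra`` optionally supplies additional per-sweep header key/value
    pairs (e.g. seed provenance, a noise_free flag, prepulse metadata).
    """
    if isinstance(recordings, SweepRecording):
        recordings = [recordings]
    if extra is not None and len(extra) != len(recordings):
        raise ValueError("extra metadata length must match recordings")
    lines: List[str] = [f"# format_version: {FORMAT_VERSION}"]
    for idx, rec in enumerate(recordings):
        proto = rec.protocol
        lines.append(f"# sweep: {idx}")
        lines.append(f"# construct_label: {rec.construct_label}")
        lines.append(f"# sample_rate_khz: {_fmt(rec.sample_rate)}")
        lines.append(f"# n_averaged: {rec.n_averaged}")
        lines.append(f"# holding_mV: {_fmt(proto.holding_voltage)}")
        lines.append(f"# sample_interval_ms: {_fmt(proto.sample_interval)}")
        lines.append(
            "# segments_json: "
            + json.dumps([[d, v] for d, v in proto.segments])
        )
        if extra is not None:
            for k, v in extra[idx].items():
                lines.append(f"# {k}: {v}")
        cols = ["time_ms", "voltage_mV", "fluorescence"]
        has_gating = rec.gating_current is not None
        if has_gating:
            cols.append("gating_current")
        lines.append(",".join(cols))
        t = rec.times
        v = proto.voltage_series(t)
        for k in range(t.size):
            row = [_fmt(t[k]), _fmt(v[k]), _fmt(rec.fluorescence[k])]
            if has_gating:
                row.append(_fmt(rec.gating_current[k]))
            lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_sweeps_with_meta(path) -> Tuple[List[SweepRecording], List[Dict[str, str]]]:
    """Parse a sweep CSV file; returns (recordings, per-sweep header dicts)."""
    text = Path(path).read_text(encoding="utf-8")
    blocks: List[Tuple[Dict[str, str], List[str], List[Tuple[int, str]]]] = []
    header: Dict[str, str] = {}
    columns: List[str] = []
    rows: List[Tuple[int, str]] = []
    file_meta: Dict[str, str] = {}
    in_block = False

    def close_block():
        nonlocal header, columns, rows, in_block
        if in_block:
            blocks.append((header, columns, rows))
        header, columns, rows, in_block = {}, [], [], False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" not in body:
                raise ValueError(f"malformed header line {lineno}: {raw!r}")
            key, _, val = body.partition(":")
            key, val = key.strip(), val.strip()
            if key == "sweep":
                close_block()
                in_block = True
                header = {}
            elif key == "format_version":
                file_meta[key] = val
            else:
                if not in_block:
                    raise ValueError(
                        f"header key {key!r} before any '# sweep:' line ({lineno})"
                    )
                header[key] = val
        else:
            if not in_block:
                raise ValueError(f"data row before any sweep header (line {lineno})")
            if not columns:
                columns = [c.strip() for c in line.split(",")]
            else:
                rows.append((lineno, line))
    close_block()

    if "format_version" not in file_meta:
        raise ValueError("missing header key: format_version")
    if file_meta["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"unrecognized format_version {file_meta['format_version']!r}"
        )
    recordings, metas = [], []
    for header, columns, rows in blocks:
        for key in _MANDATORY:
            if key not in header:
                raise ValueError(f"missing header key: {key.removesuffix('_json')}")
        segments = tuple(
            (float(d), float(v)) for d, v in json.loads(header["segments_json"])
        )
        proto = VoltageProtocol(
            segments=segments,
            holding_voltage=float(header["holding_mV"]),
            sample_interval=float(header["sample_interval_ms"]),
        )
        ncols = len(columns)
        has_gating = "gating_current" in columns
        fl, gating = [], []
        for lineno, line in rows:
            parts = line.split(",")
            if len(parts) != ncols:
                raise ValueError(
                    f"ragged row at line {lineno}: expected {ncols} fields, "
                    f"got {len(parts)}"
                )
            vals = dict(zip(columns, parts))
            fl.append(float(vals["fluorescence"]))
            if has_gating:
                gating.append(float(vals["gating_current"]))
        rec = SweepRecording(
            protocol=proto,
            sample_rate=float(header["sample_rate_khz"]),
            fluorescence=np.array(fl),
            gating_current=np.array(gating) if has_gating else None,
            n_averaged=int(header.get("n_averaged", "1")),
            construct_label=header.get("construct_label", ""),
        )
        recordings.append(rec)
        metas.append(dict(header))
    return recordings, metas


def read_sweeps(path) -> List[SweepRecording]:
    return read_sweeps_with_meta(path)[0]


def write_sweeps_hdf5(recordings: Sequence[SweepRecording], path) -> None:
    """HDF5 mirror of the CSV schema, for large ensembles."""
    import h5py

    if isinstance(recordings, SweepRecording):
        recordings = [recordings]
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        for idx, rec in enumerate(recordings):
            grp = h5.create_group(f"sweep{idx}")
            grp.attrs["construct_label"] = rec.construct_label
            grp.attrs["sample_rate_khz"] = rec.sample_rate
            grp.attrs["n_averaged"] = rec.n_averaged
            grp.attrs["holding_mV"] = rec.protocol.holding_voltage
            grp.attrs["sample_interval_ms"] = rec.protocol.sample_interval
            grp.create_dataset("segments", data=np.array(rec.protocol.segments))
            grp.create_dataset("fluorescence", data=rec.fluorescence)
            if rec.gating_current is not None:
                grp.create_dataset("gating_current", data=rec.gating_current)


def read_sweeps_hdf5(path) -> List[SweepRecording]:
    import h5py

    out = []
    with h5py.File(path, "r") as h5:
        for name in sorted(h5, key=lambda s: int(s.removeprefix("sweep"))):
            grp = h5[name]
            segments = tuple((float(d), float(v)) for d, v in grp["segments"][()])
            proto = VoltageProtocol(
                segments=segments,
                holding_voltage=float(grp.attrs["holding_mV"]),
                sample_interval=float(grp.attrs["sample_interval_ms"]),
            )
            gating = (
                grp["gating_current"][()] if "gating_current" in grp else None
            )
            out.append(
                SweepRecording(
                    protocol=proto,
                    sample_rate=float(grp.attrs["sample_rate_khz"]),
                    fluorescence=grp["fluorescence"][()],
                    gating_current=gating,
                    n_averaged=int(grp.attrs["n_averaged"]),
                    construct_label=str(grp.attrs["construct_label"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# parameter config (YAML)

_TOP_KEYS = {"format_version", "units", "scheme", "geometry", "protocol", "noise"}


def read_config(path):
    """Read a YAML parameter config.

    Returns ``(KineticScheme, QuencherGeometry, VoltageProtocol, NoiseModel)``;
    unknown keys are rejected and invariant violations are reported with
    field names. Units are fixed: ms, mV, Å, e0.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section in ("scheme", "geometry", "protocol"):
        if section not in raw:
            raise ValueError(f"missing config section: {section}")

    s = dict(raw["scheme"])
    allowed = {"positions", "charges", "kT_mV", "transitions"}
    unknown = set(s) - allowed
    if unknown:
        raise ValueError(f"unknown scheme keys: {sorted(unknown)}")
    trans = {}
    for t in s.get("transitions", []):
        t = dict(t)
        unknown = set(t) - {"from", "to", "k0", "zdelta"}
        if unknown:
            raise ValueError(f"unknown transition keys: {sorted(unknown)}")
        trans[(int(t["from"]), int(t["to"]))] = (float(t["k0"]), float(t["zdelta"]))
    try:
        scheme = KineticScheme(
            positions=tuple(s["positions"]),
            charges=tuple(s["charges"]),
            transitions=trans,
            kT=float(s.get("kT_mV", DEFAULT_KT_MV)),
        )
    except (ValueError, KeyError) as err:
        raise ValueError(f"invalid scheme: {err}") from err

    g = dict(raw["geometry"])
    unknown = set(g) - {"x_w", "lambda_half", "F0"}
    if unknown:
        raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
    try:
        geometry = QuencherGeometry(
            x_w=float(g["x_w"]),
            lambda_half=float(g.get("lambda_half", 6.0)),
            F0=float(g.get("F0", 1.0)),
        )
    except ValueError as err:
        raise ValueError(f"invalid geometry: field lambda_half/F0/x_w: {err}") from err

    p = dict(raw["protocol"])
    unknown = set(p) - {"holding_mV", "sample_interval_ms", "segments"}
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    try:
        protocol = VoltageProtocol(
            segments=tuple((float(d), float(v)) for d, v in p["segments"]),
            holding_voltage=float(p["holding_mV"]),
            sample_interval=float(p["sample_interval_ms"]),
        )
    except (ValueError, KeyError) as err:
        raise ValueError(f"invalid protocol: {err}") from err

    n = dict(raw.get("noise", {}))
    unknown = set(n) - {"gaussian_sd", "drift_slope", "bleach_rate", "seed"}
    if unknown:
        raise ValueError(f"unknown noise keys: {sorted(unknown)}")
    try:
        noise = NoiseModel(
            gaussian_sd=float(n.get("gaussian_sd", 0.0)),
            drift_slope=float(n.get("drift_slope", 0.0)),
            bleach_rate=float(n.get("bleach_rate", 0.0)),
            seed=int(n.get("seed", 0)),
        )
    except ValueError as err:
        raise ValueError(f"invalid noise model: {err}") from err
    return scheme, geometry, protocol, noise


def write_config(
    path,
    scheme: KineticScheme,
    geometry: QuencherGeometry,
    protocol: VoltageProtocol,
    noise: Optional[NoiseModel] = None,
) -> None:
    """Inverse of :func:`read_config` (round-trips exactly)."""
    doc = {
        "format_version": 1,
        "units": {"time": "ms", "voltage": "mV", "distance": "A", "charge": "e0"},
        "scheme": {
            "positions": list(scheme.positions),
            "charges": list(scheme.charges),
            "kT_mV": scheme.kT,
            "transitions": [
                {"from": i, "to": j, "k0": k0, "zdelta": zd}
                for (i, j), (k0, zd) in sorted(scheme.transitions.items())
            ],
        },
        "geometry": {
            "x_w": geometry.x_w,
            "lambda_half": geometry.lambda_half,
            "F0": geometry.F0,
        },
        "protocol": {
            "holding_mV": protocol.holding_voltage,
            "sample_interval_ms": protocol.sample_interval,
            "segments": [[d, v] for d, v in protocol.segments],
        },
    }
    if noise is not None:
        doc["noise"] = {
            "gaussian_sd": noise.gaussian_sd,
            "drift_slope": noise.drift_slope,
            "bleach_rate": noise.bleach_rate,
            "seed": noise.seed,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
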