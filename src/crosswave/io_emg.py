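"""Reading and writing of recordings, train tables and AUC diagrams.

Two recording formats are supported:

* **EDF** (European Data Format), the de-facto clinical biosignal container.
  A minimal codec for the fixed-width ASCII header + 16-bit integer record
  layout is implemented here; only continuous two-channel recordings with a
  single common sampling rate are needed.  EDF stores samples as 16-bit
  integers between a physical minimum and maximum, so amplitudes round-trip
  at the quantization resolution, not at float precision.
* **Delimited text** (TSV by default): comment-prefixed header lines carrying
  ``fs`` and channel names, followed by one numeric column per channel.

Train tables and diagrams are plain TSV; diagrams carry a JSON sidecar with
their axis grids and metadata.  All amplitudes are microvolts as recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "TRAIN_COLUMNS",
    "read_recording",
    "write_recording",
    "read_train_table",
    "write_train_table",
    "read_tremor_pair",
    "write_tremor_pair",
    "read_diagram",
    "write_diagram",
]

#: Fixed column order of a train table (one row per detected cross-wave train).
TRAIN_COLUMNS = [
    "subject_id",
    "time_s",
    "central_frequency_Hz",
    "psd",
    "duration_s",
    "duration_periods",
    "bandwidth_Hz",
    "phase_rad",
]

_GROUPS = ("PD", "ET", "other")
_SIDES = ("left", "right")


@dataclass
class Recording:
    """A raw two-channel antagonist-muscle surface EMG recording.

    Channels are the wrist flexor (musculus flexor carpi radialis) and
    extensor (musculus extensor carpi radialis longus) of one arm, in μV.
    """

    flexor: np.ndarray
    extensor: np.ndarray
    fs: float
    subject_id: str = "anon"
    group: str = "other"
    side: str = "left"
    age: float | None = None

    def __post_init__(self) -> None:
        self.flexor = np.asarray(self.flexor, dtype=float)
        self.extensor = np.asarray(self.extensor, dtype=float)
        if self.flexor.ndim != 1 or self.extensor.ndim != 1:
            raise ValueError("channels must be one-dimensional sample series")
        if len(self.flexor) != len(self.extensor):
            raise ValueError(
                f"channel length mismatch: {len(self.flexor)} vs {len(self.extensor)}"
            )
        if len(self.flexor) < 2:
            raise ValueError("recording must contain at least 2 samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")

    @property
    def duration_s(self) -> float:
        return len(self.flexor) / self.fs

    def __len__(self) -> int:
        return len(self.flexor)


# ---------------------------------------------------------------------------
# delimited text


def _write_delimited_header(fh, fs: float, channels: Sequence[str], meta: dict) -> None:
    fh.write(f"# fs={fs!r}\n")
    fh.write(f"# channels={','.join(channels)}\n")
    for key, val in meta.items():
        if val is not None:
            fh.write(f"# {key}={val}\n")


def _parse_delimited(path: Path, sep: str) -> tuple[dict, pd.DataFrame]:
    header: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                header[key.strip()] = val.strip()
    try:
        data = pd.read_csv(path, sep=sep, skiprows=n_header, header=None, comment=None,
                           float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    return header, data


def _read_recording_delimited(path: Path, sep: str, channel_map: dict | None) -> Recording:
    header, data = _parse_delimited(path, sep)
    if "fs" not in header:
        raise ValueError(f"{path}: delimited header must carry fs")
    fs = float(header["fs"])
    if fs <= 0:
        raise ValueError(f"{path}: fs must be positive, got {fs}")
    channels = [c.strip() for c in header.get("channels", "flexor,extensor").split(",")]
    if data.shape[1] != len(channels):
        raise ValueError(
            f"{path}: {data.shape[1]} data columns but {len(channels)} channel names"
        )
    for j in range(data.shape[1]):
        col = pd.to_numeric(data.iloc[:, j], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy())[0]
        if bad.size:
            raise ValueError(f"{path}: non-numeric value in data row {bad[0] + 1}")
        data.iloc[:, j] = col
    roles = _resolve_channel_roles(channels, channel_map)
    age = header.get("age")
    return Recording(
        flexor=data.iloc[:, roles["flexor"]].to_numpy(float),
        extensor=data.iloc[:, roles["extensor"]].to_numpy(float),
        fs=fs,
        subject_id=header.get("subject_id", "anon"),
        group=header.get("group", "other"),
        side=header.get("side", "left"),
        age=float(age) if age not in (None, "", "None") else None,
    )


def _resolve_channel_roles(labels: Sequence[str], channel_map: dict | None) -> dict:
    """Map channel labels to flexor/extensor column indices.

    Labels vary by site, so substring matching on 'flex'/'ext' is used with an
    explicit ``channel_map`` override of the form {'flexor': label_or_index}.
    """
    roles: dict[str, int] = {}
    if channel_map:
        for role, ident in channel_map.items():
            if isinstance(ident, int):
                roles[role] = ident
            else:
                matches = [i for i, lab in enumerate(labels) if ident.lower() in lab.lower()]
                if not matches:
                    raise ValueError(f"channel {ident!r} not found in {list(labels)}")
                roles[role] = matches[0]
    for role, tag in (("flexor", "flex"), ("extensor", "ext")):
        if role not in roles:
            matches = [i for i, lab in enumerate(labels) if tag in lab.lower()]
            if not matches:
                raise ValueError(
                    f"cannot identify {role} channel among {list(labels)}; "
                    "pass channel_map={'flexor': ..., 'extensor': ...}"
                )
            roles[role] = matches[0]
    if roles["flexor"] == roles["extensor"]:
        raise ValueError("flexor and extensor map to the same channel")
    return roles


# ---------------------------------------------------------------------------
# minimal EDF codec

_EDF_DIGITAL_MIN = -32768
_EDF_DIGITAL_MAX = 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a single-record EDF file (both channels, μV)."""
    path = Path(path)
    n = len(rec)
    # one data record holding the whole signal keeps the codec trivial
    record_duration = n / rec.fs
    chans = [("flexor", rec.flexor), ("extensor", rec.extensor)]
    phys_ranges = []
    for _, x in chans:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        # the header stores the range as 8-char ASCII; quantize against the
        # stored (rounded) values so decode error stays within one LSB
        lo = float(f"{lo:.6g}"[:8])
        hi = float(f"{hi:.6g}"[:8])
        if hi <= lo:
            hi = lo + 1.0
        phys_ranges.append((lo, hi))

    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "side": rec.side,
        "age": rec.age,
    }
    local_rec = json.dumps(meta, separators=(",", ":"))
    header = b""
    header += _edf_field("0", 8)
    header += _edf_field(rec.subject_id, 80)
    header += _edf_field(local_rec, 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    n_chan = len(chans)
    header_bytes = 256 + 256 * n_chan
    header += _edf_field(str(header_bytes), 8)
    header += _edf_field("", 44)
    header += _edf_field("1", 8)  # number of data records
    header += _edf_field(f"{record_duration:.6f}"[:8], 8)
    header += _edf_field(str(n_chan), 4)
    for name, _ in chans:
        header += _edf_field(name, 16)
    for _ in chans:
        header += _edf_field("", 80)  # transducer
    for _ in chans:
        header += _edf_field("uV", 8)
    for lo, hi in phys_ranges:
        header += _edf_field(f"{lo:.8g}"[:8], 8)
    for lo, hi in phys_ranges:
        header += _edf_field(f"{hi:.8g}"[:8], 8)
    for _ in chans:
        header += _edf_field(str(_EDF_DIGITAL_MIN), 8)
    for _ in chans:
        header += _edf_field(str(_EDF_DIGITAL_MAX), 8)
    for _ in chans:
        header += _edf_field("", 80)  # prefiltering
    for _ in chans:
        header += _edf_field(str(n), 8)
    for _ in chans:
        header += _edf_field("", 32)
    assert len(header) == header_bytes

    with open(path, "wb") as fh:
        fh.write(header)
        for (name, x), (lo, hi) in zip(chans, phys_ranges):
            scale = (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN) / (hi - lo)
            dig = np.round((x - lo) * scale + _EDF_DIGITAL_MIN)
            dig = np.clip(dig, _EDF_DIGITAL_MIN, _EDF_DIGITAL_MAX).astype("<i2")
            fh.write(dig.tobytes())


def _read_edf(path: Path, channel_map: dict | None) -> Recording:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        local_rec = head[88:168].decode("ascii", errors="replace").strip()
        header_bytes = int(head[184:192])
        n_records = int(head[236:244])
        record_duration = float(head[244:252])
        n_chan = int(head[252:256])
        chan_head = fh.read(header_bytes - 256)

        def fields(offset: int, width: int) -> list[str]:
            base = offset * n_chan
            return [
                chan_head[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_chan)
            ]

        labels = fields(0, 16)
        # per-channel blocks: label16, transducer80, dim8, phys_min8, phys_max8,
        # dig_min8, dig_max8, prefilter80, n_samples8, reserved32
        off = 16 * n_chan + 80 * n_chan
        dims = [chan_head[off + i * 8 : off + (i + 1) * 8].decode().strip() for i in range(n_chan)]
        off += 8 * n_chan
        pmin = [float(chan_head[off + i * 8 : off + (i + 1) * 8]) for i in range(n_chan)]
        off += 8 * n_chan
        pmax = [float(chan_head[off + i * 8 : off + (i + 1) * 8]) for i in range(n_chan)]
        off += 8 * n_chan
        dmin = [int(chan_head[off + i * 8 : off + (i + 1) * 8]) for i in range(n_chan)]
        off += 8 * n_chan
        dmax = [int(chan_head[off + i * 8 : off + (i + 1) * 8]) for i in range(n_chan)]
        off += 8 * n_chan + 80 * n_chan
        nsamp = [int(chan_head[off + i * 8 : off + (i + 1) * 8]) for i in range(n_chan)]

        signals: list[np.ndarray] = [np.empty(0)] * n_chan
        chunks: list[list[np.ndarray]] = [[] for _ in range(n_chan)]
        for _ in range(n_records):
            for i in range(n_chan):
                raw = fh.read(2 * nsamp[i])
                if len(raw) < 2 * nsamp[i]:
                    raise ValueError(f"{path}: truncated EDF data record")
                dig = np.frombuffer(raw, dtype="<i2").astype(float)
                scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
                chunks[i].append((dig - dmin[i]) * scale + pmin[i])
        for i in range(n_chan):
            signals[i] = np.concatenate(chunks[i]) if chunks[i] else np.empty(0)

    fs = nsamp[0] / record_duration
    roles = _resolve_channel_roles(labels, channel_map)
    meta: dict = {}
    if local_rec.startswith("{"):
        try:
            meta = json.loads(local_rec)
        except json.JSONDecodeError:
            meta = {}
    age = meta.get("age")
    return Recording(
        flexor=signals[roles["flexor"]],
        extensor=signals[roles["extensor"]],
        fs=fs,
        subject_id=meta.get("subject_id", "anon"),
        group=meta.get("group", "other"),
        side=meta.get("side", "left"),
        age=float(age) if age is not None else None,
    )


# ---------------------------------------------------------------------------
# public recording API


def read_recording(
    path: str | Path,
    format: str = "auto",
    sep: str = "\t",
    channel_map: dict | None = None,
) -> Recording:
    """Read a two-channel EMG recording from EDF or delimited text.

    Parameters
    ----------
    path : file path
    format : {'auto', 'edf', 'delimited'}
        'auto' dispatches on the file suffix ('.edf' → EDF).
    sep : delimiter for the text dialect.
    channel_map : optional {'flexor': label-or-index, 'extensor': ...} override
        when channel labels do not contain 'flex'/'ext'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path, channel_map)
    if format == "delimited":
        return _read_recording_delimited(path, sep, channel_map)
    raise ValueError(f"unknown format {format!r}")


def write_recording(rec: Recording, path: str | Path, format: str = "auto", sep: str = "\t") -> None:
    """Write a Recording to EDF or delimited text (dispatch as read_recording)."""
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        write_recording_edf(rec, path)
        return
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        _write_delimited_header(
            fh,
            rec.fs,
            ["flexor", "extensor"],
            {"subject_id": rec.subject_id, "group": rec.group, "side": rec.side, "age": rec.age},
        )
        for a, b in zip(rec.flexor, rec.extensor):
            fh.write(f"{float(a)!r}{sep}{float(b)!r}\n")


# ---------------------------------------------------------------------------
# tremor-pair text I/O (envelope-domain, post-preprocessing)


def write_tremor_pair(pair, path: str | Path, sep: str = "\t") -> None:
    """Write a TremorPair as delimited text with an fs/metadata header."""
    with open(Path(path), "w") as fh:
        _write_delimited_header(
            fh,
            pair.fs,
            ["flexor_env", "extensor_env"],
            {
                "subject_id": pair.subject_id,
                "group": pair.group,
                "side": pair.side,
                "age": pair.age,
            },
        )
        for a, b in zip(pair.flexor_env, pair.extensor_env):
            fh.write(f"{float(a)!r}{sep}{float(b)!r}\n")


def read_tremor_pair(path: str | Path, sep: str = "\t"):
    """Read a TremorPair written by :func:`write_tremor_pair`."""
    from .preprocess import TremorPair  # local import: preprocess imports io_emg

    path = Path(path)
    header, data = _parse_delimited(path, sep)
    if "fs" not in header:
        raise ValueError(f"{path}: header must carry fs")
    age = header.get("age")
    return TremorPair(
        flexor_env=data.iloc[:, 0].to_numpy(float),
        extensor_env=data.iloc[:, 1].to_numpy(float),
        fs=float(header["fs"]),
        subject_id=header.get("subject_id", "anon"),
        group=header.get("group", "other"),
        side=header.get("side", "left"),
        age=float(age) if age not in (None, "", "None") else None,
    )


# ---------------------------------------------------------------------------
# train tables


def _validate_train_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"train table missing columns {missing}")
    df = df[TRAIN_COLUMNS].copy()
    for col in TRAIN_COLUMNS[1:]:
        df[col] = df[col].astype(float)
    num = df.drop(columns=["subject_id"]).to_numpy(float)
    if num.size and not np.all(np.isfinite(num)):
        raise ValueError("train table contains non-finite values")
    if num.size:
        ph = df["phase_rad"].to_numpy(float)
        if np.any(ph < -np.pi - 1e-12) or np.any(ph > np.pi + 1e-12):
            raise ValueError("phase_rad outside [-pi, pi]")
        dp = df["duration_s"].to_numpy(float) * df["central_frequency_Hz"].to_numpy(float)
        if not np.allclose(dp, df["duration_periods"].to_numpy(float), rtol=1e-6, atol=1e-9):
            raise ValueError("duration_periods inconsistent with duration_s * frequency")
    return df


def write_train_table(trains: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a train table as TSV with the fixed column order."""
    df = _validate_train_table(trains)
    df.to_csv(Path(path), sep=sep, index=False, float_format="%.17g")


def read_train_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a train table written by :func:`write_train_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str}, float_precision="round_trip")
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=(str if c == "subject_id" else float)) for c in TRAIN_COLUMNS})
    return _validate_train_table(df)


# ---------------------------------------------------------------------------
# diagrams


def write_diagram(diagram, path: str | Path, sep: str = "\t") -> None:
    """Write an AUCDiagram as a TSV matrix plus a JSON sidecar (`<path>.json`)."""
    path = Path(path)
    np.savetxt(path, diagram.matrix, delimiter=sep, fmt="%.17g")
    sidecar = {
        "x_axis": list(map(float, diagram.x_axis)),
        "y_axis": list(map(float, diagram.y_axis)),
        "axis_kind": diagram.axis_kind,
        "metadata": diagram.metadata,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_diagram(path: str | Path, sep: str = "\t"):
    """Read an AUCDiagram written by :func:`write_diagram`."""
    from .phase_diagram import AUCDiagram

    path = Path(path)
    matrix = np.loadtxt(path, delimiter=sep, ndmin=2)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    return AUCDiagram(
        x_axis=np.asarray(sidecar["x_axis"], float),
        y_axis=np.asarray(sidecar["y_axis"], float),
        matrix=matrix,
        axis_kind=sidecar["axis_kind"],
        metadata=sidecar.get("metadata", {}),
    )
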