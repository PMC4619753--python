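"""Readers and writers for continuous-wave fNIRS containers.

Two on-disk formats are supported:

* ``.nirs`` — a MATLAB container holding the raw intensity matrix ``d``
  (measurements x time points), the time vector ``t`` (seconds) and the probe
  structure ``SD`` with source/detector positions, the wavelength list and the
  measurement list.
* a minimal Hitachi-style CSV dialect — a ``key,value`` header block
  (including ``Sampling Period[s]`` and ``Wavelength[nm]``) followed by a
  ``Data`` marker and a rectangular numeric block, one column per measurement.

Intermediate pipeline state is persisted as a ``.proc`` record: a MATLAB
container with the raw data, the optical-density matrix, the hemoglobin
concentration series and the probe structure, plus a JSON-encoded processing
history so batch runs are auditable.

Internally channels are 0-based; the measurement list keeps the 1-based
source/detector/wavelength indices exactly as stored on disk.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io as sio

__all__ = [
    "ProbeGeometry",
    "RawRecording",
    "ConcentrationSeries",
    "ProcRecord",
    "CsvDialect",
    "FormatError",
    "read_nirs",
    "write_nirs",
    "read_hitachi_csv",
    "convert_csv_to_nirs",
    "write_proc",
    "read_proc",
]


class FormatError(ValueError):
    """Raised when an on-disk container violates the expected format."""


@dataclass
class ProbeGeometry:
    """Source/detector layout and the channel measurement list.

    ``meas_list`` rows are ``(source, detector, aux, wavelength_index)``,
    1-based as conventionally stored on disk.  Rows measuring the same
    source-detector pair at different wavelengths form one *measurement
    channel* (see :meth:`channel_pairs`).
    """

    source_pos: np.ndarray  # (n_sources, 3), cm
    detector_pos: np.ndarray  # (n_detectors, 3), cm
    meas_list: np.ndarray  # (n_measurements, 4), int, 1-based
    wavelengths: np.ndarray  # (n_wavelengths,), nm

    def __post_init__(self) -> None:
        self.source_pos = np.atleast_2d(np.asarray(self.source_pos, dtype=float))
        self.detector_pos = np.atleast_2d(np.asarray(self.detector_pos, dtype=float))
        self.meas_list = np.atleast_2d(np.asarray(self.meas_list, dtype=int))
        self.wavelengths = np.atleast_1d(np.asarray(self.wavelengths, dtype=float))
        ml = self.meas_list
        if ml.shape[1] < 4:
            raise FormatError("measurement list must have 4 columns (src, det, aux, wavelength)")
        if ml[:, 0].min() < 1 or ml[:, 0].max() > len(self.source_pos):
            raise FormatError("measurement list references a nonexistent source")
        if ml[:, 1].min() < 1 or ml[:, 1].max() > len(self.detector_pos):
            raise FormatError("measurement list references a nonexistent detector")
        if ml[:, 3].min() < 1 or ml[:, 3].max() > len(self.wavelengths):
            raise FormatError("measurement list references a nonexistent wavelength")

    @property
    def n_measurements(self) -> int:
        return len(self.meas_list)

    @property
    def separations(self) -> np.ndarray:
        """Per-measurement source-detector distance (same units as positions)."""
        src = self.source_pos[self.meas_list[:, 0] - 1]
        det = self.detector_pos[self.meas_list[:, 1] - 1]
        sep = np.linalg.norm(src - det, axis=1)
        if np.any(sep <= 0):
            raise FormatError("zero source-detector separation in probe geometry")
        return sep

    def channel_pairs(self) -> list[tuple[int, ...]]:
        """Group measurement rows by source-detector pair.

        Returns one tuple of 0-based row indices per measurement channel,
        ordered by first occurrence, indices within a tuple ordered by
        wavelength index.
        """
        groups: dict[tuple[int, int], list[int]] = {}
        for i, (s, d) in enumerate(self.meas_list[:, :2]):
            groups.setdefault((int(s), int(d)), []).append(i)
        out = []
        for key, rows in groups.items():
            rows.sort(key=lambda i: self.meas_list[i, 3])
            out.append(tuple(rows))
        return out


def _check_time(t: np.ndarray) -> float:
    t = np.asarray(t, dtype=float).ravel()
    if t.size < 2:
        raise FormatError("time vector needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError("time vector not increasing")
    if (dt.max() - dt.min()) > 1e-6 * dt.mean():
        raise FormatError("time vector not uniformly sampled")
    return 1.0 / dt.mean()


@dataclass
class RawRecording:
    """Raw optical intensity in canonical channels x time orientation."""

    intensity: np.ndarray  # (n_measurements, n_times), detector units
    time: np.ndarray  # (n_times,), seconds
    probe: ProbeGeometry
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        self.time = np.asarray(self.time, dtype=float).ravel()
        self._fs = _check_time(self.time)
        if self.intensity.shape[1] != self.time.size:
            raise FormatError(
                f"intensity has {self.intensity.shape[1]} time points, "
                f"time vector has {self.time.size}"
            )
        if self.intensity.shape[0] != self.probe.n_measurements:
            raise FormatError(
                f"intensity has {self.intensity.shape[0]} rows but the measurement "
                f"list has {self.probe.n_measurements} entries"
            )

    @property
    def sampling_rate(self) -> float:
        """Sampling rate in Hz, derived from the time vector."""
        return self._fs

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]


@dataclass
class ConcentrationSeries:
    """Relative hemoglobin concentration changes per measurement channel.

    All three matrices are channels x time in micromol/L; HbT is the sum of
    HbO and HbR.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray
    time: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        self.hbt = np.atleast_2d(np.asarray(self.hbt, dtype=float))
        self.time = np.asarray(self.time, dtype=float).ravel()
        if not (self.hbo.shape == self.hbr.shape == self.hbt.shape):
            raise ValueError("hbo, hbr, hbt shapes disagree")
        if self.hbo.shape[1] != self.time.size:
            raise ValueError("time axis length mismatch")
        scale = max(np.abs(self.hbt).max(), 1.0)
        if not np.allclose(self.hbt, self.hbo + self.hbr, atol=1e-9 * scale):
            raise ValueError("hbt is not hbo + hbr")

    def signal(self, name: str) -> np.ndarray:
        if name not in ("hbo", "hbr", "hbt"):
            raise ValueError(f"unknown signal {name!r}; expected hbo|hbr|hbt")
        return getattr(self, name)

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    def replace(self, hbo: np.ndarray, hbr: np.ndarray) -> "ConcentrationSeries":
        return ConcentrationSeries(hbo=hbo, hbr=hbr, hbt=hbo + hbr,
                                   time=self.time, sampling_rate=self.sampling_rate)


@dataclass
class ProcRecord:
    """A preprocessed recording: raw data, OD, concentrations and history."""

    raw: RawRecording
    od: np.ndarray | None = None
    conc: ConcentrationSeries | None = None
    history: list[tuple[str, dict, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.od is not None:
            self.od = np.atleast_2d(np.asarray(self.od, dtype=float))
            if self.od.shape != self.raw.intensity.shape:
                raise ValueError("OD shape does not match raw intensity")

    @property
    def probe(self) -> ProbeGeometry:
        return self.raw.probe

    def log(self, op: str, params: dict | None = None) -> None:
        """Append a processing step to the (append-only) history."""
        stamp = datetime.now(timezone.utc).isoformat()
        self.history.append((op, dict(params or {}), stamp))


# ---------------------------------------------------------------------------
# .nirs container
# ---------------------------------------------------------------------------

def _orient_d(d: np.ndarray, n_times: int, orientation: str | None) -> np.ndarray:
    d = np.atleast_2d(d)
    if np.iscomplexobj(d):
        raise FormatError("complex-valued intensity (demodulated data) is not supported")
    if orientation == "channels_by_time":
        return d
    if orientation == "time_by_channels":
        return d.T
    if d.shape[0] == d.shape[1]:
        raise FormatError(
            "square intensity matrix: orientation is ambiguous, pass "
            "orientation='channels_by_time' or 'time_by_channels'"
        )
    if d.shape[1] == n_times:
        return d
    if d.shape[0] == n_times:
        return d.T
    raise FormatError(
        f"neither dimension of d {d.shape} matches the time vector length {n_times}"
    )


def _sd_to_mat(probe: ProbeGeometry) -> dict:
    return {
        "SrcPos": probe.source_pos,
        "DetPos": probe.detector_pos,
        "MeasList": probe.meas_list.astype(float),
        "Lambda": probe.wavelengths,
        "nSrcs": float(len(probe.source_pos)),
        "nDets": float(len(probe.detector_pos)),
    }


def _sd_from_mat(sd: dict, path: Path) -> ProbeGeometry:
    for key in ("SrcPos", "DetPos", "MeasList", "Lambda"):
        if key not in sd:
            raise FormatError(f"{path}: SD structure is missing field {key!r}")
    return ProbeGeometry(
        source_pos=np.atleast_2d(sd["SrcPos"]),
        detector_pos=np.atleast_2d(sd["DetPos"]),
        meas_list=np.rint(np.atleast_2d(sd["MeasList"])).astype(int),
        wavelengths=np.atleast_1d(sd["Lambda"]),
    )


def read_nirs(path: str | Path, orientation: str | None = None) -> RawRecording:
    """Read a ``.nirs`` MATLAB container.

    The intensity matrix is returned in channels x time orientation regardless
    of how it is stored; the orientation is disambiguated by matching one
    dimension against ``len(t)``.  A square matrix requires an explicit
    ``orientation`` flag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mat = sio.loadmat(path, simplify_cells=True)
    except Exception as exc:  # corrupt container
        raise FormatError(f"{path}: not a readable MATLAB container ({exc})") from exc
    for var in ("d", "t", "SD"):
        if var not in mat:
            raise FormatError(f"{path}: missing required variable {var!r}")
    t = np.asarray(mat["t"], dtype=float).ravel()
    fs = _check_time(t)  # noqa: F841 - raises on bad time vector
    d = _orient_d(np.asarray(mat["d"]), t.size, orientation)
    probe = _sd_from_mat(mat["SD"], path)
    return RawRecording(intensity=d, time=t, probe=probe, subject_id=path.stem)


def write_nirs(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as a ``.nirs`` MATLAB container (measurements x time)."""
    sio.savemat(str(path), {
        "d": rec.intensity,
        "t": rec.time.reshape(-1, 1),
        "SD": _sd_to_mat(rec.probe),
    })


# ---------------------------------------------------------------------------
# Hitachi-style CSV
# ---------------------------------------------------------------------------

@dataclass
class CsvDialect:
    """Configurable separators for the documented CSV dialect.

    The dialect is a stand-in for vendor exports: ``key<sep>value`` header
    lines — at minimum ``Sampling Period[s]`` — then a line equal to
    ``data_marker``, then a rectangular numeric block with one column per
    measurement, wavelength-major within each source-detector pair.
    """

    sep: str = ","
    data_marker: str = "Data"


def read_hitachi_csv(path: str | Path, dialect: CsvDialect | None = None) -> RawRecording:
    """Read a recording from the documented CSV dialect."""
    dialect = dialect or CsvDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    in_data = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if not in_data:
                if line == dialect.data_marker:
                    in_data = True
                    continue
                parts = line.split(dialect.sep)
                if len(parts) >= 2:
                    header[parts[0].strip()] = dialect.sep.join(p.strip() for p in parts[1:])
                continue
            cells = line.split(dialect.sep)
            row = []
            for col, cell in enumerate(cells, start=1):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell at row {lineno}, column {col}: {cell!r}"
                    ) from None
            rows.append(row)
    if "Sampling Period[s]" not in header:
        raise FormatError(f"{path}: missing 'Sampling Period[s]' header line")
    period = float(header["Sampling Period[s]"])
    if period <= 0:
        raise FormatError(f"{path}: nonpositive sampling period")
    if not rows:
        raise FormatError(f"{path}: no samples in data block")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged data block (row widths {sorted(widths)})")
    data = np.asarray(rows, dtype=float)  # time x measurements
    n_meas = data.shape[1]
    wavelengths = np.asarray(
        [float(w) for w in header.get("Wavelength[nm]", "690,830").replace(dialect.sep, ",").split(",")]
    ) if "Wavelength[nm]" in header else np.array([690.0, 830.0])
    n_wl = len(wavelengths)
    if n_meas % n_wl:
        raise FormatError(
            f"{path}: {n_meas} data columns not divisible by {n_wl} wavelengths"
        )
    n_pairs = n_meas // n_wl
    sep_cm = float(header.get("Separation[cm]", "3.0"))
    # Vendor CSVs carry no optode coordinates; synthesize a collinear layout
    # with the declared (or default 3 cm) separation so downstream geometry
    # queries stay well defined.
    src = np.array([[3.0 * sep_cm * c, 0.0, 0.0] for c in range(n_pairs)])
    det = src + np.array([sep_cm, 0.0, 0.0])
    ml = np.array([
        [c + 1, c + 1, 1, w + 1]
        for c in range(n_pairs) for w in range(n_wl)
    ], dtype=int)
    time = np.arange(data.shape[0]) * period
    probe = ProbeGeometry(source_pos=src, detector_pos=det, meas_list=ml,
                          wavelengths=wavelengths)
    return RawRecording(intensity=data.T, time=time, probe=probe,
                        subject_id=path.stem)


def convert_csv_to_nirs(in_path: str | Path, out_path: str | Path,
                        dialect: CsvDialect | None = None) -> None:
    """Convert a CSV export to a ``.nirs`` container readable by :func:`read_nirs`."""
    write_nirs(read_hitachi_csv(in_path, dialect), out_path)


# ---------------------------------------------------------------------------
# .proc container
# ---------------------------------------------------------------------------

def write_proc(rec: ProcRecord, path: str | Path) -> None:
    """Persist a processed record (RawData/OD/Conc/SD + history) losslessly.

    A record whose concentrations have not yet been computed is written with
    an explicit empty marker and flagged on read.
    """
    out: dict = {
        "RawData": rec.raw.intensity,
        "t": rec.raw.time.reshape(-1, 1),
        "SD": _sd_to_mat(rec.raw.probe),
        "OD": rec.od if rec.od is not None else np.zeros((0, 0)),
        "HistoryJSON": json.dumps([list(h) for h in rec.history]),
        "SubjectID": rec.raw.subject_id,
    }
    if rec.conc is not None:
        out["Conc"] = {
            "HbO": rec.conc.hbo, "HbR": rec.conc.hbr, "HbT": rec.conc.hbt,
            "t": rec.conc.time.reshape(-1, 1), "fs": rec.conc.sampling_rate,
        }
    else:
        out["Conc"] = np.zeros((0, 0))
    sio.savemat(str(path), out)


def read_proc(path: str | Path) -> ProcRecord:
    """Read a ``.proc`` record back; warns when concentrations are absent."""
    path = Path(path)
    try:
        mat = sio.loadmat(path, simplify_cells=True)
    except Exception as exc:
        raise FormatError(f"{path}: corrupt proc container ({exc})") from exc
    for var in ("RawData", "t", "SD", "OD", "Conc"):
        if var not in mat:
            raise FormatError(f"{path}: missing required field {var!r}")
    t = np.asarray(mat["t"], dtype=float).ravel()
    probe = _sd_from_mat(mat["SD"], path)
    subject = str(mat.get("SubjectID", path.stem)) or path.stem
    raw = RawRecording(intensity=np.atleast_2d(mat["RawData"]), time=t,
                       probe=probe, subject_id=subject)
    od = np.atleast_2d(mat["OD"])
    od_out = od if od.size else None
    conc = None
    c = mat["Conc"]
    if isinstance(c, dict) and np.asarray(c.get("HbO", np.zeros(0))).size:
        fs = float(np.asarray(c["fs"]).ravel()[0])
        conc = ConcentrationSeries(
            hbo=c["HbO"], hbr=c["HbR"], hbt=c["HbT"],
            time=np.asarray(c["t"], dtype=float).ravel(), sampling_rate=fs,
        )
    else:
        warnings.warn(f"{path}: concentration missing from proc record")
    history_raw = json.loads(str(mat.get("HistoryJSON", "[]")))
    history = [(h[0], h[1], h[2]) for h in history_raw]
    return ProcRecord(raw=raw, od=od_out, conc=conc, history=history)
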