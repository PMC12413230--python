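"""Spectrum input/output: delimited text, Bruker processed directories,
result export and session persistence.

The ppm axis is normalized to strictly ascending order on read; Bruker stores
it descending, text files may use either. Exports use ``%.17g`` formatting so
doubles survive a write/read round trip bit-exactly.
"""

from __future__ import annotations

import csv
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .errors import FormatError, MultipletFitError, VersionError

__all__ = [
    "Spectrum1D",
    "SpectrumSeries",
    "Session",
    "read_text",
    "write_text",
    "read_bruker",
    "write_bruker",
    "export_results",
    "save_session",
    "load_session",
    "SESSION_SCHEMA_VERSION",
]

SESSION_SCHEMA_VERSION = 1


def _fmt(v: float) -> str:
    """Locale-independent full-precision float formatting."""
    return format(float(v), ".17g")


@dataclass
class Spectrum1D:
    """One 1D spectrum: ascending ppm axis, intensity vector, metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError("spectrum axes must be one-dimensional")
        if self.ppm.size != self.intensity.size:
            raise FormatError(
                f"ppm axis has {self.ppm.size} points but intensity has "
                f"{self.intensity.size}"
            )
        if np.any(~np.isfinite(self.ppm)) or np.any(~np.isfinite(self.intensity)):
            raise FormatError("spectrum contains non-finite values")
        d = np.diff(self.ppm)
        if np.all(d < 0):  # descending input: normalize
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise FormatError("ppm axis is not strictly monotone")

    @property
    def sf_mhz(self) -> float | None:
        return self.meta.get("sf_mhz")


@dataclass
class SpectrumSeries:
    """Pseudo-2D experiment: rows of intensities sharing one ppm axis."""

    ppm: np.ndarray
    data: np.ndarray  # shape (n_rows, n_points)
    labels: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("series data must be a 2D array (rows x points)")
        if self.data.shape[1] != self.ppm.size:
            raise FormatError(
                f"series rows have {self.data.shape[1]} points but axis has {self.ppm.size}"
            )
        if np.any(~np.isfinite(self.data)) or np.any(~np.isfinite(self.ppm)):
            raise FormatError("series contains non-finite values")
        if not self.labels:
            self.labels = list(range(self.data.shape[0]))
        if len(self.labels) != self.data.shape[0]:
            raise FormatError("one label required per row")
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("row labels must be unique")
        d = np.diff(self.ppm)
        if np.all(d < 0):
            self.ppm = self.ppm[::-1].copy()
            self.data = self.data[:, ::-1].copy()
        elif not np.all(d > 0):
            raise FormatError("ppm axis is not strictly monotone")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def row(self, i: int) -> Spectrum1D:
        meta = dict(self.meta)
        meta["row_index"] = i
        meta["row_label"] = self.labels[i]
        return Spectrum1D(self.ppm.copy(), self.data[i].copy(), meta)


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

def _detect_delimiter(line: str) -> str | None:
    for cand in ("\t", ",", ";"):
        if cand in line:
            return cand
    return None  # whitespace split


def _split(line: str, delim: str | None) -> list[str]:
    if delim is None:
        return line.split()
    return [c.strip() for c in line.split(delim)]


def read_text(path: str | Path, delimiter: str | None = None):
    """Read a delimited text spectrum.

    Column 1 is the ppm axis; columns 2..k are intensity rows. Returns
    :class:`Spectrum1D` for two columns, :class:`SpectrumSeries` otherwise.
    The delimiter is auto-detected among tab/comma/semicolon/whitespace unless
    given. A leading non-numeric row is treated as a header.
    """
    path = Path(path)
    rows: list[list[float]] = []
    header: list[str] | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            delim = delimiter if delimiter is not None else _detect_delimiter(line)
            cells = _split(line, delim)
            parsed: list[float] = []
            for colno, cell in enumerate(cells, start=1):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    if not rows and header is None:
                        header = cells
                        parsed = []
                        break
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at row {lineno}, "
                        f"column {colno}"
                    ) from None
            if parsed:
                if rows and len(parsed) != len(rows[0]):
                    raise FormatError(
                        f"{path}: row {lineno} has {len(parsed)} columns, "
                        f"expected {len(rows[0])}"
                    )
                rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: no numeric data found")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 columns (ppm, intensity), got 1")
    meta = {"source": str(path)}
    if arr.shape[1] == 2:
        return Spectrum1D(arr[:, 0], arr[:, 1], meta)
    labels: list = list(range(arr.shape[1] - 1))
    if header is not None and len(header) == arr.shape[1]:
        labels = header[1:]
    return SpectrumSeries(arr[:, 0], arr[:, 1:].T, labels, meta)


def write_text(obj, path: str | Path, delimiter: str = "\t") -> Path:
    """Write a spectrum or series as delimited text at full double precision."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if isinstance(obj, Spectrum1D):
            for p, v in zip(obj.ppm, obj.intensity):
                fh.write(_fmt(p) + delimiter + _fmt(v) + "\n")
        elif isinstance(obj, SpectrumSeries):
            for i in range(obj.ppm.size):
                cells = [_fmt(obj.ppm[i])] + [_fmt(v) for v in obj.data[:, i]]
                fh.write(delimiter.join(cells) + "\n")
        else:
            raise MultipletFitError(f"cannot write object of type {type(obj).__name__}")
    return path


# ---------------------------------------------------------------------------
# Bruker processed data
# ---------------------------------------------------------------------------

def _parse_jcamp(path: Path) -> dict:
    """Parse the ``##$KEY= value`` entries of a Bruker parameter file."""
    if not path.is_file():
        raise FormatError(f"missing Bruker parameter file: {path}")
    params: dict = {}
    for line in path.read_text(errors="replace").splitlines():
        if not line.startswith("##$"):
            continue
        key, _, value = line[3:].partition("=")
        value = value.strip()
        try:
            params[key.strip()] = int(value)
        except ValueError:
            try:
                params[key.strip()] = float(value)
            except ValueError:
                params[key.strip()] = value
    return params


def _require(params: dict, key: str, path: Path):
    if key not in params:
        raise FormatError(f"{path}: missing required parameter ##${key}")
    return params[key]


def _axis_from_procs(procs: dict, path: Path) -> tuple[np.ndarray, float]:
    si = int(_require(procs, "SI", path))
    offset = float(_require(procs, "OFFSET", path))
    sw_p = float(_require(procs, "SW_p", path))
    sf = float(_require(procs, "SF", path))
    step = sw_p / sf / si
    ppm = offset - step * np.arange(si)
    return ppm, sf


def _read_processed_vector(path: Path, n_expected: int, procs: dict) -> np.ndarray:
    if not path.is_file():
        raise FormatError(f"missing Bruker data file: {path}")
    dtypp = int(procs.get("DTYPP", 0))
    bytordp = int(procs.get("BYTORDP", 0))
    dtype = np.dtype("float64" if dtypp == 2 else "int32")
    dtype = dtype.newbyteorder(">" if bytordp == 1 else "<")
    raw = np.frombuffer(path.read_bytes(), dtype=dtype)
    if raw.size != n_expected:
        raise FormatError(
            f"{path}: expected {n_expected} points, found {raw.size}"
        )
    scale = 2.0 ** int(procs.get("NC_proc", 0))
    return raw.astype(float) * scale


def _deblock(flat: np.ndarray, si1: int, si2: int, xdim1: int, xdim2: int) -> np.ndarray:
    """Undo Bruker submatrix storage of a processed 2D file."""
    if xdim1 in (0, si1) and xdim2 in (0, si2):
        return flat.reshape(si1, si2)
    if si1 % xdim1 or si2 % xdim2:
        raise FormatError(
            f"submatrix shape ({xdim1}, {xdim2}) does not tile ({si1}, {si2})"
        )
    nb1, nb2 = si1 // xdim1, si2 // xdim2
    return (
        flat.reshape(nb1, nb2, xdim1, xdim2)
        .transpose(0, 2, 1, 3)
        .reshape(si1, si2)
    )


def read_bruker(base_dir: str | Path, expno: int | str = 1, procno: int | str = 1):
    """Read a processed Bruker 1D (``1r``) or pseudo-2D (``2rr``) dataset.

    ``base_dir/expno/pdata/procno`` must contain ``procs`` plus the data file;
    pseudo-2D additionally needs ``proc2s``. Intensities are rescaled by
    ``2**NC_proc``; the ppm axis is rebuilt from OFFSET/SW_p/SF/SI.
    """
    pdata = Path(base_dir) / str(expno) / "pdata" / str(procno)
    if not pdata.is_dir():
        raise FormatError(f"no processed data directory: {pdata}")
    procs_path = pdata / "procs"
    procs = _parse_jcamp(procs_path)
    ppm, sf = _axis_from_procs(procs, procs_path)
    meta = {
        "sf_mhz": sf,
        "source": str(pdata),
        "experiment": str(expno),
        "procno": str(procno),
    }
    two_d = (pdata / "2rr").is_file()
    if not two_d:
        data = _read_processed_vector(pdata / "1r", ppm.size, procs)
        return Spectrum1D(ppm, data, meta)
    proc2s_path = pdata / "proc2s"
    proc2s = _parse_jcamp(proc2s_path)
    si1 = int(_require(proc2s, "SI", proc2s_path))
    flat = _read_processed_vector(pdata / "2rr", si1 * ppm.size, procs)
    xdim2 = int(procs.get("XDIM", 0))
    xdim1 = int(proc2s.get("XDIM", 0))
    mat = _deblock(flat, si1, ppm.size, xdim1 or si1, xdim2 or ppm.size)
    return SpectrumSeries(ppm, mat, list(range(si1)), meta)


def write_bruker(
    obj,
    base_dir: str | Path,
    expno: int | str = 1,
    procno: int | str = 1,
    sf_mhz: float = 500.0,
) -> Path:
    """Write a spectrum/series as a minimal Bruker processed directory.

    Used to build on-the-fly test fixtures and export synthetic data in a
    vendor-compatible layout. Data are stored as little-endian int32 with an
    ``NC_proc`` chosen to preserve dynamic range.
    """
    pdata = Path(base_dir) / str(expno) / "pdata" / str(procno)
    pdata.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, Spectrum1D):
        ppm, rows = obj.ppm, obj.intensity[None, :]
    else:
        ppm, rows = obj.ppm, obj.data
    sf = float(obj.meta.get("sf_mhz", sf_mhz))
    si = ppm.size
    # stored descending, per vendor convention
    step = ppm[1] - ppm[0]
    offset = float(ppm[-1])
    sw_p = step * si * sf
    desc = rows[:, ::-1]
    amax = float(np.max(np.abs(desc))) or 1.0
    nc_proc = int(np.ceil(np.log2(amax / (2**28))))
    ints = np.round(desc / 2.0**nc_proc).astype("<i4")

    def dump(path: Path, entries: dict) -> None:
        lines = ["##TITLE= processed parameters", "##JCAMPDX= 5.0"]
        lines += [f"##${k}= {v}" for k, v in entries.items()]
        lines.append("##END=")
        path.write_text("\n".join(lines) + "\n")

    dump(
        pdata / "procs",
        {
            "SI": si,
            "OFFSET": _fmt(offset),
            "SW_p": _fmt(sw_p),
            "SF": _fmt(sf),
            "NC_proc": nc_proc,
            "BYTORDP": 0,
            "DTYPP": 0,
            "XDIM": 0,
        },
    )
    if isinstance(obj, Spectrum1D):
        (pdata / "1r").write_bytes(ints[0].tobytes())
    else:
        dump(pdata / "proc2s", {"SI": rows.shape[0], "XDIM": 0, "SF": _fmt(sf)})
        (pdata / "2rr").write_bytes(ints.tobytes())
    return pdata


# ---------------------------------------------------------------------------
# session persistence and result export
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """Everything needed to re-export results: config, signals, fits, log.

    ``entries`` is a list of per-spectrum fit records (plain dicts, JSON
    serializable) as produced by :meth:`record_fit`.
    """

    config: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)
    entries: list = field(default_factory=list)
    log: list = field(default_factory=list)
    schema_version: int = SESSION_SCHEMA_VERSION

    def log_event(self, message: str) -> None:
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        self.log.append({"time": stamp, "message": message})

    def record_fit(self, spectrum_id, region, x, experimental, result) -> dict:
        """Append a fit record built from a :class:`~multipletfit.fitting.FitResult`."""
        entry = {
            "spectrum_id": spectrum_id,
            "region": [float(region[0]), float(region[1])],
            "x": [float(v) for v in x],
            "experimental": [float(v) for v in experimental],
            "cost": float(result.cost),
            "converged": bool(result.converged),
            "message": str(result.message),
            "signals": [],
        }
        for sig in result.signals:
            entry["signals"].append(
                {
                    "id": sig["id"],
                    "model": sig["model"],
                    "parameters": sig["parameters"],
                    "derived": sig["derived"],
                }
            )
        self.entries.append(entry)
        return entry


def save_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "schema_version": session.schema_version,
        "config": session.config,
        "provenance": session.provenance,
        "entries": session.entries,
        "log": session.log,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def load_session(path: str | Path) -> Session:
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read session file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise FormatError(f"{path}: not a multipletfit session file")
    version = payload["schema_version"]
    if not isinstance(version, int) or version > SESSION_SCHEMA_VERSION:
        raise VersionError(
            f"{path}: session schema version {version!r} is newer than the "
            f"supported version {SESSION_SCHEMA_VERSION}; upgrade multipletfit"
        )
    session = Session(
        config=payload.get("config", {}),
        provenance=payload.get("provenance", []),
        entries=payload.get("entries", []),
        log=payload.get("log", []),
        schema_version=version,
    )
    session.log_event(f"session loaded from {path}")
    return session


_PARAMS_HEADER = [
    "spectrum_id",
    "region",
    "signal_id",
    "model",
    "parameter",
    "value",
    "sd",
    "ci_lower",
    "ci_upper",
    "at_bound",
    "converged",
]


def export_results(session: Session, out_dir: str | Path) -> dict[str, Path]:
    """Write ``params.csv``, ``curves.csv`` and ``run.log``.

    ``params.csv`` carries one row per fitted or derived parameter with sd and
    a 95% normal-approximation confidence interval. ``curves.csv`` carries the
    experimental trace, the fitted total, and one column per signal; the
    fitted total equals the sum of the per-signal columns at every grid point.
    """
    from .models import simulate_signal  # deferred: avoid import cycle
    from . import models as _models

    if not session.entries:
        raise MultipletFitError("session holds no fit results to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params_path = out_dir / "params.csv"
    curves_path = out_dir / "curves.csv"
    log_path = out_dir / "run.log"

    registry = _models.default_registry()
    for model_file in session.config.get("model_files", []):
        registry.register(_models.load_model_file(model_file))

    with open(params_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_PARAMS_HEADER)
        for entry in session.entries:
            region = f"{_fmt(entry['region'][0])}:{_fmt(entry['region'][1])}"
            for sig in entry["signals"]:
                rows = sorted(sig["parameters"].items()) + [
                    (k, {"value": v, "sd": "", "at_bound": False})
                    for k, v in sorted(sig["derived"].items())
                ]
                for pname, state in rows:
                    value = state["value"]
                    sd = state.get("sd", "")
                    has_sd = isinstance(sd, (int, float))
                    writer.writerow(
                        [
                            entry["spectrum_id"],
                            region,
                            sig["id"],
                            sig["model"],
                            pname,
                            _fmt(value),
                            _fmt(sd) if has_sd else "",
                            _fmt(value - 1.96 * sd) if has_sd else "",
                            _fmt(value + 1.96 * sd) if has_sd else "",
                            int(bool(state.get("at_bound", False))),
                            int(bool(entry["converged"])),
                        ]
                    )

    with open(curves_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        signal_ids: list[str] = []
        for entry in session.entries:
            for sig in entry["signals"]:
                if sig["id"] not in signal_ids:
                    signal_ids.append(sig["id"])
        writer.writerow(["spectrum_id", "ppm", "experimental", "fitted"] + signal_ids)
        for entry in session.entries:
            x = np.asarray(entry["x"], dtype=float)
            per_signal = {}
            for sig in entry["signals"]:
                model = registry.get(sig["model"])
                values = {k: v["value"] for k, v in sig["parameters"].items()}
                per_signal[sig["id"]] = simulate_signal(model, values, x)
            total = np.zeros_like(x)
            for y in per_signal.values():
                total = total + y
            for i in range(x.size):
                row = [
                    entry["spectrum_id"],
                    _fmt(x[i]),
                    _fmt(entry["experimental"][i]),
                    _fmt(total[i]),
                ]
                row += [
                    _fmt(per_signal[sid][i]) if sid in per_signal else ""
                    for sid in signal_ids
                ]
                writer.writerow(row)

    with open(log_path, "w", encoding="utf-8", newline="\n") as fh:
        for item in session.log:
            fh.write(f"{item['time']}\t{item['message']}\n")

    return {"params": params_path, "curves": curves_path, "log": log_path}
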