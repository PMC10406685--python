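"""Readers and writers for spectrum data.

Three formats are supported:

* the internal container: one directory per series, a JSON manifest
  plus one flat little-endian binary file per spectrum (float64,
  interleaved re/im for complex time-domain data, plain float64 for
  real spectra, row-major);
* a documented subset of the NMRPipe 2D format (512-word float32
  header; the words written and read are listed in ``_PIPE_WORDS``);
* Varian/Agilent fid directories (procpar + fid, big-endian, float32 /
  int32 / int16 traces).
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .sampling import SamplingSchedule
from .signal_model import AxisMeta, Spectrum2D, TimeDomain2D

__all__ = [
    "UnknownFormatError",
    "CorruptDataError",
    "write_container",
    "read_container",
    "write_nmrpipe_2d",
    "read_nmrpipe_2d",
    "write_varian",
    "read_varian",
    "read_spectrum_data",
    "write_manifest",
]


class UnknownFormatError(ValueError):
    pass


class CorruptDataError(ValueError):
    pass


# ---------------------------------------------------------------- internal


def _axis_to_dict(axis: AxisMeta) -> dict:
    return {
        "n_points": axis.n_points,
        "spectral_width": axis.spectral_width,
        "carrier_ppm": axis.carrier_ppm,
        "base_frequency": axis.base_frequency,
    }


def _axis_from_dict(d: dict) -> AxisMeta:
    return AxisMeta(
        n_points=int(d["n_points"]),
        spectral_width=float(d["spectral_width"]),
        carrier_ppm=float(d.get("carrier_ppm", 0.0)),
        base_frequency=float(d.get("base_frequency", 500.0)),
    )


def write_container(path, items, meta: dict | None = None) -> None:
    """Write a list of TimeDomain2D or Spectrum2D to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, item in enumerate(items):
        fname = f"{i:03d}.bin"
        is_time = isinstance(item, TimeDomain2D)
        if is_time:
            raw = np.empty(item.data.shape + (2,), dtype="<f8")
            raw[..., 0] = item.data.real
            raw[..., 1] = item.data.imag
        else:
            raw = np.ascontiguousarray(item.data, dtype="<f8")
        (path / fname).write_bytes(raw.tobytes())
        entry = {
            "file": fname,
            "kind": "time" if is_time else "spectrum",
            "shape": list(item.data.shape),
            "temperature": item.temperature,
            "axis1": _axis_to_dict(item.axis1),
            "axis2": _axis_to_dict(item.axis2),
        }
        if is_time:
            entry["label"] = item.label
            entry["schedule"] = (
                None if item.schedule is None else [int(v) for v in item.schedule.indices]
            )
            entry["schedule_n"] = None if item.schedule is None else int(item.schedule.n)
        else:
            entry["provenance"] = item.provenance
        entries.append(entry)
    manifest = {"format": "diffcs-container-v1", "entries": entries, "meta": meta or {}}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_container(path):
    """Read a container directory; returns (items, meta)."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != "diffcs-container-v1":
        raise UnknownFormatError(f"unrecognized container format in {manifest_path}")
    items = []
    for entry in manifest["entries"]:
        raw = np.frombuffer((path / entry["file"]).read_bytes(), dtype="<f8")
        shape = tuple(entry["shape"])
        axis1, axis2 = _axis_from_dict(entry["axis1"]), _axis_from_dict(entry["axis2"])
        if entry["kind"] == "time":
            if raw.size != 2 * shape[0] * shape[1]:
                raise CorruptDataError(f"truncated data file {entry['file']}")
            raw = raw.reshape(shape + (2,))
            data = raw[..., 0] + 1j * raw[..., 1]
            schedule = None
            if entry.get("schedule") is not None:
                schedule = SamplingSchedule(
                    np.asarray(entry["schedule"], dtype=np.intp),
                    n=int(entry["schedule_n"]),
                )
            items.append(
                TimeDomain2D(
                    data=data,
                    axis1=axis1,
                    axis2=axis2,
                    schedule=schedule,
                    temperature=entry.get("temperature"),
                    label=entry.get("label", ""),
                )
            )
        else:
            if raw.size != shape[0] * shape[1]:
                raise CorruptDataError(f"truncated data file {entry['file']}")
            items.append(
                Spectrum2D(
                    data=raw.reshape(shape).copy(),
                    axis1=axis1,
                    axis2=axis2,
                    temperature=entry.get("temperature"),
                    provenance=entry.get("provenance", "full_ft"),
                )
            )
    return items, manifest.get("meta", {})


# ---------------------------------------------------------------- NMRPipe

# header word offsets (subset)
_PIPE_WORDS = {
    "FDMAGIC": 0,
    "FDFLTORDER": 2,  # 2.345 marks native byte order
    "FDDIMCOUNT": 9,
    "FDF2SW": 100,
    "FDF2OBS": 119,
    "FDF2CAR": 66,
    "FDF1SW": 229,
    "FDF1OBS": 218,
    "FDF1CAR": 67,
    "FDSIZE": 99,  # direct-dimension points per row
    "FDSPECNUM": 219,  # number of rows
    "FDQUADFLAG": 106,
    "FDF1QUADFLAG": 55,
    "FDF2QUADFLAG": 56,
    "FDF1FTFLAG": 222,
    "FDF2FTFLAG": 220,
    "FDTRANSPOSED": 221,
    "FDTEMPERATURE": 157,
    "FD2DPHASE": 256,
}


def write_nmrpipe_2d(spectrum: Spectrum2D, path) -> None:
    """Write a real 2D frequency-domain spectrum as an NMRPipe file."""
    header = np.zeros(512, dtype="<f4")
    w = _PIPE_WORDS
    header[w["FDFLTORDER"]] = 2.345
    header[w["FDDIMCOUNT"]] = 2
    header[w["FDSIZE"]] = spectrum.axis2.n_points
    header[w["FDSPECNUM"]] = spectrum.axis1.n_points
    header[w["FDF2SW"]] = spectrum.axis2.spectral_width
    header[w["FDF2OBS"]] = spectrum.axis2.base_frequency
    header[w["FDF2CAR"]] = spectrum.axis2.carrier_ppm
    header[w["FDF1SW"]] = spectrum.axis1.spectral_width
    header[w["FDF1OBS"]] = spectrum.axis1.base_frequency
    header[w["FDF1CAR"]] = spectrum.axis1.carrier_ppm
    header[w["FDQUADFLAG"]] = 1
    header[w["FDF1QUADFLAG"]] = 1
    header[w["FDF2QUADFLAG"]] = 1
    header[w["FDF1FTFLAG"]] = 1
    header[w["FDF2FTFLAG"]] = 1
    header[w["FD2DPHASE"]] = 2
    if spectrum.temperature is not None:
        header[w["FDTEMPERATURE"]] = spectrum.temperature
    data = np.ascontiguousarray(spectrum.data, dtype="<f4")
    Path(path).write_bytes(header.tobytes() + data.tobytes())


def read_nmrpipe_2d(path) -> Spectrum2D:
    raw = Path(path).read_bytes()
    if len(raw) < 512 * 4:
        raise CorruptDataError(f"{path}: shorter than an NMRPipe header")
    header = np.frombuffer(raw[: 512 * 4], dtype="<f4")
    if abs(header[_PIPE_WORDS["FDFLTORDER"]] - 2.345) > 1e-4:
        header = np.frombuffer(raw[: 512 * 4], dtype=">f4")
        if abs(header[_PIPE_WORDS["FDFLTORDER"]] - 2.345) > 1e-4:
            raise UnknownFormatError(f"{path}: no NMRPipe byte-order signature")
        data_dtype = ">f4"
    else:
        data_dtype = "<f4"
    w = _PIPE_WORDS
    n2 = int(header[w["FDSIZE"]])
    n1 = int(header[w["FDSPECNUM"]])
    data = np.frombuffer(raw[512 * 4 :], dtype=data_dtype)
    if data.size != n1 * n2:
        raise CorruptDataError(
            f"{path}: data size {data.size} does not match header {n1}x{n2}"
        )
    axis1 = AxisMeta(n1, float(header[w["FDF1SW"]]), float(header[w["FDF1CAR"]]),
                     float(header[w["FDF1OBS"]]))
    axis2 = AxisMeta(n2, float(header[w["FDF2SW"]]), float(header[w["FDF2CAR"]]),
                     float(header[w["FDF2OBS"]]))
    temp = float(header[w["FDTEMPERATURE"]])
    return Spectrum2D(
        data=data.astype(np.float64).reshape(n1, n2),
        axis1=axis1,
        axis2=axis2,
        temperature=temp if temp != 0 else None,
    )


# ---------------------------------------------------------------- Varian

_S_FLOAT = 0x8
_S_32 = 0x4


def write_varian(fid: TimeDomain2D, path) -> None:
    """Write a minimal Varian-style fid directory (float32 traces)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n1, n2 = fid.data.shape
    pars = {
        "np": 2 * n2,
        "ni": n1,
        "sw": fid.axis2.spectral_width,
        "sw1": fid.axis1.spectral_width,
        "sfrq": fid.axis2.base_frequency,
        "dfrq": fid.axis1.base_frequency,
    }
    lines = []
    for name, value in pars.items():
        lines.append(f"{name} 1 1 0 0 0 1 1 0 1 64")
        lines.append(f"1 {value}")
        lines.append("0")
    (path / "procpar").write_text("\n".join(lines) + "\n")

    status = 0x1 | _S_FLOAT | 0x10  # data, float, complex
    head = struct.pack(
        ">6i2hi", n1, 1, 2 * n2, 4, 2 * n2 * 4, 2 * n2 * 4 + 28, 0, status, 1
    )
    blocks = [head]
    for i in range(n1):
        blocks.append(struct.pack(">4h4f i", 0, status, i + 1, 0, 0.0, 0.0, 0.0, 0.0, 1))
        trace = np.empty(2 * n2, dtype=">f4")
        trace[0::2] = fid.data[i].real
        trace[1::2] = fid.data[i].imag
        blocks.append(trace.tobytes())
    (path / "fid").write_bytes(b"".join(blocks))


def _parse_procpar(text: str) -> dict:
    values: dict[str, float] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines) - 1:
        parts = lines[i].split()
        if len(parts) >= 2 and not lines[i][:1].isspace() and not parts[0][0].isdigit():
            name = parts[0]
            vals = lines[i + 1].split()
            if len(vals) >= 2:
                try:
                    values[name] = float(vals[1])
                except ValueError:
                    pass
            i += 2
        else:
            i += 1
    return values


def read_varian(path) -> TimeDomain2D:
    """Read a Varian/Agilent fid directory (procpar + fid)."""
    path = Path(path)
    procpar = path / "procpar"
    fid_path = path / "fid"
    if not procpar.exists() or not fid_path.exists():
        raise FileNotFoundError(f"{path} is not a Varian fid directory (procpar/fid missing)")
    pars = _parse_procpar(procpar.read_text())
    raw = fid_path.read_bytes()
    if len(raw) < 32:
        raise CorruptDataError(f"{fid_path}: truncated file header")
    nblocks, ntraces, np_pts, ebytes, tbytes, bbytes, _, status, nbheaders = struct.unpack(
        ">6i2hi", raw[:32]
    )
    if status & _S_FLOAT:
        dtype = ">f4"
    elif status & _S_32:
        dtype = ">i4"
    else:
        dtype = ">i2"
    rows = []
    offset = 32
    for _ in range(nblocks):
        offset += 28 * max(nbheaders, 1)
        end = offset + np_pts * ebytes * max(ntraces, 1)
        if end > len(raw):
            raise CorruptDataError(f"{fid_path}: truncated data block")
        trace = np.frombuffer(raw[offset:end], dtype=dtype).astype(np.float64)
        rows.append(trace[0::2] + 1j * trace[1::2])
        offset = end
    data = np.asarray(rows)
    n2 = np_pts // 2
    axis2 = AxisMeta(n2, float(pars.get("sw", n2)), base_frequency=float(pars.get("sfrq", 500.0)))
    axis1 = AxisMeta(
        data.shape[0], float(pars.get("sw1", data.shape[0])),
        base_frequency=float(pars.get("dfrq", 50.0)),
    )
    return TimeDomain2D(data=data, axis1=axis1, axis2=axis2)


# ---------------------------------------------------------------- dispatch


def read_spectrum_data(path, format: str | None = None):
    """Read time- or frequency-domain data, auto-detecting the format.

    Returns a list of items for the internal container, a TimeDomain2D
    for Varian input and a Spectrum2D for NMRPipe input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format is None:
        if path.is_dir() and (path / "manifest.json").exists():
            format = "internal"
        elif path.is_dir() and (path / "procpar").exists():
            format = "varian"
        elif path.is_file():
            format = "nmrpipe"
        else:
            raise UnknownFormatError(f"cannot determine the format of {path}")
    if format == "internal":
        return read_container(path)[0]
    if format == "varian":
        return read_varian(path)
    if format == "nmrpipe":
        return read_nmrpipe_2d(path)
    raise UnknownFormatError(f"unknown format {format!r}")


def write_manifest(directory, config: dict, seed: int | None = None) -> None:
    """Record how a pipeline output was produced (config, seed, versions)."""
    import scipy

    from . import __version__

    payload = {
        "config": config,
        "seed": seed,
        "versions": {
            "diffcs": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    Path(directory).mkdir(parents=True, exist_ok=True)
    (Path(directory) / "run_manifest.json").write_text(json.dumps(payload, indent=1, default=str))
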