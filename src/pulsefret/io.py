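"""Readers and writers for photon streams and tabular results.

Two interchangeable on-disk layouts are supported:

* **HDF5** (``.h5``/``.hdf5``), following the Photon-HDF5 convention of a
  ``/photon_data`` group with ``timestamps``, ``nanotimes`` and ``detectors``
  datasets plus resolution metadata, and a ``/setup`` group holding the
  channel map and PIE gate boundaries.
* **gzipped columnar text** (``.tsv.gz``/``.txt.gz``), three integer columns
  with the same metadata embedded in ``# key<TAB>json`` header lines.

Both round-trip losslessly (integer ticks, TCSPC channels, detector ids and
all resolutions).  Every file written records the package version and, when
present in the stream metadata, the RNG seed and configuration hash that
produced it.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .photons import ChannelMap, PhotonStream

__all__ = ["read_photon_file", "write_photon_file", "SchemaError"]


class SchemaError(ValueError):
    """A photon file is missing required datasets or metadata."""


_REQUIRED_DATASETS = ("timestamps", "nanotimes", "detectors")
_REQUIRED_ATTRS = ("timestamp_resolution_s", "nanotime_resolution_s")


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5")


def write_photon_file(stream: PhotonStream, path: str | Path) -> Path:
    """Write ``stream`` to ``path``; the format follows the file extension."""
    path = Path(path)
    stream.validate()
    if _is_hdf5(path):
        _write_hdf5(stream, path)
    else:
        _write_text(stream, path)
    return path


def read_photon_file(path: str | Path) -> PhotonStream:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    stream = _read_hdf5(path) if _is_hdf5(path) else _read_text(path)
    stream.validate()
    return stream


# ---------------------------------------------------------------------------
# HDF5 layout
# ---------------------------------------------------------------------------

def _write_hdf5(stream: PhotonStream, path: Path) -> None:
    with h5py.File(path, "w") as fh:
        pd_grp = fh.create_group("photon_data")
        pd_grp.create_dataset("timestamps", data=stream.timestamps)
        pd_grp.create_dataset("nanotimes", data=stream.nanotimes)
        pd_grp.create_dataset("detectors", data=stream.detectors)
        pd_grp.attrs["timestamp_resolution_s"] = stream.timestamp_resolution
        pd_grp.attrs["nanotime_resolution_s"] = stream.nanotime_resolution
        setup = fh.create_group("setup")
        setup.attrs["channel_map"] = json.dumps(stream.channel_map.to_dict())
        ident = fh.create_group("identity")
        ident.attrs["software"] = "pulsefret"
        ident.attrs["version"] = __version__
        ident.attrs["metadata"] = json.dumps(stream.metadata, default=str)


def _read_hdf5(path: Path) -> PhotonStream:
    with h5py.File(path, "r") as fh:
        if "photon_data" not in fh:
            raise SchemaError(f"{path}: missing required group 'photon_data'")
        grp = fh["photon_data"]
        for name in _REQUIRED_DATASETS:
            if name not in grp:
                raise SchemaError(f"{path}: missing dataset 'photon_data/{name}'")
        for name in _REQUIRED_ATTRS:
            if name not in grp.attrs:
                raise SchemaError(f"{path}: missing attribute 'photon_data/{name}'")
        if "setup" not in fh or "channel_map" not in fh["setup"].attrs:
            raise SchemaError(f"{path}: missing attribute 'setup/channel_map'")
        cmap = ChannelMap.from_dict(json.loads(fh["setup"].attrs["channel_map"]))
        metadata = {}
        if "identity" in fh and "metadata" in fh["identity"].attrs:
            metadata = json.loads(fh["identity"].attrs["metadata"])
        return PhotonStream(
            timestamps=grp["timestamps"][:],
            nanotimes=grp["nanotimes"][:],
            detectors=grp["detectors"][:],
            timestamp_resolution=float(grp.attrs["timestamp_resolution_s"]),
            nanotime_resolution=float(grp.attrs["nanotime_resolution_s"]),
            channel_map=cmap,
            metadata=metadata,
        )


# ---------------------------------------------------------------------------
# gzipped columnar text layout
# ---------------------------------------------------------------------------

def _write_text(stream: PhotonStream, path: Path) -> None:
    header = {
        "software": "pulsefret",
        "version": __version__,
        "timestamp_resolution_s": stream.timestamp_resolution,
        "nanotime_resolution_s": stream.nanotime_resolution,
        "channel_map": stream.channel_map.to_dict(),
        "metadata": stream.metadata,
    }
    opener = gzip.open if "".join(path.suffixes).endswith(".gz") else open
    with opener(path, "wt") as fh:  # type: ignore[operator]
        for key, value in header.items():
            fh.write(f"# {key}\t{json.dumps(value, default=str)}\n")
        fh.write("# columns\ttimestamp\tnanotime\tdetector\n")
        for row in zip(stream.timestamps, stream.nanotimes, stream.detectors):
            fh.write(f"{row[0]}\t{row[1]}\t{row[2]}\n")


def _read_text(path: Path) -> PhotonStream:
    opener = gzip.open if "".join(path.suffixes).endswith(".gz") else open
    header: dict = {}
    rows: list[tuple[int, int, int]] = []
    with opener(path, "rt") as fh:  # type: ignore[operator]
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t", 1)
                if len(parts) == 2 and parts[0] != "columns":
                    header[parts[0]] = json.loads(parts[1])
                continue
            a, b, c = line.split("\t")
            rows.append((int(a), int(b), int(c)))
    for name in _REQUIRED_ATTRS:
        if name not in header:
            raise SchemaError(f"{path}: missing header field '{name}'")
    if "channel_map" not in header:
        raise SchemaError(f"{path}: missing header field 'channel_map'")
    arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
    return PhotonStream(
        timestamps=arr[:, 0],
        nanotimes=arr[:, 1].astype(np.int32),
        detectors=arr[:, 2].astype(np.uint8),
        timestamp_resolution=float(header["timestamp_resolution_s"]),
        nanotime_resolution=float(header["nanotime_resolution_s"]),
        channel_map=ChannelMap.from_dict(header["channel_map"]),
        metadata=header.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# provenance helpers for tabular/JSON outputs
# ---------------------------------------------------------------------------

def provenance(config=None, seed=None) -> dict:
    """Provenance block embedded in every CSV/JSON output."""
    out = {"software": "pulsefret", "version": __version__}
    if config is not None:
        out["config_hash"] = config.config_hash()
    if seed is not None:
        out["seed"] = int(seed)
    return out


def write_csv_with_provenance(df, path: str | Path, config=None, seed=None) -> Path:
    """Write a DataFrame as CSV preceded by ``# key=value`` provenance lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in provenance(config, seed).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)
    return path


def write_json_summary(obj: dict, path: str | Path, config=None, seed=None) -> Path:
    path = Path(path)
    payload = {"provenance": provenance(config, seed), **obj}
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    return path
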