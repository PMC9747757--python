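"""File formats: configs (TOML/YAML), rasters (HDF5 / event-list CSV) and
recordings (delimited text / HDF5)."""

from __future__ import annotations

import csv
import tomllib
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .cbm import CBMConfig, Raster
from .errors import InvalidArgumentError
from .events import Recording

__all__ = [
    "load_config_mapping",
    "load_cbm_config",
    "save_raster",
    "load_raster",
    "save_recording",
    "load_recording",
]


def load_config_mapping(path: str | Path) -> dict:
    """Read a TOML (.toml) or YAML (.yaml/.yml) file into a dict."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh) or {}
    raise InvalidArgumentError(f"unsupported config format: {path.suffix!r}")


def load_cbm_config(path: str | Path) -> CBMConfig:
    """Load a :class:`CBMConfig`; keys are exactly the field names."""
    mapping = load_config_mapping(path)
    valid = set(CBMConfig.__dataclass_fields__)
    unknown = set(mapping) - valid
    if unknown:
        raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
    return CBMConfig(**mapping)


def save_raster(raster: Raster, path: str | Path) -> None:
    """Write a raster as HDF5 (.h5/.hdf5) or sparse event-list CSV.

    The CSV has columns ``node,time_step`` (one row per active entry) plus
    ``#``-prefixed header lines carrying the shape and bin metadata.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("raster", data=raster.data, compression="gzip")
            ds.attrs["bin_width"] = raster.bin_width
            if raster.sampling_rate is not None:
                ds.attrs["sampling_rate"] = raster.sampling_rate
        return
    nodes, times = np.nonzero(raster.data)
    with open(path, "w", newline="") as fh:
        fh.write(f"# shape={raster.n_rows}x{raster.n_bins}"
                 f" bin_width={raster.bin_width}\n")
        writer = csv.writer(fh)
        writer.writerow(["node", "time_step"])
        writer.writerows(zip(nodes.tolist(), times.tolist()))


def load_raster(path: str | Path) -> Raster:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["raster"]
            return Raster(
                data=ds[...],
                bin_width=int(ds.attrs.get("bin_width", 1)),
                sampling_rate=(
                    float(ds.attrs["sampling_rate"])
                    if "sampling_rate" in ds.attrs
                    else None
                ),
            )
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise InvalidArgumentError("event-list CSV missing metadata header")
        meta = dict(item.split("=") for item in header[1:].split())
        n_rows, n_bins = (int(v) for v in meta["shape"].split("x"))
        reader = csv.reader(fh)
        next(reader)  # column header
        data = np.zeros((n_rows, n_bins), dtype=np.uint8)
        for node, t in reader:
            data[int(node), int(t)] = 1
    return Raster(data=data, bin_width=int(meta.get("bin_width", 1)))


def save_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as HDF5 or delimited text (channels as columns)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset(
                "recording", data=recording.samples, compression="gzip"
            )
            ds.attrs["sampling_rate"] = recording.sampling_rate
            ds.attrs["channel_ids"] = [c.encode() for c in recording.channel_ids]
        return
    header = "\t".join(recording.channel_ids)
    np.savetxt(path, recording.samples.T, delimiter="\t",
               header=header, comments="", fmt="%.8g")


def load_recording(path: str | Path, sampling_rate: float | None = None) -> Recording:
    """Load a recording; text files need ``sampling_rate`` supplied."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["recording"]
            return Recording(
                samples=ds[...],
                sampling_rate=float(ds.attrs["sampling_rate"]),
                channel_ids=[
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in ds.attrs["channel_ids"]
                ],
            )
    if sampling_rate is None:
        raise InvalidArgumentError("sampling_rate required for text recordings")
    with open(path) as fh:
        channel_ids = fh.readline().strip().split("\t")
    samples = np.loadtxt(path, delimiter="\t", skiprows=1).T
    samples = np.atleast_2d(samples)
    return Recording(
        samples=samples, sampling_rate=sampling_rate, channel_ids=channel_ids
    )
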