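"""Plain-text I/O for spectral maps and plate manifests.

A map file is columnar CSV (UTF-8, '.' decimal separator): the first column
is the wavenumber axis in cm^-1, then one column per spectrum, with a header
row carrying the raster coordinates as ``L{line}P{position}``.  Values are
written at full float64 precision (%.17g) so round trips are lossless.
Files ending in ``.gz`` are transparently gzip-compressed.

A plate manifest is a small YAML document tying the design (samples, wells,
raster geometry, provenance) to the per-well map files.
"""

from __future__ import annotations

import gzip
import io
import re
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd
import yaml

from .errors import ConsistencyError, FormatError
from .spectra import Plate, PlateDesign, Sample, SpectralMap

__all__ = [
    "write_map",
    "read_map",
    "write_plate",
    "read_plate",
]

_COLUMN_RE = re.compile(r"^L(\d+)P(\d+)$")


def _open_text(path: Path, mode: str) -> TextIO:
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, mode + "b"), encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def write_map(smap: SpectralMap, path: str | Path) -> Path:
    """Write one well's map; returns the path written."""
    path = Path(path)
    header = "wavenumber," + ",".join(
        f"L{line}P{pos}" for line, pos in smap.coordinates
    )
    table = np.column_stack([smap.wavenumbers, smap.intensities.T])
    with _open_text(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, table, fmt="%.17g", delimiter=",")
    return path


def read_map(path: str | Path, well_id: str | None = None) -> SpectralMap:
    """Read a map file written by :func:`write_map`.

    ``well_id`` defaults to the file stem.  Raises :class:`FormatError` for
    a missing/garbled header, ragged rows, or a non-ascending axis.
    """
    path = Path(path)
    if well_id is None:
        well_id = path.name.split(".")[0]
    with _open_text(path, "r") as fh:
        header = fh.readline().strip()
        columns = header.split(",") if header else []
        if not columns or columns[0] != "wavenumber":
            raise FormatError(
                f"{path}: missing header (first column must be 'wavenumber')"
            )
        coords = []
        for name in columns[1:]:
            m = _COLUMN_RE.match(name)
            if not m:
                raise FormatError(f"{path}: bad spectrum column name {name!r}")
            coords.append((int(m.group(1)), int(m.group(2))))
        if not coords:
            raise FormatError(f"{path}: no spectrum columns")
        try:
            frame = pd.read_csv(
                fh,
                header=None,
                names=columns,
                dtype=float,
                float_precision="round_trip",
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if frame.isna().to_numpy().any():
        raise FormatError(f"{path}: ragged or non-numeric rows")
    w = frame["wavenumber"].to_numpy()
    if w.size > 1 and not np.all(np.diff(w) > 0):
        raise FormatError(f"{path}: wavenumber axis is not strictly ascending")
    intensities = frame.iloc[:, 1:].to_numpy().T
    try:
        return SpectralMap(well_id, w, intensities, np.asarray(coords))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_plate(
    plate: Plate,
    directory: str | Path,
    plate_id: str = "plate",
    seed: int | None = None,
    compress: bool = False,
    axis_description: str | None = None,
) -> Path:
    """Write every well map plus a ``manifest.yaml``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    design = plate.design
    suffix = ".csv.gz" if compress else ".csv"
    well_files: dict[str, str] = {}
    lines = per_line = None
    for well_id, smap in plate.maps.items():
        filename = well_id + suffix
        write_map(smap, directory / filename)
        well_files[well_id] = filename
        lines = int(smap.coordinates[:, 0].max()) + 1
        per_line = int(smap.coordinates[:, 1].max()) + 1
    axis = next(iter(plate.maps.values())).wavenumbers if plate.maps else None
    manifest = {
        "plate_id": plate_id,
        "rows": design.rows,
        "cols": design.cols,
        "replicate_wells_per_sample": design.replicate_wells_per_sample,
        "raster_lines": lines,
        "raster_per_line": per_line,
        "axis": axis_description
        or (
            f"{axis[0]:g}-{axis[-1]:g} cm^-1, {axis.size} points"
            if axis is not None
            else "empty"
        ),
        "seed": seed,
        "samples": [
            {
                "label": s.label,
                "concentration_ng_mL": s.concentration,
                "index": s.index,
                "wells": design.wells_for(s.index),
            }
            for s in design.samples
        ],
        "well_files": well_files,
    }
    manifest_path = directory / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_plate(manifest_path: str | Path) -> Plate:
    """Read a manifest plus every referenced map file.

    Raises :class:`ConsistencyError` for an empty manifest or design/file
    well mismatches, and :class:`FileNotFoundError` for missing map files.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise FormatError(f"{manifest_path}: manifest is not a mapping")
    samples_spec = manifest.get("samples") or []
    well_files = manifest.get("well_files") or {}
    if not samples_spec or not well_files:
        raise ConsistencyError(f"{manifest_path}: manifest defines no wells")

    samples = []
    well_to_sample: dict[str, int] = {}
    for entry in samples_spec:
        sample = Sample(
            label=str(entry["label"]),
            concentration=float(entry["concentration_ng_mL"]),
            index=int(entry["index"]),
        )
        samples.append(sample)
        for well in entry["wells"]:
            well_to_sample[well] = sample.index
    design = PlateDesign(
        rows=int(manifest["rows"]),
        cols=int(manifest["cols"]),
        samples=tuple(samples),
        well_to_sample=well_to_sample,
        replicate_wells_per_sample=int(manifest["replicate_wells_per_sample"]),
    )

    missing = [w for w in design.well_ids if w not in well_files]
    if missing:
        raise ConsistencyError(f"{manifest_path}: no map file for wells {missing}")
    maps: dict[str, SpectralMap] = {}
    for well_id in design.well_ids:
        path = manifest_path.parent / well_files[well_id]
        if not path.exists():
            raise FileNotFoundError(f"map file missing: {path}")
        maps[well_id] = read_map(path, well_id=well_id)

    n_expected = int(manifest["raster_lines"]) * int(manifest["raster_per_line"])
    for well_id, smap in maps.items():
        if smap.n_spectra != n_expected:
            raise ConsistencyError(
                f"well {well_id}: {smap.n_spectra} spectra, expected {n_expected}"
            )
    return Plate(design=design, maps=maps)
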