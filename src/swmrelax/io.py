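"""Readers, writers and provenance records for the pipeline.

CSV is the lingua franca for tables and small 2D grids; TIFF is
supported for microscopy-style grids and NIfTI for 3D volumes.  2D
grids carry their physical geometry and units in a JSON sidecar file
(same path with an added ``.json`` suffix), e.g.::

    iron.csv        # the grid
    iron.csv.json   # {"pixel_size_um": 1.0, "section_thickness_um": 10.0,
                    #  "units": "ug/g"}

Every written artifact can be accompanied by a provenance record
(inputs, parameters, constants, seed, package version) sufficient to
reproduce it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .fieldsim import IronConcentrationMap, LarmorFieldMap, LineShape
from .surface import SurfaceSampleTable

__all__ = [
    "QuantitativeMap",
    "read_quantitative_map",
    "write_quantitative_map",
    "write_field_nifti",
    "write_line_shape",
    "read_surface_table",
    "write_surface_table",
    "write_provenance",
]

PathLike = Union[str, Path]

# canonical unit strings per quantity kind
_UNIT_ALIASES = {
    "ug/g": {"ug/g", "ug/g wtw", "ppm", "ppm wtw", "µg/g"},
    "s^-1": {"s^-1", "1/s", "s-1", "hz*2pi"},
    "ppb": {"ppb"},
    "rad/s": {"rad/s"},
    "fraction": {"fraction", "dimensionless", "1"},
}


@dataclass
class QuantitativeMap:
    """A gridded quantitative value with geometry and declared units."""

    values: np.ndarray
    pixel_size: tuple
    units: str
    section_thickness: Optional[float] = None

    def as_iron_map(self) -> IronConcentrationMap:
        if not _units_match(self.units, "ug/g"):
            raise ValueError(
                f"map declares units {self.units!r}, expected an iron "
                "concentration in ug/g wtw"
            )
        return IronConcentrationMap(
            self.values, self.pixel_size, self.section_thickness
        )


def _units_match(declared: str, expected: str) -> bool:
    aliases = _UNIT_ALIASES.get(expected, {expected})
    return declared.strip().lower() in {a.lower() for a in aliases}


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _load_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing geometry sidecar {sidecar}; write a JSON file with at "
            'least {"pixel_size_um": <um>, "units": "<units>"}'
        )
    return json.loads(sidecar.read_text())


def read_quantitative_map(
    path: PathLike, expected_units: Optional[str] = None
) -> QuantitativeMap:
    """Read a gridded map from CSV, TIFF or NIfTI with its geometry.

    CSV and TIFF grids require a JSON sidecar declaring
    ``pixel_size_um`` (scalar or per-axis list) and ``units``; NIfTI
    volumes take the pixel size from the header zooms (assumed mm,
    converted to um) and the units from the sidecar if present, else
    the header description.  When ``expected_units`` is given, the
    declared units must name the same quantity or the read is rejected.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        values = np.loadtxt(path, delimiter=",", ndmin=2)
        meta = _load_sidecar(path)
    elif suffix in (".tif", ".tiff"):
        values = np.asarray(tifffile.imread(path), dtype=float)
        meta = _load_sidecar(path)
    elif suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        values = np.asarray(img.get_fdata())
        zooms = img.header.get_zooms()[: values.ndim]
        meta = {"pixel_size_um": [z * 1000.0 for z in zooms]}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta.update(json.loads(sidecar.read_text()))
        else:
            descrip = img.header.get("descrip", b"")
            meta.setdefault("units", bytes(descrip).decode(errors="ignore").strip("\x00"))
    else:
        raise ValueError(f"unsupported map format: {path.name}")

    if "pixel_size_um" not in meta:
        raise ValueError(
            f"{path.name}: sidecar lacks 'pixel_size_um'; add the physical "
            "pixel size in micrometers"
        )
    units = str(meta.get("units", "")).strip()
    if not units:
        raise ValueError(f"{path.name}: no units declared for this map")
    if expected_units is not None and not _units_match(units, expected_units):
        raise ValueError(
            f"{path.name}: declared units {units!r} do not match the "
            f"expected quantity ({expected_units})"
        )
    pix = meta["pixel_size_um"]
    pixel_size = tuple(np.atleast_1d(np.asarray(pix, dtype=float)))
    if len(pixel_size) == 1:
        pixel_size = pixel_size * values.ndim
    return QuantitativeMap(
        values=values,
        pixel_size=pixel_size,
        units=units,
        section_thickness=meta.get("section_thickness_um"),
    )


def write_quantitative_map(
    path: PathLike,
    values: np.ndarray,
    pixel_size,
    units: str,
    section_thickness: Optional[float] = None,
) -> Path:
    """Write a 2D grid as CSV (or TIFF) plus its JSON geometry sidecar."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, values, delimiter=",")
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, values.astype(np.float32))
    else:
        raise ValueError(f"unsupported grid format: {path.name}")
    meta = {
        "pixel_size_um": list(np.atleast_1d(pixel_size).astype(float)),
        "units": units,
    }
    if section_thickness is not None:
        meta["section_thickness_um"] = float(section_thickness)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def write_field_nifti(path: PathLike, field_map: LarmorFieldMap) -> Path:
    """Write a 3D Larmor field map as NIfTI with rad/s noted in the header."""
    path = Path(path)
    pixel_mm = (
        np.asarray(field_map.pixel_size, dtype=float) / 1000.0
        if field_map.pixel_size is not None
        else np.ones(3)
    )
    affine = np.diag([*pixel_mm, 1.0])
    img = nib.Nifti1Image(field_map.values.astype(np.float32), affine)
    img.header["descrip"] = b"Larmor frequency offset, rad/s"
    nib.save(img, str(path))
    return path


def write_line_shape(path_prefix: PathLike, shape: LineShape) -> dict:
    """Export a line shape as two-column CSV plus a JSON fit summary."""
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    pd.DataFrame(
        {"frequency_rad_s": shape.bin_centers, "density": shape.density}
    ).to_csv(csv_path, index=False)
    summary = {
        "model": shape.model,
        "fwhm_rad_s": shape.fwhm,
        "fit_residual": shape.fit_residual,
        "degenerate": shape.degenerate,
        "candidates": shape.candidates,
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(summary, indent=2))
    return {"csv": csv_path, "json": json_path}


def read_surface_table(path: PathLike) -> SurfaceSampleTable:
    """Read a per-vertex CSV table and its optional JSON metadata sidecar."""
    path = Path(path)
    data = pd.read_csv(path)
    sidecar = _sidecar_path(path)
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SurfaceSampleTable(data, metadata)


def write_surface_table(path: PathLike, table: SurfaceSampleTable) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False)
    _sidecar_path(path).write_text(json.dumps(table.metadata, indent=2, default=str))
    return path


def write_provenance(
    path: PathLike,
    *,
    stage: str,
    inputs: Optional[dict] = None,
    parameters: Optional[dict] = None,
    constants: Optional[dict] = None,
    seed: Optional[int] = None,
) -> Path:
    """Write a JSON provenance record next to an output artifact."""
    record = {
        "stage": stage,
        "inputs": inputs or {},
        "parameters": parameters or {},
        "constants": constants or {},
        "seed": seed,
        "software": {"package": "swmrelax", "version": __version__},
    }
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
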