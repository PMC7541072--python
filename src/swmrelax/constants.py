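"""Physical constants and unit conversions for the SWM relaxation model.

All other modules take a :class:`PhysicalConstants` instance so that the
model is parameter-free where the underlying physics is: the proton
gyromagnetic ratio, the static field strength, the mass magnetic
susceptibility of ferritin-bound iron, the nanoscale relaxivity of
ferritin-bound iron, the tissue density used to convert section
concentrations, and the tissue shrinkage factor of dehydrated sections.

Unit conventions
----------------
* Iron concentrations are in micrograms per gram of wet tissue weight
  (ug/g wtw). "ppm wtw" is the same unit (1 ppm by mass == 1 ug/g).
* All frequencies are angular (rad/s) internally.  Reported line widths
  in "s^-1" follow the common convention of quoting rad/s as s^-1.
* Volume magnetic susceptibility is dimensionless (SI).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "PhysicalConstants",
    "mass_to_volume_susceptibility",
    "volume_to_mass_concentration",
    "areal_to_mass_concentration",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the iron-relaxation model.

    Attributes
    ----------
    gamma:
        Proton gyromagnetic ratio, rad s^-1 T^-1.
    B0:
        Static magnetic field strength, T.
    chi_mass_fe:
        Mass magnetic susceptibility of ferritin-bound iron, dimensionless
        SI per (ug/g wtw).  Literature values for brain iron span roughly
        0.8e-9 to 1.37e-9; the default is the ferritin upper bound.
    r2_nano:
        Nanoscale relaxivity of ferritin-bound iron at 7 T,
        s^-1 per (ug/g wtw).
    tissue_density:
        Brain tissue density, g/ml, used for section-to-wet-weight
        concentration conversion.
    shrinkage_factor:
        Dimensionless tissue volume shrinkage factor of dehydrated,
        paraffin-embedded sections relative to wet tissue.
    """

    gamma: float = 2.675e8
    B0: float = 7.0
    chi_mass_fe: float = 1.37e-9
    r2_nano: float = 0.0225
    tissue_density: float = 1.05
    shrinkage_factor: float = 0.7

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"PhysicalConstants.{f.name} must be strictly positive, "
                    f"got {value!r}"
                )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PhysicalConstants":
        """Load constants from a YAML or JSON file.

        Unknown keys are rejected; keys not present keep their defaults.
        """
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PhysicalConstants":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"Unknown constant name(s): {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        return cls(**data)

    def replace(self, **kwargs) -> "PhysicalConstants":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _check_nonnegative(values: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        bad = arr[arr < 0]
        raise ValueError(
            f"{name} must be nonnegative; found values in "
            f"[{bad.min():.6g}, {bad.max():.6g}]"
        )
    return arr


def mass_to_volume_susceptibility(
    c_fe: ArrayLike, constants: PhysicalConstants = PhysicalConstants()
) -> ArrayLike:
    """Convert an iron mass concentration to a volume susceptibility.

    chi = chi_mass_fe * c_fe, elementwise.  c_fe is in ug/g wtw, the
    result is dimensionless SI.
    """
    arr = _check_nonnegative(c_fe, "iron concentration")
    out = constants.chi_mass_fe * arr
    return float(out) if np.isscalar(c_fe) or arr.ndim == 0 else out


def volume_to_mass_concentration(
    chi: ArrayLike, constants: PhysicalConstants = PhysicalConstants()
) -> ArrayLike:
    """Inverse of :func:`mass_to_volume_susceptibility`."""
    arr = np.asarray(chi, dtype=float)
    out = arr / constants.chi_mass_fe
    return float(out) if np.isscalar(chi) or arr.ndim == 0 else out


def areal_to_mass_concentration(
    c_section: ArrayLike,
    constants: PhysicalConstants = PhysicalConstants(),
    *,
    tissue_density: float | None = None,
    shrinkage_factor: float | None = None,
) -> ArrayLike:
    """Convert a per-volume concentration in a dehydrated section to
    a wet-tissue mass concentration (ug/g wtw).

    Convention (documented, see package docs): the dehydrated section is
    a shrunk version of the original wet tissue, so the concentration per
    wet volume is ``c_section * shrinkage_factor`` and dividing by the
    tissue density (g/ml) yields the per-wet-mass concentration::

        c_wtw = c_section * shrinkage_factor / tissue_density

    Both factors can be overridden per call so the inverse convention is
    one configuration change away.
    """
    density = constants.tissue_density if tissue_density is None else tissue_density
    shrink = constants.shrinkage_factor if shrinkage_factor is None else shrinkage_factor
    if density <= 0 or shrink <= 0:
        raise ValueError(
            f"tissue density and shrinkage factor must be positive, got "
            f"density={density!r}, shrinkage={shrink!r}"
        )
    arr = _check_nonnegative(c_section, "section concentration")
    out = arr * shrink / density
    return float(out) if np.isscalar(c_section) or arr.ndim == 0 else out
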