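"""Calyx biovolume from geometric solid approximations.

A crinoid calyx (the rigid cup housing the viscera) is approximated by a
standard geometric solid measured from figured specimens; its volume in
mm^3 is the genus-level body-size proxy, analysed on a log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "SolidSpec",
    "SHAPES",
    "DimensionError",
    "UnsupportedShapeError",
    "solid_volume",
    "log_biovolume",
]


class DimensionError(ValueError):
    """A required dimension is missing or non-positive."""


class UnsupportedShapeError(ValueError):
    """The requested solid is not in the supported shape list."""


def _cylinder(d: Mapping[str, float]) -> float:
    return math.pi * d["r"] ** 2 * d["h"]


def _cone(d: Mapping[str, float]) -> float:
    return math.pi * d["r"] ** 2 * d["h"] / 3.0


def _frustum(d: Mapping[str, float]) -> float:
    # symmetric in (R, r); no ordering requirement
    return math.pi * d["h"] * (d["R"] ** 2 + d["R"] * d["r"] + d["r"] ** 2) / 3.0


def _sphere(d: Mapping[str, float]) -> float:
    return 4.0 / 3.0 * math.pi * d["r"] ** 3


def _hemisphere(d: Mapping[str, float]) -> float:
    return 2.0 / 3.0 * math.pi * d["r"] ** 3


def _ellipsoid(d: Mapping[str, float]) -> float:
    return 4.0 / 3.0 * math.pi * d["a"] * d["b"] * d["c"]


def _hemi_ellipsoid(d: Mapping[str, float]) -> float:
    return 2.0 / 3.0 * math.pi * d["a"] * d["b"] * d["c"]


#: shape name -> (required dimension names, closed-form volume)
SHAPES = {
    "cylinder": (("r", "h"), _cylinder),
    "cone": (("r", "h"), _cone),
    "frustum": (("r", "R", "h"), _frustum),
    "sphere": (("r",), _sphere),
    "hemisphere": (("r",), _hemisphere),
    "ellipsoid": (("a", "b", "c"), _ellipsoid),
    "hemi_ellipsoid": (("a", "b", "c"), _hemi_ellipsoid),
}


@dataclass(frozen=True)
class SolidSpec:
    """A geometric solid assigned to a calyx plus its measured dimensions (mm).

    Shapes cover the conical, bowl-shaped and globular calyx morphologies
    typical of Palaeozoic crinoids: cylinder, cone, frustum (truncated
    cone), sphere, hemisphere, ellipsoid and hemi-ellipsoid.
    """

    shape: str
    dims: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise UnsupportedShapeError(
                f"unsupported shape {self.shape!r}; expected one of "
                f"{sorted(SHAPES)}"
            )
        required, _ = SHAPES[self.shape]
        for name in required:
            if name not in self.dims:
                raise DimensionError(
                    f"shape {self.shape!r} requires dimension {name!r}"
                )
            value = self.dims[name]
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise DimensionError(
                    f"dimension {name!r} must be a finite positive length, got {value!r}"
                )


def solid_volume(spec: SolidSpec) -> float:
    """Closed-form volume (mm^3) of the solid described by *spec*."""
    _, formula = SHAPES[spec.shape]
    return formula(spec.dims)


def log_biovolume(v: float) -> float:
    """Base-10 logarithm of a biovolume in mm^3.

    The log base is a package convention (the downstream statistics are
    linear in the choice of base and the extinction/origination
    decomposition identity is base-free); all sizes in this package are
    log10 mm^3.
    """
    if not (math.isfinite(v) and v > 0):
        raise ValueError(f"biovolume must be a finite positive volume, got {v!r}")
    return math.log10(v)
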