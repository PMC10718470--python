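"""Closed-form area approximations of the lumbar spinal canal.

The bony canal at a lumbar level is characterised by two linear
measurements taken on axial CT: the interpedicular distance (IPD, the
maximum transverse distance between the medial aspects of the pedicles)
and the anteroposterior (AP) diameter.  Treating these as the axes of a
simple figure gives three closed-form area estimates:

* ellipse   — semi-axes IPD/2 and AP/2, area = pi * (IPD/2) * (AP/2)
* triangle  — base IPD, height AP,      area = IPD * AP / 2
* rectangle — sides IPD and AP,         area = IPD * AP

All three are scalar multiples of the product IPD * AP, with factors
pi/4, 1/2 and 1 respectively.  This collinearity has two consequences
used throughout the package: Pearson correlation against any reference
area is identical across the three shapes, and any linear combination of
them is again a scalar multiple of IPD * AP.

Units are fixed: lengths in mm, areas in mm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Level",
    "LEVELS",
    "Shape",
    "SHAPES",
    "LevelMeasurement",
    "ShapeEstimate",
    "approximate_area",
    "shape_factor",
]


class Level(str, Enum):
    """Lumbar vertebral level."""

    L1 = "L1"
    L2 = "L2"
    L3 = "L3"
    L4 = "L4"
    L5 = "L5"


#: Canonical cranial-to-caudal ordering.
LEVELS: tuple[Level, ...] = (Level.L1, Level.L2, Level.L3, Level.L4, Level.L5)


class Shape(str, Enum):
    """Geometric figure used to approximate the canal cross-section."""

    ELLIPSE = "ellipse"
    TRIANGLE = "triangle"
    RECTANGLE = "rectangle"


#: Canonical reporting order.
SHAPES: tuple[Shape, ...] = (Shape.ELLIPSE, Shape.TRIANGLE, Shape.RECTANGLE)

_FACTORS: dict[Shape, float] = {
    Shape.ELLIPSE: math.pi / 4.0,
    Shape.TRIANGLE: 0.5,
    Shape.RECTANGLE: 1.0,
}


def shape_factor(shape: Shape | str) -> float:
    """Dimensionless scale of a shape estimate relative to IPD * AP.

    Parameters
    ----------
    shape
        One of ``ellipse``, ``triangle``, ``rectangle`` (enum or string).

    Returns
    -------
    float
        pi/4 for the ellipse, 1/2 for the triangle, 1 for the rectangle.
    """
    try:
        shape = Shape(shape)
    except ValueError:
        raise ValueError(
            f"unknown shape {shape!r}; expected one of "
            f"{[s.value for s in SHAPES]}"
        ) from None
    return _FACTORS[shape]


def _validated_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if not np.all(arr > 0.0):
        bad = float(np.min(arr))
        raise ValueError(f"{name} must be strictly positive (smallest value: {bad})")
    return arr


def approximate_area(ipd, ap, shape: Shape | str):
    """Approximate the canal area from IPD and AP diameter.

    Accepts scalars or broadcastable arrays of lengths in mm and returns
    the area(s) in mm^2 for the requested shape.  Both lengths must be
    strictly positive.
    """
    factor = shape_factor(shape)
    ipd_arr = _validated_positive("ipd", ipd)
    ap_arr = _validated_positive("ap", ap)
    area = factor * ipd_arr * ap_arr
    if np.isscalar(ipd) and np.isscalar(ap):
        return float(area)
    return area


@dataclass(frozen=True)
class LevelMeasurement:
    """One patient at one vertebral level.

    ``manual_area`` is the canal area traced on the image (the reference
    measurement); it may be ``None`` for approximation-only records.
    """

    patient_id: str
    level: Level
    ipd: float
    ap: float
    manual_area: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", Level(self.level))
        for name in ("ipd", "ap"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(
                    f"{name} must be strictly positive (got {value!r})"
                )
        if self.manual_area is not None and not (
            np.isfinite(self.manual_area) and self.manual_area > 0
        ):
            raise ValueError(
                f"manual_area must be strictly positive (got {self.manual_area!r})"
            )

    @property
    def product(self) -> float:
        """IPD * AP in mm^2 — the quantity all shape estimates rescale."""
        return self.ipd * self.ap

    def estimate(self, shape: Shape | str) -> "ShapeEstimate":
        return ShapeEstimate.from_measurement(self, shape)


@dataclass(frozen=True)
class ShapeEstimate:
    """An approximated area together with its scale factor."""

    shape: Shape
    area: float
    factor: float = field(default=0.0)

    @classmethod
    def from_measurement(
        cls, measurement: LevelMeasurement, shape: Shape | str
    ) -> "ShapeEstimate":
        shape = Shape(shape)
        return cls(
            shape=shape,
            area=approximate_area(measurement.ipd, measurement.ap, shape),
            factor=shape_factor(shape),
        )
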