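"""Single-islet geometry: volumes, equivalent diameter, circularity, axis ratios.

Isolated islets of Langerhans are conventionally treated as spheres, but
measured islets — especially large ones — are closer to triaxial ellipsoids,
with typical axis ratios b/a ≈ 0.82 and c/a ≈ 0.70.  This module provides the
geometric primitives that the IEQ and cell-number estimators build on: sphere
and ellipsoid volumes, the equal-area equivalent diameter used by digital
image analysis, and 2-D circularity (4πA/P²) of projected outlines.

All lengths are in micrometres (μm), areas in μm², volumes in μm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class DiameterConvention(str, Enum):
    """How a single representative diameter is derived from measured axes.

    Practice varies: some laboratories record the mean of two to four
    measured diameters, some the major axis, some the diameter of the
    equal-volume sphere.  ``MEAN_AXES`` is the default here.
    """

    MEAN_AXES = "mean_axes"
    MAJOR_AXIS = "major_axis"
    EQUAL_VOLUME = "equal_volume"


@dataclass(frozen=True)
class IsletShape:
    """Triaxial ellipsoid axes of one islet, full lengths in μm.

    Invariant: ``a >= b >= c > 0``.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.c > 0):
            raise ValueError(f"axes must be positive, got c={self.c}")
        if not (self.a >= self.b >= self.c):
            raise ValueError(
                f"axis ordering violated: require a >= b >= c, got "
                f"a={self.a}, b={self.b}, c={self.c}"
            )

    @property
    def ba_ratio(self) -> float:
        return self.b / self.a

    @property
    def ca_ratio(self) -> float:
        return self.c / self.a


@dataclass(frozen=True)
class IsletRecord:
    """One measured islet: representative diameter plus optional extras."""

    id: str
    diameter: float
    shape: Optional[IsletShape] = None
    area: Optional[float] = None
    perimeter: Optional[float] = None
    cell_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"islet {self.id!r}: diameter must be > 0, got {self.diameter}")
        if self.area is not None and not self.area > 0:
            raise ValueError(f"islet {self.id!r}: area must be > 0, got {self.area}")
        if self.perimeter is not None and not self.perimeter > 0:
            raise ValueError(f"islet {self.id!r}: perimeter must be > 0, got {self.perimeter}")
        if self.cell_count is not None and self.cell_count < 0:
            raise ValueError(f"islet {self.id!r}: cell_count must be >= 0, got {self.cell_count}")

    @property
    def circularity(self) -> Optional[float]:
        if self.area is None or self.perimeter is None:
            return None
        return circularity(self.area, self.perimeter)


@dataclass
class IsletBatch:
    """An ordered collection of islet records from one preparation."""

    records: list[IsletRecord] = field(default_factory=list)
    species: str = "unspecified"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def diameters(self) -> list[float]:
        return [r.diameter for r in self.records]

    def require_nonempty(self, op: str) -> None:
        if not self.records:
            raise ValueError(f"{op}: batch is empty")


def sphere_volume(d: float) -> float:
    """Volume of a sphere of diameter ``d`` μm: π·d³/6."""
    if not d > 0:
        raise ValueError(f"diameter must be > 0, got {d}")
    return math.pi * d**3 / 6.0


def ellipsoid_volume(shape: IsletShape) -> float:
    """Volume of a triaxial ellipsoid with full axes a, b, c: π·a·b·c/6."""
    return math.pi * shape.a * shape.b * shape.c / 6.0


def circularity(area: float, perimeter: float) -> float:
    """2-D circularity 4π·A/P² of a projected outline, capped at 1.0.

    Equals 1 for a perfect circle and decreases with boundary irregularity.
    The cap absorbs small overshoots from pixel-discretised perimeters.
    """
    if not area > 0:
        raise ValueError(f"area must be > 0, got {area}")
    if not perimeter > 0:
        raise ValueError(f"perimeter must be > 0, got {perimeter}")
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the same area: 2·sqrt(A/π)."""
    if not area > 0:
        raise ValueError(f"area must be > 0, got {area}")
    return 2.0 * math.sqrt(area / math.pi)


def representative_diameter(
    shape: IsletShape,
    convention: DiameterConvention = DiameterConvention.MEAN_AXES,
) -> float:
    """Collapse measured axes to a single diameter under the given convention."""
    if convention is DiameterConvention.MEAN_AXES:
        return (shape.a + shape.b + shape.c) / 3.0
    if convention is DiameterConvention.MAJOR_AXIS:
        return shape.a
    if convention is DiameterConvention.EQUAL_VOLUME:
        return (shape.a * shape.b * shape.c) ** (1.0 / 3.0)
    raise ValueError(f"unknown diameter convention: {convention}")


def batch_from_diameters(
    diameters: Sequence[float], species: str = "unspecified", prefix: str = "islet"
) -> IsletBatch:
    """Convenience constructor for a batch holding only diameters."""
    records = [
        IsletRecord(id=f"{prefix}{i}", diameter=float(d)) for i, d in enumerate(diameters)
    ]
    return IsletBatch(records=records, species=species)
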