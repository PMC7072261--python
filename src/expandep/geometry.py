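"""Parametric geometry of deployable expandable needle electrodes.

An expandable electrode packs four peripheral needles — optionally plus a
central one — into a single shaft of a few millimetres diameter.  The
peripheral needles leave the shaft head on a square of half-diagonal
``i/2`` (the base spacing) and diverge from the shaft axis by a fixed
angle ``alpha``; advancing them by an exposure ``e`` therefore opens the
array.  The clinically relevant quantities are the inter-needle gaps over
which pulse voltages are applied:

* semi-diagonal ``d/2`` — peripheral needle to central needle,
* diagonal ``d``       — two opposite peripheral needles,
* side                 — two consecutive peripheral needles.

All three derive from the centre-to-peripheral-axis distance

    r(e) = (e + h_t) * tan(alpha) + i/2

where ``h_t`` is the head offset of the divergence origin behind the
shaft tip.  The usable gap subtracts one full needle diameter from the
centre-to-centre distance (gaps are the inner free space the field must
bridge):

    d/2  = r - D,    d = 2 r - D,    side = sqrt(2) r - D

with ``D`` the needle diameter.  Units are millimetres and degrees
throughout; reported gaps are rounded half-up to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, UnsupportedConfigurationError

__all__ = [
    "ElectrodeSpec",
    "DeploymentState",
    "GapSet",
    "Needle",
    "NeedleLayout",
    "round_half_up",
    "radial_offset",
    "gap_semi_diagonal",
    "gap_diagonal",
    "gap_side",
    "gaps",
    "needle_positions",
]

MM_PER_CM = 10.0

#: Azimuths of the four peripheral needles (degrees, about the shaft axis).
PERIPHERAL_AZIMUTHS_DEG = (45.0, 135.0, 225.0, 315.0)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero-half upward (not banker's rounding).

    Reported gaps and voltages use this rule; it reproduces the majority of
    the reference values the defaults were taken from.
    """
    factor = 10.0 ** decimals
    return math.floor(value * factor + 0.5) / factor


@dataclass(frozen=True)
class ElectrodeSpec:
    """Fixed mechanical parameters of one electrode variant.

    Lengths in the units named by each field; ``divergence_deg`` is the
    angle between each peripheral needle and the shaft axis.
    """

    n_needles: int
    divergence_deg: float
    shaft_diameter_mm: float = 5.0
    shaft_length_cm: float = 20.0
    max_deployment_mm: float = 40.0
    active_length_mm: float = 20.0
    needle_diameter_mm: float = 0.45
    head_offset_mm: float = 3.0
    base_spacing_mm: float = 3.26
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_needles not in (4, 5):
            raise DomainError(f"n_needles must be 4 or 5, got {self.n_needles}")
        if not 0.0 <= self.divergence_deg < 90.0:
            raise DomainError(
                f"divergence_deg must lie in [0, 90), got {self.divergence_deg}"
            )
        for attr in (
            "shaft_diameter_mm",
            "shaft_length_cm",
            "max_deployment_mm",
            "active_length_mm",
            "needle_diameter_mm",
            "head_offset_mm",
            "base_spacing_mm",
        ):
            if getattr(self, attr) <= 0:
                raise DomainError(f"{attr} must be positive, got {getattr(self, attr)}")
        if self.active_length_mm > self.max_deployment_mm:
            raise DomainError(
                "active_length_mm cannot exceed max_deployment_mm "
                f"({self.active_length_mm} > {self.max_deployment_mm})"
            )

    @property
    def has_central_needle(self) -> bool:
        return self.n_needles == 5

    @property
    def divergence_rad(self) -> float:
        return math.radians(self.divergence_deg)


@dataclass(frozen=True)
class DeploymentState:
    """One step of a segmented treatment: needle exposure beyond the shaft tip."""

    exposure_mm: float
    step_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.exposure_mm <= 0:
            raise DomainError(f"exposure_mm must be positive, got {self.exposure_mm}")

    @property
    def label(self) -> str:
        return self.step_label if self.step_label is not None else f"{self.exposure_mm:g}mm"


@dataclass(frozen=True)
class GapSet:
    """Inter-needle gaps (mm) of one electrode variant at one exposure."""

    side_mm: float
    diagonal_mm: float
    semi_diagonal_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.side_mm <= 0 or self.diagonal_mm <= 0:
            raise DomainError("gaps must be positive")
        if self.semi_diagonal_mm is not None and self.semi_diagonal_mm <= 0:
            raise DomainError("gaps must be positive")
        if not self.side_mm < self.diagonal_mm:
            raise DomainError("side gap must be smaller than the diagonal gap")


def _check_exposure(spec: ElectrodeSpec, exposure_mm: float) -> None:
    if not 0 < exposure_mm <= spec.max_deployment_mm:
        raise DomainError(
            f"exposure {exposure_mm} mm outside (0, {spec.max_deployment_mm}] mm "
            "allowed by the electrode specification"
        )


def radial_offset(spec: ElectrodeSpec, exposure_mm: float) -> float:
    """Centre-to-peripheral-needle-axis distance r(e) in mm.

    r = (e + h_t) tan(alpha) + i/2; reduces to i/2 for parallel needles.
    This is the geometric centre distance before the needle-diameter
    correction applied by the gap functions.
    """
    _check_exposure(spec, exposure_mm)
    return (exposure_mm + spec.head_offset_mm) * math.tan(spec.divergence_rad) + (
        spec.base_spacing_mm / 2.0
    )


def gap_semi_diagonal(spec: ElectrodeSpec, exposure_mm: float) -> float:
    """Peripheral-to-central gap d/2 = r(e) - needle diameter (mm).

    Only defined for the five-needle variant.
    """
    if not spec.has_central_needle:
        raise UnsupportedConfigurationError(
            "semi-diagonal gap requires a central needle (five-needle variant)"
        )
    return radial_offset(spec, exposure_mm) - spec.needle_diameter_mm


def gap_diagonal(spec: ElectrodeSpec, exposure_mm: float) -> float:
    """Opposite-peripheral gap d = 2 r(e) - needle diameter (mm)."""
    return 2.0 * radial_offset(spec, exposure_mm) - spec.needle_diameter_mm


def gap_side(spec: ElectrodeSpec, exposure_mm: float) -> float:
    """Consecutive-peripheral gap side = sqrt(2) r(e) - needle diameter (mm)."""
    return math.sqrt(2.0) * radial_offset(spec, exposure_mm) - spec.needle_diameter_mm


def gaps(spec: ElectrodeSpec, exposure_mm: float) -> GapSet:
    """All gaps of ``spec`` at one exposure (semi-diagonal only with 5 needles)."""
    return GapSet(
        side_mm=gap_side(spec, exposure_mm),
        diagonal_mm=gap_diagonal(spec, exposure_mm),
        semi_diagonal_mm=(
            gap_semi_diagonal(spec, exposure_mm) if spec.has_central_needle else None
        ),
    )


@dataclass(frozen=True)
class Needle:
    """One needle's tip and conductive (active) segment in the shaft frame.

    Coordinates in mm; shaft axis is +z, the shaft tip plane is z = 0.
    """

    tip: np.ndarray
    active_start: np.ndarray
    active_end: np.ndarray
    central: bool

    @property
    def active_length_mm(self) -> float:
        return float(np.linalg.norm(self.active_end - self.active_start))


@dataclass(frozen=True)
class NeedleLayout:
    """Geometric realization of a deployed electrode.

    ``needles[0]`` is the central needle when present; peripherals follow in
    azimuth order 45, 135, 225, 315 degrees.
    """

    spec: ElectrodeSpec
    exposure_mm: float
    needles: tuple[Needle, ...] = field(default_factory=tuple)

    @property
    def peripheral_indices(self) -> tuple[int, ...]:
        first = 1 if self.spec.has_central_needle else 0
        return tuple(range(first, len(self.needles)))

    def tip(self, index: int) -> np.ndarray:
        return self.needles[index].tip

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners in mm enclosing every active segment."""
        pts = np.array(
            [p for n in self.needles for p in (n.active_start, n.active_end)]
        )
        return pts.min(axis=0), pts.max(axis=0)


def needle_positions(spec: ElectrodeSpec, exposure_mm: float) -> NeedleLayout:
    """3D needle layout at exposure ``e``.

    Peripheral needles originate ``h_t`` behind the shaft tip on a circle
    of radius ``i/2`` and run at the divergence angle; tips sit at axial
    depth ``e`` and radius r(e), so pairwise tip distances minus one needle
    diameter reproduce the gap functions exactly.  The conductive segment
    is the distal ``active_length`` of the needle, truncated to the exposed
    path length (e + h_t)/cos(alpha) - h_t when a step exposes less steel
    than the insulation window.
    """
    _check_exposure(spec, exposure_mm)
    alpha = spec.divergence_rad
    e, ht, half_i = exposure_mm, spec.head_offset_mm, spec.base_spacing_mm / 2.0
    needles: list[Needle] = []

    if spec.has_central_needle:
        tip = np.array([0.0, 0.0, e])
        length = min(spec.active_length_mm, e)
        start = np.array([0.0, 0.0, e - length])
        needles.append(Needle(tip=tip, active_start=start, active_end=tip, central=True))

    exposed_path = (e + ht) / math.cos(alpha) - ht
    active = min(spec.active_length_mm, exposed_path)
    for az in PERIPHERAL_AZIMUTHS_DEG:
        c, s = math.cos(math.radians(az)), math.sin(math.radians(az))
        direction = np.array(
            [math.sin(alpha) * c, math.sin(alpha) * s, math.cos(alpha)]
        )
        origin = np.array([half_i * c, half_i * s, -ht])
        tip = origin + ((e + ht) / math.cos(alpha)) * direction
        start = tip - active * direction
        needles.append(Needle(tip=tip, active_start=start, active_end=tip, central=False))

    return NeedleLayout(spec=spec, exposure_mm=exposure_mm, needles=tuple(needles))


def table_rows(
    spec: ElectrodeSpec, exposures_mm: Sequence[float], decimals: int = 2
) -> list[dict]:
    """Rounded gap rows for reporting, one per exposure."""
    rows = []
    for e in exposures_mm:
        g = gaps(spec, e)
        rows.append(
            {
                "exposure_mm": e,
                "side_mm": round_half_up(g.side_mm, decimals),
                "diagonal_mm": round_half_up(g.diagonal_mm, decimals),
                "semi_diagonal_mm": (
                    None
                    if g.semi_diagonal_mm is None
                    else round_half_up(g.semi_diagonal_mm, decimals)
                ),
            }
        )
    return rows
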