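"""Seeded synthetic inputs: ablation-mask and field phantoms with oracles.

Every stage of the pipeline can be exercised without imaging data:

* ellipsoidal segmentation masks with known diameters, spacing and an
  optional seeded boundary-noise model stand in for manually drawn CT
  ablation areas;
* field phantoms (parallel plate, concentric spherical shells, analytic
  radial field) supply solver-ready scenarios together with closed-form
  evaluators, so solver error can be measured rather than assumed.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DomainError, GeometryError
from .solver import FieldGrid, V_PER_CM_PER_V_PER_MM
from .volumetrics import SegmentationVolume

__all__ = [
    "PhantomSpec",
    "FieldPhantom",
    "make_ellipsoid_mask",
    "make_field_phantom",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom request; ``make`` dispatches on ``kind``."""

    kind: str  # ellipsoid_mask | parallel_plate | concentric_shells | radial_field
    params: dict = field(default_factory=dict)
    spacing_mm: float = 0.5
    noise_voxels: float = 0.0
    seed: int = 0

    def make(self):
        if self.kind == "ellipsoid_mask":
            return make_ellipsoid_mask(
                spacing_mm=self.spacing_mm,
                noise_voxels=self.noise_voxels,
                seed=self.seed,
                **self.params,
            )
        if self.kind in ("parallel_plate", "concentric_shells", "radial_field"):
            return make_field_phantom(self.kind, spacing_mm=self.spacing_mm, **self.params)
        raise ConfigurationError(f"unknown phantom kind {self.kind!r}")


def make_ellipsoid_mask(
    diameters_cm: Sequence[float] = (2.05, 1.53, 1.77),
    spacing_mm: float = 0.2,
    margin_mm: float = 2.0,
    grid_shape: Optional[tuple[int, int, int]] = None,
    noise_voxels: float = 0.0,
    seed: int = 0,
) -> SegmentationVolume:
    """Binary ellipsoid mask with isotropic spacing (PS = ST = SBS).

    A voxel is included iff its centre satisfies the ellipsoid
    inequality, keeping the pixel count an exact reproducible integer.
    ``diameters_cm`` are the (horizontal, vertical, through-slice) axes.
    ``noise_voxels`` is the expected number of seeded voxel flips,
    restricted to the one-voxel boundary layer so the overall shape and
    topology survive.
    """
    if spacing_mm <= 0:
        raise DomainError("spacing must be positive")
    d = np.asarray(diameters_cm, dtype=float)
    if d.shape != (3,) or (d <= 0).any():
        raise DomainError("need three positive diameters (cm)")
    radii_mm = d * 10.0 / 2.0  # (x=col, y=row, z=slice)

    if grid_shape is None:
        extents = 2 * radii_mm + 2 * margin_mm
        # shape in (slice, row, col) order
        grid_shape = tuple(int(np.ceil(e / spacing_mm)) + 1 for e in extents[::-1])
    nz, ny, nx = grid_shape
    axes_mm = [spacing_mm * (np.arange(n) - (n - 1) / 2.0) for n in (nz, ny, nx)]
    if any(
        2 * r > (n - 1) * spacing_mm
        for r, n in zip(radii_mm[::-1], (nz, ny, nx))
    ):
        raise GeometryError("ellipsoid does not fit inside the requested grid")
    zz = (axes_mm[0] / radii_mm[2])[:, None, None]
    yy = (axes_mm[1] / radii_mm[1])[None, :, None]
    xx = (axes_mm[2] / radii_mm[0])[None, None, :]
    mask = zz**2 + yy**2 + xx**2 <= 1.0

    if noise_voxels > 0:
        rng = np.random.default_rng(seed)
        inner = mask & ~ndimage.binary_erosion(mask)
        outer = ndimage.binary_dilation(mask) & ~mask
        layer = np.flatnonzero(inner | outer)
        if layer.size:
            p = min(1.0, noise_voxels / layer.size)
            flips = layer[rng.random(layer.size) < p]
            flat = mask.ravel()
            flat[flips] = ~flat[flips]
            mask = flat.reshape(mask.shape)

    return SegmentationVolume(
        mask=mask,
        ps_o_mm=spacing_mm,
        ps_v_mm=spacing_mm,
        st_mm=spacing_mm,
        sbs_mm=spacing_mm,
    )


@dataclass(frozen=True)
class FieldPhantom:
    """Solver-ready scenario plus closed-form evaluators.

    ``dirichlet`` is the boundary in the solver's (node indices, values)
    form; ``exact_potential``/``exact_field`` evaluate the closed form on
    the grid's nodes (None where the phantom defines the field directly,
    in which case ``field_V_per_cm`` holds it).  ``measure_mask`` marks
    the nodes on which solver error should be measured.
    """

    kind: str
    grid: FieldGrid
    sigma_S_per_m: np.ndarray
    dirichlet: tuple
    exact_potential: Optional[Callable[[], np.ndarray]]
    exact_field: Optional[Callable[[], np.ndarray]]
    measure_mask: Optional[np.ndarray] = None
    field_V_per_cm: Optional[np.ndarray] = None
    analytic: dict = field(default_factory=dict)


def _node_radii(grid: FieldGrid, centre: np.ndarray) -> np.ndarray:
    ax, ay, az = grid.axes()
    dx = (ax - centre[0])[:, None, None]
    dy = (ay - centre[1])[None, :, None]
    dz = (az - centre[2])[None, None, :]
    return np.sqrt(dx**2 + dy**2 + dz**2)


def make_field_phantom(
    kind: str,
    spacing_mm: float = 0.5,
    voltage_V: float = 100.0,
    length_cm: float = 1.0,
    inner_radius_mm: float = 2.0,
    outer_radius_mm: float = 10.0,
    boundary_values: str = "exact",
    strength_V_mm2_per_cm: float = 1e4,
    sigma_S_per_m: float = 0.1,
) -> FieldPhantom:
    """Build one of the closed-form validation scenarios.

    parallel_plate
        Two opposite Dirichlet faces (V and 0) a distance ``length_cm``
        apart with uniform conductivity; phi is linear and |E| = V/L.
    concentric_shells
        Spherical conductor problem, phi(r) = V a (b - r) / (r (b - a)).
        With ``boundary_values='exact'`` the fixed sets are two ~2h-thick
        spherical bands carrying the closed form at each node's radius
        (the extended 1/r form is harmonic away from the origin), so the
        comparison isolates discrete-operator error from the staircase
        bias of a voxelized electrode; 'constant' realizes solid
        electrodes at V and 0 instead.
    radial_field
        Directly defined magnitude |E| = c / r^2 (V/cm, r in mm) whose
        iso-field surface at threshold t is a sphere of radius
        sqrt(c / t) — an analytic oracle for coverage volumes.
    """
    if spacing_mm <= 0:
        raise DomainError("spacing must be positive")
    h = spacing_mm

    if kind == "parallel_plate":
        length_mm = length_cm * 10.0
        n_axis = int(round(length_mm / h)) + 1
        grid = FieldGrid(
            origin=(0.0, 0.0, 0.0), spacing=(h, h, h), shape=(n_axis, n_axis, n_axis)
        )
        idx = np.arange(grid.n_nodes).reshape(grid.shape)
        lo_face = idx[0].ravel()
        hi_face = idx[-1].ravel()
        ax = grid.axes()[0]
        phi_exact = np.broadcast_to(
            (voltage_V * (1.0 - ax / length_mm))[:, None, None], grid.shape
        )
        interior = np.zeros(grid.shape, dtype=bool)
        interior[1:-1, :, :] = True
        return FieldPhantom(
            kind=kind,
            grid=grid,
            sigma_S_per_m=np.full(grid.shape, sigma_S_per_m),
            dirichlet=((lo_face, voltage_V), (hi_face, 0.0)),
            exact_potential=lambda: np.array(phi_exact),
            exact_field=lambda: np.full(
                grid.shape, voltage_V / length_mm * V_PER_CM_PER_V_PER_MM
            ),
            measure_mask=interior,
            analytic={"E_V_per_cm": voltage_V / length_mm * V_PER_CM_PER_V_PER_MM},
        )

    if kind == "concentric_shells":
        a, b = float(inner_radius_mm), float(outer_radius_mm)
        if not 0 < a < b:
            raise DomainError("need 0 < inner radius < outer radius")
        half = b + 2 * h
        n_axis = 2 * int(np.ceil(half / h)) + 1
        grid = FieldGrid(
            origin=(-half, -half, -half), spacing=(h, h, h), shape=(n_axis,) * 3
        )
        centre = np.zeros(3)
        r = _node_radii(grid, centre)
        with np.errstate(divide="ignore"):
            phi_all = voltage_V * a * (b - r) / (np.where(r == 0, np.inf, r) * (b - a))
        e_all = np.where(
            r == 0,
            0.0,
            voltage_V * a * b / (np.maximum(r, 1e-12) ** 2 * (b - a)),
        ) * V_PER_CM_PER_V_PER_MM
        if boundary_values == "exact":
            inner_set = np.flatnonzero((r >= a - h) & (r <= a + h))
            outer_set = np.flatnonzero((r >= b - h) & (r <= b + h))
            dirichlet = (
                (inner_set, phi_all.ravel()[inner_set]),
                (outer_set, phi_all.ravel()[outer_set]),
            )
            measure = (r > a + h) & (r < b - h)
        elif boundary_values == "constant":
            inner_set = np.flatnonzero(r <= a)
            outer_set = np.flatnonzero(r >= b)
            dirichlet = ((inner_set, voltage_V), (outer_set, 0.0))
            measure = (r > a + h) & (r < b - h)
        else:
            raise ConfigurationError(
                f"boundary_values must be 'exact' or 'constant', got {boundary_values!r}"
            )
        return FieldPhantom(
            kind=kind,
            grid=grid,
            sigma_S_per_m=np.full(grid.shape, sigma_S_per_m),
            dirichlet=dirichlet,
            exact_potential=lambda: np.array(phi_all),
            exact_field=lambda: np.array(e_all),
            measure_mask=measure,
            analytic={"inner_radius_mm": a, "outer_radius_mm": b},
        )

    if kind == "radial_field":
        c = float(strength_V_mm2_per_cm)  # |E| = c / r^2, V/cm with r in mm
        half = outer_radius_mm
        n_axis = 2 * int(np.ceil(half / h)) + 1
        grid = FieldGrid(
            origin=(-half, -half, -half), spacing=(h, h, h), shape=(n_axis,) * 3
        )
        r = _node_radii(grid, np.zeros(3))
        emag = c / np.maximum(r, h / 2.0) ** 2
        return FieldPhantom(
            kind=kind,
            grid=grid,
            sigma_S_per_m=np.full(grid.shape, sigma_S_per_m),
            dirichlet=(),
            exact_potential=None,
            exact_field=None,
            field_V_per_cm=emag,
            analytic={
                "iso_radius_mm": lambda threshold: float(np.sqrt(c / threshold)),
                "iso_volume_cm3": lambda threshold: (4.0 / 3.0)
                * np.pi
                * float(np.sqrt(c / threshold)) ** 3
                / 1000.0,
            },
        )

    raise ConfigurationError(f"unknown phantom kind {kind!r}")
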