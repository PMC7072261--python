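"""Quasi-static electric-field simulation with field-dependent conductivity.

The tissue is modelled as a homogeneous, isotropic conductor whose
conductivity rises irreversibly with the maximum field magnitude it has
experienced (electroporation opens membranes and raises bulk
conductivity, here from 0.1 to 0.3 S/m).  For each activated needle pair
the stationary current problem

    div( sigma(|E|_max) grad(phi) ) = 0

is solved with Dirichlet values on the conductive needle segments and an
insulating outer boundary, iterating solve -> |E| -> sigma to a fixed
point because sigma depends on the field it shapes.  Pulses of a pair
are sequential in time, so pairs are solved independently and coupled
only through the running per-node maximum field magnitude; tissue where
that maximum exceeds a success threshold (400 V/cm by default) counts as
electroporated.  Deployment steps of a segmented treatment accumulate
coverage as the union of their per-step covered regions.

Discretization: node-centred finite volumes on a regular grid with a
7-point stencil and harmonic-mean face conductivities; conjugate
gradients with Jacobi preconditioning for the linear solves.  Internal
units are mm, V and S/m; field magnitudes are exposed in V/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates
from scipy.sparse.linalg import cg

from .errors import (
    ConfigurationError,
    DomainError,
    GeometryError,
    SolverConvergenceError,
)
from .geometry import NeedleLayout
from .planning import PulsePlan

__all__ = [
    "ConductivityModel",
    "FieldGrid",
    "FieldState",
    "CoverageResult",
    "TipFieldReport",
    "rasterize_needles",
    "solve_potential",
    "field_magnitude",
    "update_conductivity",
    "simulate_deployment",
    "coverage_volume",
    "union_coverage",
    "verify_tip_field",
    "plane_current",
]

V_PER_CM_PER_V_PER_MM = 10.0


@dataclass(frozen=True)
class ConductivityModel:
    """Monotone map from experienced field magnitude to conductivity.

    The transition runs between ``threshold_low`` (onset, defaulting to
    the 400 V/cm electroporation-success threshold) and
    ``threshold_high`` (saturation); output is bounded by
    [sigma_low, sigma_high].  The smoothstep shape is C1 and symmetric,
    so the midpoint of the transition maps to the mid conductivity.
    """

    sigma_low_S_per_m: float = 0.1
    sigma_high_S_per_m: float = 0.3
    threshold_low_V_per_cm: float = 400.0
    threshold_high_V_per_cm: float = 800.0
    shape: str = "smoothstep"

    def __post_init__(self) -> None:
        if not 0 < self.sigma_low_S_per_m <= self.sigma_high_S_per_m:
            raise DomainError("need 0 < sigma_low <= sigma_high")
        if not self.threshold_low_V_per_cm < self.threshold_high_V_per_cm:
            raise DomainError("need threshold_low < threshold_high")
        if self.shape not in ("smoothstep", "sigmoid"):
            raise DomainError(f"unknown shape {self.shape!r}")

    def __call__(self, max_field_V_per_cm: np.ndarray) -> np.ndarray:
        e = np.asarray(max_field_V_per_cm, dtype=float)
        lo, hi = self.threshold_low_V_per_cm, self.threshold_high_V_per_cm
        t = np.clip((e - lo) / (hi - lo), 0.0, 1.0)
        if self.shape == "smoothstep":
            s = t * t * (3.0 - 2.0 * t)
        else:  # logistic in the transition band, clipped outside it
            s = 1.0 / (1.0 + np.exp(-10.0 * (t - 0.5)))
        return self.sigma_low_S_per_m + (
            self.sigma_high_S_per_m - self.sigma_low_S_per_m
        ) * s


def update_conductivity(
    model: ConductivityModel, max_field_V_per_cm: np.ndarray
) -> np.ndarray:
    """Conductivity grid from the running maximum field magnitude."""
    return model(max_field_V_per_cm)


@dataclass(frozen=True)
class FieldGrid:
    """Regular 3D node lattice (mm): origin, per-axis spacing, node counts."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.spacing):
            raise DomainError("grid spacing must be positive")
        if any(n < 2 for n in self.shape):
            raise DomainError("grid needs at least 2 nodes per axis")

    @classmethod
    def from_bounds(
        cls,
        lo: Sequence[float],
        hi: Sequence[float],
        spacing: float | Sequence[float],
    ) -> "FieldGrid":
        h = (
            (float(spacing),) * 3
            if np.isscalar(spacing)
            else tuple(float(s) for s in spacing)
        )
        shape = tuple(
            int(np.ceil((b - a) / s)) + 1 for a, b, s in zip(lo, hi, h)
        )
        return cls(origin=tuple(float(a) for a in lo), spacing=h, shape=shape)

    @classmethod
    def for_layouts(
        cls,
        layouts: "NeedleLayout | Iterable[NeedleLayout]",
        spacing: float = 0.5,
        margin_mm: float = 20.0,
    ) -> "FieldGrid":
        """Grid enclosing every active segment with a uniform margin."""
        if isinstance(layouts, NeedleLayout):
            layouts = [layouts]
        boxes = [lay.bounding_box() for lay in layouts]
        lo = np.min([b[0] for b in boxes], axis=0) - margin_mm
        hi = np.max([b[1] for b in boxes], axis=0) + margin_mm
        return cls.from_bounds(lo, hi, spacing)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def node_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )

    def index_coords(self, points: np.ndarray) -> np.ndarray:
        """Fractional node indices of Cartesian points (mm)."""
        return (np.asarray(points, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )


def rasterize_needles(
    layout: NeedleLayout, grid: FieldGrid, indices: Optional[Sequence[int]] = None
) -> dict[int, np.ndarray]:
    """Map each needle's conductive segment to grid nodes.

    Segments are sampled densely and snapped to the nearest node, which
    dilates the (sub-spacing) needle radius to one node; the insulated
    proximal part contributes nothing.  Every mapped node must lie in the
    grid interior.  Returns flat node indices per needle index.
    """
    hmin = min(grid.spacing)
    shape = np.asarray(grid.shape)
    out: dict[int, np.ndarray] = {}
    which = range(len(layout.needles)) if indices is None else indices
    for k in which:
        needle = layout.needles[k]
        seg = needle.active_end - needle.active_start
        length = float(np.linalg.norm(seg))
        if length <= 0:
            raise GeometryError(f"needle {k} has a zero-length active segment")
        n_samples = max(2, int(np.ceil(length / (hmin / 4.0))) + 1)
        t = np.linspace(0.0, 1.0, n_samples)[:, None]
        pts = needle.active_start[None, :] + t * seg[None, :]
        idx = np.rint(grid.index_coords(pts)).astype(np.int64)
        if (idx < 1).any() or (idx >= shape - 1).any():
            raise GeometryError(
                f"active segment of needle {k} leaves the grid interior; "
                "enlarge the domain margin"
            )
        flat = np.unique(
            np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), grid.shape)
        )
        out[k] = flat
    return out


def _face_system(sigma: np.ndarray, spacing: Sequence[float]):
    """Finite-volume conductance graph: 7-point stencil, harmonic faces."""
    nx, ny, nz = sigma.shape
    n = sigma.size
    s = sigma.ravel()
    idx = np.arange(n, dtype=np.int64).reshape(sigma.shape)
    hx, hy, hz = spacing
    geo = (hy * hz / hx, hx * hz / hy, hx * hy / hz)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        i = idx[tuple(sl_a)].ravel()
        j = idx[tuple(sl_b)].ravel()
        si, sj = s[i], s[j]
        g = geo[axis] * 2.0 * si * sj / (si + sj)  # S*mm
        rows.append(i)
        cols.append(j)
        vals.append(-g)
        rows.append(j)
        cols.append(i)
        vals.append(-g)
        diag += np.bincount(i, weights=g, minlength=n)
        diag += np.bincount(j, weights=g, minlength=n)
    rows.append(np.arange(n, dtype=np.int64))
    cols.append(np.arange(n, dtype=np.int64))
    vals.append(diag)
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def solve_potential(
    sigma: np.ndarray,
    spacing: Sequence[float],
    dirichlet: Sequence[tuple[np.ndarray, "float | np.ndarray"]],
    rtol: float = 1e-8,
    maxiter: int = 20000,
) -> np.ndarray:
    """Solve div(sigma grad phi) = 0 on the grid, insulating outer boundary.

    ``dirichlet`` lists (flat node indices, value) per electrode; values
    may be scalars or per-node arrays.  Raises ConfigurationError when the
    boundary carries fewer than two distinct potentials (no current can
    be defined) and SolverConvergenceError when CG stalls.
    """
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any():
        raise DomainError("conductivity must be positive everywhere")
    n = sigma.size
    fixed_value = np.zeros(n)
    fixed_mask = np.zeros(n, dtype=bool)
    for nodes, value in dirichlet:
        nodes = np.asarray(nodes, dtype=np.int64)
        vals = np.broadcast_to(np.asarray(value, dtype=float), nodes.shape)
        clash = fixed_mask[nodes] & (fixed_value[nodes] != vals)
        if clash.any():
            raise ConfigurationError(
                "conflicting Dirichlet assignments: electrodes overlap on the grid"
            )
        fixed_mask[nodes] = True
        fixed_value[nodes] = vals
    if not fixed_mask.any():
        raise ConfigurationError("no electrode boundary nodes supplied")
    vset = fixed_value[fixed_mask]
    if np.ptp(vset) == 0.0:
        raise ConfigurationError(
            "ill-posed boundary: need at least two electrodes at distinct potentials"
        )

    L = _face_system(sigma, spacing)
    free = ~fixed_mask
    A = L[free][:, free]
    b = -L[free][:, fixed_mask] @ fixed_value[fixed_mask]
    M = sparse.diags(1.0 / A.diagonal())
    x0 = np.full(free.sum(), vset.mean())
    x, info = cg(A, b, x0=x0, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    if info != 0:
        residual = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))
        raise SolverConvergenceError(
            f"conjugate gradients did not reach rtol={rtol} in {maxiter} "
            f"iterations (relative residual {residual:.3e})",
            residual=residual,
        )
    phi = np.empty(n)
    phi[fixed_mask] = fixed_value[fixed_mask]
    phi[free] = x
    return phi.reshape(sigma.shape)


def field_magnitude(potential: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """|E| in V/cm from a potential grid in V (central differences)."""
    gx, gy, gz = np.gradient(potential, *spacing)
    return np.sqrt(gx**2 + gy**2 + gz**2) * V_PER_CM_PER_V_PER_MM


def plane_current(
    potential: np.ndarray,
    sigma: np.ndarray,
    spacing: Sequence[float],
    axis: int,
    index: int,
) -> float:
    """Net current (A/mm scale: S*mm*V) crossing the plane between node
    layers ``index`` and ``index+1`` along ``axis``.  Used for discrete
    conservation checks: any cut between the two electrodes of a pair
    must carry the same current."""
    hx, hy, hz = spacing
    geo = (hy * hz / hx, hx * hz / hy, hx * hy / hz)[axis]
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    sl_a[axis] = index
    sl_b[axis] = index + 1
    sa, sb = sigma[tuple(sl_a)], sigma[tuple(sl_b)]
    g = geo * 2.0 * sa * sb / (sa + sb)
    return float(np.sum(g * (potential[tuple(sl_a)] - potential[tuple(sl_b)])))


@dataclass
class FieldState:
    """Result of simulating one deployment: accumulated max field and sigma."""

    grid: FieldGrid
    max_field_V_per_cm: np.ndarray
    sigma_S_per_m: np.ndarray
    pair_iterations: dict[str, int] = field(default_factory=dict)


def _same_grid(a: FieldGrid, b: FieldGrid) -> bool:
    return a.origin == b.origin and a.spacing == b.spacing and a.shape == b.shape


def simulate_deployment(
    plan: PulsePlan,
    layout: NeedleLayout,
    grid: FieldGrid,
    model: ConductivityModel,
    initial_max_field: Optional[np.ndarray] = None,
    cg_rtol: float = 1e-8,
    fixed_point_tol: float = 1e-3,
    fixed_point_maxiter: int = 25,
) -> FieldState:
    """Run every pair of a deployment's plan and accumulate the max field.

    Per pair: a fixed-point loop solves the potential, measures |E|,
    updates sigma from the running maximum (history is irreversible) and
    repeats until the relative sigma change falls below
    ``fixed_point_tol``.  Needles not in the active pair are electrically
    inert.  ``initial_max_field`` carries history from earlier
    deployments on the same grid.
    """
    if layout.exposure_mm != plan.deployment.exposure_mm:
        raise ConfigurationError(
            "plan and layout refer to different deployments "
            f"({plan.deployment.exposure_mm} vs {layout.exposure_mm} mm)"
        )
    nodes = rasterize_needles(layout, grid)
    for a in nodes:
        for b in nodes:
            if a < b and np.intersect1d(nodes[a], nodes[b]).size:
                raise GeometryError(
                    f"needles {a} and {b} overlap after rasterization; "
                    "use a finer grid spacing"
                )
    max_field = (
        np.zeros(grid.shape)
        if initial_max_field is None
        else np.array(initial_max_field, dtype=float)
    )
    iterations: dict[str, int] = {}
    for entry in plan.entries:
        if entry.voltage_V == 0:
            iterations[entry.pair.pair_id] = 0
            continue
        boundary = [
            (nodes[entry.pair.a], float(entry.voltage_V)),
            (nodes[entry.pair.b], 0.0),
        ]
        sigma = model(max_field)
        converged = False
        relax = 0.6  # damped Picard update; plain iteration can 2-cycle
        for it in range(1, fixed_point_maxiter + 1):
            phi = solve_potential(sigma, grid.spacing, boundary, rtol=cg_rtol)
            emag = field_magnitude(phi, grid.spacing)
            candidate = np.maximum(max_field, emag)
            target_sigma = model(candidate)
            change = float(
                np.max(np.abs(target_sigma - sigma)) / np.max(np.abs(sigma))
            )
            if change <= fixed_point_tol:
                sigma = target_sigma
                converged = True
                break
            sigma = sigma + relax * (target_sigma - sigma)
        if not converged:
            raise SolverConvergenceError(
                f"sigma fixed point for pair {entry.pair.pair_id} did not "
                f"converge in {fixed_point_maxiter} iterations "
                f"(last relative change {change:.3e})",
                residual=change,
            )
        iterations[entry.pair.pair_id] = it
        max_field = candidate
    return FieldState(
        grid=grid,
        max_field_V_per_cm=max_field,
        sigma_S_per_m=model(max_field),
        pair_iterations=iterations,
    )


def coverage_volume(
    state: "FieldState | np.ndarray",
    threshold_V_per_cm: float,
    grid: Optional[FieldGrid] = None,
) -> float:
    """Volume (cm^3) where the accumulated max field reaches the threshold."""
    if threshold_V_per_cm <= 0:
        raise DomainError("coverage threshold must be positive")
    if isinstance(state, FieldState):
        max_field, grid = state.max_field_V_per_cm, state.grid
    else:
        if grid is None:
            raise ConfigurationError("grid required when passing a bare field array")
        max_field = state
    count = int(np.count_nonzero(max_field >= threshold_V_per_cm))
    return count * grid.node_volume_mm3 / 1000.0


@dataclass(frozen=True)
class CoverageResult:
    """Per-deployment and union electroporated volumes at one threshold."""

    threshold_V_per_cm: float
    per_deployment_cm3: tuple[float, ...]
    union_cm3: float


def union_coverage(
    states: Sequence[FieldState], threshold_V_per_cm: float
) -> CoverageResult:
    """Coverage of a segmented treatment: union over deployment steps."""
    if not states:
        raise ConfigurationError("at least one field state is required")
    grid = states[0].grid
    for st in states[1:]:
        if not _same_grid(st.grid, grid):
            raise ConfigurationError("all field states must share one grid")
    if threshold_V_per_cm <= 0:
        raise DomainError("coverage threshold must be positive")
    per = tuple(coverage_volume(st, threshold_V_per_cm) for st in states)
    union_mask = np.zeros(grid.shape, dtype=bool)
    for st in states:
        union_mask |= st.max_field_V_per_cm >= threshold_V_per_cm
    union = int(np.count_nonzero(union_mask)) * grid.node_volume_mm3 / 1000.0
    return CoverageResult(
        threshold_V_per_cm=threshold_V_per_cm,
        per_deployment_cm3=per,
        union_cm3=union,
    )


@dataclass(frozen=True)
class TipFieldReport:
    """Minimum sampled field along each pair's tip-to-tip segment."""

    threshold_V_per_cm: float
    per_pair_min_V_per_cm: dict[str, float]

    @property
    def ok(self) -> bool:
        return all(
            v >= self.threshold_V_per_cm for v in self.per_pair_min_V_per_cm.values()
        )


def verify_tip_field(
    state: FieldState,
    layout: NeedleLayout,
    pairs: Sequence,
    threshold_V_per_cm: float = 1000.0,
    n_samples: int = 33,
) -> TipFieldReport:
    """Check the design criterion that the field between needle tips
    reaches ``threshold`` (1000 V/cm by default).

    Samples the accumulated max-field grid along the straight tip-to-tip
    segment of every pair with trilinear interpolation and reports the
    per-pair minima."""
    minima: dict[str, float] = {}
    for pair in pairs:
        a, b = layout.tip(pair.a), layout.tip(pair.b)
        t = np.linspace(0.0, 1.0, n_samples)[:, None]
        pts = a[None, :] + t * (b - a)[None, :]
        coords = state.grid.index_coords(pts).T
        samples = map_coordinates(
            state.max_field_V_per_cm, coords, order=1, mode="nearest"
        )
        minima[pair.pair_id] = float(samples.min())
    return TipFieldReport(
        threshold_V_per_cm=threshold_V_per_cm, per_pair_min_V_per_cm=minima
    )
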