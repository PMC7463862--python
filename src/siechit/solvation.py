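"""Continuum solvation: reaction-field energy and molecular surface area.

The reaction-field term solves the Poisson equation

    div( eps(r) grad phi ) = -4 pi k rho_q(r)

on a uniform Cartesian grid with a two-dielectric coefficient: eps = D_in
inside the union of atom spheres of radius rho * boundary_radius, eps =
D_solv outside. Face dielectric constants are harmonic means weighted by
the exact fraction of each grid edge inside the cavity, which keeps the
discretization error smooth as the grid is refined. Charges are spread to
grid nodes trilinearly; the boundary condition is the analytic
solvent-screened monopole potential; iteration is red-black successive
over-relaxation. The reported energy is

    dG_RF = 1/2 sum_i q_i ( phi(r_i) - phi_vac(r_i) )

where phi_vac is the same solve with eps = D_in everywhere, so the
self-energy of the lattice charge distribution cancels exactly.

The surface-area term is a rolling-probe accessible area over spheres of
radius rho * boundary_radius + probe, sampled with deterministic
generalized-spiral points so results are bit-reproducible for a given
n_points.

Units: kcal/mol, Angstrom, elementary charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atoms import AtomSelection, MolecularSystem, SelectionError
from .energy import COULOMB_K

__all__ = [
    "GridSpec",
    "SolvationResult",
    "SurfaceArea",
    "GridError",
    "ConvergenceError",
    "born_reaction_field",
    "reaction_field_energy",
    "delta_reaction_field",
    "molecular_surface_area",
    "delta_msa",
    "solvate",
]


class GridError(ValueError):
    """Atom outside the solver grid."""


class ConvergenceError(RuntimeError):
    """SOR iteration did not reach tolerance; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class GridSpec:
    """Finite-difference grid parameters.

    spacing and padding in Angstrom; tolerance is the maximum potential
    change per sweep, kcal/(mol e), at which iteration stops.
    """

    spacing: float = 0.5
    padding: float = 6.0
    max_iterations: int = 20000
    tolerance: float = 1e-4

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.padding < 4 * self.spacing:
            raise ValueError("padding must be at least 4 grid spacings")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class SolvationResult:
    reaction_field: float      # kcal/mol
    surface_area: float        # A^2
    boundary_scaling: float    # rho
    solute_dielectric: float   # D_in
    solvent_dielectric: float


@dataclass(frozen=True)
class SurfaceArea:
    total: float               # A^2
    per_atom: np.ndarray       # A^2, one entry per atom


def born_reaction_field(q: float, radius: float, d_in: float, d_solv: float) -> float:
    """Analytic Born reaction-field energy of a point charge centered in a
    spherical cavity, kcal/mol."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return -0.5 * COULOMB_K * q * q / radius * (1.0 / d_in - 1.0 / d_solv)


# ---------------------------------------------------------------- grid setup

def _axes(coords: np.ndarray, spec: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Node coordinate arrays per axis; odd node counts keep the box center
    on a node, which keeps single-ion validation geometry exact."""
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo) + spec.padding
    out = []
    for d in range(3):
        n = int(math.ceil(2.0 * half[d] / spec.spacing)) + 1
        if n % 2 == 0:
            n += 1
        span = (n - 1) * spec.spacing
        out.append(center[d] - span / 2.0 + spec.spacing * np.arange(n))
    return tuple(out)  # type: ignore[return-value]


def _check_inside(coords: np.ndarray, axes, margin: float) -> None:
    for d, ax in enumerate(axes):
        if coords[:, d].min() < ax[0] + margin or coords[:, d].max() > ax[-1] - margin:
            raise GridError("atom too close to or outside the grid boundary")


def _trilinear(axes, coords: np.ndarray):
    """Cell indices and trilinear weights for a set of points."""
    h = axes[0][1] - axes[0][0]
    idx = np.empty((len(coords), 3), dtype=int)
    frac = np.empty((len(coords), 3))
    for d in range(3):
        t = (coords[:, d] - axes[d][0]) / h
        i = np.clip(np.floor(t).astype(int), 0, len(axes[d]) - 2)
        idx[:, d] = i
        frac[:, d] = t - i
    return idx, frac


def _spread_charges(axes, coords: np.ndarray, charges: np.ndarray) -> np.ndarray:
    grid = np.zeros((len(axes[0]), len(axes[1]), len(axes[2])))
    idx, frac = _trilinear(axes, coords)
    for (i, j, k), (fx, fy, fz), q in zip(idx, frac, charges):
        for di, wx in ((0, 1 - fx), (1, fx)):
            for dj, wy in ((0, 1 - fy), (1, fy)):
                for dk, wz in ((0, 1 - fz), (1, fz)):
                    grid[i + di, j + dj, k + dk] += q * wx * wy * wz
    return grid


def _interpolate(axes, field3d: np.ndarray, coords: np.ndarray) -> np.ndarray:
    idx, frac = _trilinear(axes, coords)
    out = np.zeros(len(coords))
    for n, ((i, j, k), (fx, fy, fz)) in enumerate(zip(idx, frac)):
        acc = 0.0
        for di, wx in ((0, 1 - fx), (1, fx)):
            for dj, wy in ((0, 1 - fy), (1, fy)):
                for dk, wz in ((0, 1 - fz), (1, fz)):
                    acc += field3d[i + di, j + dj, k + dk] * wx * wy * wz
        out[n] = acc
    return out


# ------------------------------------------------- dielectric boundary faces

def _edge_inside_fraction(
    edge_starts: np.ndarray, perp_a: np.ndarray, perp_b: np.ndarray,
    centers: np.ndarray, radii: np.ndarray, axis: int, h: float,
) -> np.ndarray:
    """Fraction of each axis-aligned grid edge inside the union of spheres.

    edge_starts: 1-D array of edge start coordinates along `axis`;
    perp_a/perp_b: 1-D node coordinate arrays of the two perpendicular axes.
    Returns array of shape (len(edge_starts), len(perp_a), len(perp_b)).
    Per-sphere chord lengths are exact; edges covered by more than one
    sphere get an exact interval-union correction.
    """
    shape = (len(edge_starts), len(perp_a), len(perp_b))
    total = np.zeros(shape)
    count = np.zeros(shape, dtype=np.uint8)
    sparse: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    x0 = edge_starts[:, None, None]
    x1 = x0 + h
    perp_axes = [d for d in range(3) if d != axis]
    pa = perp_a[None, :, None]
    pb = perp_b[None, None, :]
    for c, r in zip(centers, radii):
        d2 = (pa - c[perp_axes[0]]) ** 2 + (pb - c[perp_axes[1]]) ** 2
        s2 = r * r - d2
        chord = np.zeros(shape)
        hit2d = s2 > 0
        s = np.sqrt(np.where(hit2d, s2, 0.0))
        lo = np.maximum(c[axis] - s, x0)
        hi = np.minimum(c[axis] + s, x1)
        chord = np.where(hit2d, np.clip(hi - lo, 0.0, None), 0.0)
        hit = chord > 0
        total += chord
        count += hit
        flat = np.flatnonzero(hit)
        if flat.size:
            sparse.append((flat, lo.ravel()[flat], hi.ravel()[flat]))

    # exact union where two or more spheres cover the same edge
    multi = np.flatnonzero(count.ravel() >= 2)
    if multi.size:
        multiset = set(multi.tolist())
        per_edge: dict[int, list[tuple[float, float]]] = {m: [] for m in multiset}
        for flat, lo, hi in sparse:
            for f, a, b in zip(flat.tolist(), lo.tolist(), hi.tolist()):
                if f in multiset:
                    per_edge[f].append((a, b))
        flat_total = total.ravel()
        for f, ivals in per_edge.items():
            ivals.sort()
            merged = 0.0
            cur_a, cur_b = ivals[0]
            for a, b in ivals[1:]:
                if a > cur_b:
                    merged += cur_b - cur_a
                    cur_a, cur_b = a, b
                else:
                    cur_b = max(cur_b, b)
            merged += cur_b - cur_a
            flat_total[f] = merged
        total = flat_total.reshape(shape)

    return np.clip(total / h, 0.0, 1.0)


def _face_dielectrics(axes, centers, radii, d_in, d_solv):
    h = axes[0][1] - axes[0][0]
    eps = []
    for axis in range(3):
        perp = [d for d in range(3) if d != axis]
        frac = _edge_inside_fraction(
            axes[axis][:-1], axes[perp[0]], axes[perp[1]],
            centers, radii, axis, h,
        )
        # harmonic (series) mean of the two dielectrics along the edge
        e = 1.0 / (frac / d_in + (1.0 - frac) / d_solv)
        # reorder so array axes are (x, y, z): array dim d corresponds to
        # physical axis order[d], so dim d moves to position order[d]
        order = [axis, perp[0], perp[1]]
        eps.append(np.moveaxis(e, [0, 1, 2], order))
    return eps


# ----------------------------------------------------------------- SOR solve

def _screened_monopole(axes, coords, charges, dielectric) -> np.ndarray:
    """Analytic potential sum_i k q_i / (D |r - r_i|) on the full grid."""
    X = axes[0][:, None, None]
    Y = axes[1][None, :, None]
    Z = axes[2][None, None, :]
    phi = np.zeros((len(axes[0]), len(axes[1]), len(axes[2])))
    for c, q in zip(coords, charges):
        if q == 0.0:
            continue
        r = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        r = np.maximum(r, 1e-6)
        phi += COULOMB_K * q / (dielectric * r)
    return phi


def _sor(phi, eps_x, eps_y, eps_z, source, spec: GridSpec) -> np.ndarray:
    """Red-black SOR on the interior nodes; boundary values held fixed."""
    nx, ny, nz = phi.shape
    ii, jj, kk = np.meshgrid(
        np.arange(1, nx - 1), np.arange(1, ny - 1), np.arange(1, nz - 1),
        indexing="ij",
    )
    parity = (ii + jj + kk) % 2
    diag = (
        eps_x[:-1, 1:-1, 1:-1] + eps_x[1:, 1:-1, 1:-1]
        + eps_y[1:-1, :-1, 1:-1] + eps_y[1:-1, 1:, 1:-1]
        + eps_z[1:-1, 1:-1, :-1] + eps_z[1:-1, 1:-1, 1:]
    )
    src = source[1:-1, 1:-1, 1:-1]
    n = max(nx, ny, nz)
    omega = 2.0 / (1.0 + math.sin(math.pi / n))
    residual = math.inf
    for _ in range(spec.max_iterations):
        residual = 0.0
        for color in (0, 1):
            nb = (
                eps_x[:-1, 1:-1, 1:-1] * phi[:-2, 1:-1, 1:-1]
                + eps_x[1:, 1:-1, 1:-1] * phi[2:, 1:-1, 1:-1]
                + eps_y[1:-1, :-1, 1:-1] * phi[1:-1, :-2, 1:-1]
                + eps_y[1:-1, 1:, 1:-1] * phi[1:-1, 2:, 1:-1]
                + eps_z[1:-1, 1:-1, :-1] * phi[1:-1, 1:-1, :-2]
                + eps_z[1:-1, 1:-1, 1:] * phi[1:-1, 1:-1, 2:]
            )
            target = (nb + src) / diag
            interior = phi[1:-1, 1:-1, 1:-1]
            delta = omega * (target - interior)
            mask = parity == color
            interior[mask] += delta[mask]
            step = np.abs(delta[mask]).max() if mask.any() else 0.0
            residual = max(residual, float(step))
        if residual < spec.tolerance:
            return phi
    raise ConvergenceError(
        f"SOR did not converge in {spec.max_iterations} iterations "
        f"(final residual {residual:.3e})",
        residual,
    )


def _rf_energy_arrays(
    coords: np.ndarray,
    charges: np.ndarray,
    cavity_radii: np.ndarray,
    d_in: float,
    d_solv: float,
    spec: GridSpec,
    axes=None,
) -> float:
    """Core reaction-field computation on explicit arrays."""
    if axes is None:
        axes = _axes(coords, spec)
    _check_inside(coords, axes, margin=2 * spec.spacing)
    h = spec.spacing
    q_grid = _spread_charges(axes, coords, charges)
    source = 4.0 * math.pi * COULOMB_K * q_grid / h

    # heterogeneous solve: D_in inside the cavity union, D_solv outside
    eps_x, eps_y, eps_z = _face_dielectrics(axes, coords, cavity_radii, d_in, d_solv)
    phi_het = _screened_monopole(axes, coords, charges, d_solv)
    phi_het = _sor(phi_het, eps_x, eps_y, eps_z, source, spec)

    # vacuum reference: uniform D_in (cancels lattice self-energy)
    shape = q_grid.shape
    ex = np.full((shape[0] - 1, shape[1], shape[2]), d_in)
    ey = np.full((shape[0], shape[1] - 1, shape[2]), d_in)
    ez = np.full((shape[0], shape[1], shape[2] - 1), d_in)
    phi_vac = _screened_monopole(axes, coords, charges, d_in)
    phi_vac = _sor(phi_vac, ex, ey, ez, source, spec)

    dphi = _interpolate(axes, phi_het - phi_vac, coords)
    return float(0.5 * np.sum(charges * dphi))


def reaction_field_energy(
    system: MolecularSystem,
    d_in: float = 2.25,
    d_solv: float = 78.5,
    rho: float = 1.1,
    grid: GridSpec | None = None,
    frame: np.ndarray | None = None,
) -> float:
    """Reaction-field (solvation) energy of one system, kcal/mol.

    Negative for any net-charged solute when the solvent is more polar
    than the solute interior.
    """
    if d_solv < d_in:
        raise ValueError("d_solv must be >= d_in")
    system.require_parameterized()
    grid = grid or GridSpec()
    coords = system.coords if frame is None else np.asarray(frame, float)
    return _rf_energy_arrays(
        coords, system.charges, rho * system.boundary_radii, d_in, d_solv, grid
    )


def _check_partition(receptor: AtomSelection, ligand: AtomSelection) -> MolecularSystem:
    if receptor.system is not ligand.system:
        raise SelectionError("selections must address the same system")
    if not receptor.disjoint(ligand):
        raise SelectionError("receptor and ligand selections overlap")
    system = receptor.system
    if len(receptor) + len(ligand) != len(system):
        raise SelectionError("receptor and ligand must partition the complex")
    return system


def delta_reaction_field(
    receptor: AtomSelection,
    ligand: AtomSelection,
    d_in: float = 2.25,
    d_solv: float = 78.5,
    rho: float = 1.1,
    grid: GridSpec | None = None,
    frame: np.ndarray | None = None,
) -> float:
    """Reaction-field change upon binding: RF(complex) - RF(receptor) -
    RF(ligand), all three on the identical grid, frozen coordinates
    (single-trajectory endpoint convention). Typically positive: binding
    desolvates both partners."""
    system = _check_partition(receptor, ligand)
    if d_solv < d_in:
        raise ValueError("d_solv must be >= d_in")
    system.require_parameterized()
    grid = grid or GridSpec()
    coords = system.coords if frame is None else np.asarray(frame, float)
    charges = system.charges
    radii = rho * system.boundary_radii
    axes = _axes(coords, grid)

    def rf(idx: np.ndarray | None) -> float:
        if idx is None:
            return _rf_energy_arrays(coords, charges, radii, d_in, d_solv, grid, axes)
        return _rf_energy_arrays(
            coords[idx], charges[idx], radii[idx], d_in, d_solv, grid, axes
        )

    return rf(None) - rf(receptor.indices) - rf(ligand.indices)


# ------------------------------------------------------------- surface area

def _spiral_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden-angle) points on the unit
    sphere, approximately equal-area."""
    i = np.arange(n)
    z = (2.0 * i + 1.0) / n - 1.0
    golden = math.pi * (3.0 - math.sqrt(5.0))
    theta = golden * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def molecular_surface_area(
    system: MolecularSystem,
    probe: float = 1.4,
    rho: float = 1.1,
    n_points: int = 960,
    frame: np.ndarray | None = None,
    indices: np.ndarray | None = None,
) -> SurfaceArea:
    """Probe-inflated accessible surface area over spheres of radius
    rho * boundary_radius + probe, A^2. Deterministic for given n_points."""
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    system.require_parameterized()
    coords = system.coords if frame is None else np.asarray(frame, float)
    radii = rho * system.boundary_radii + probe
    if indices is not None:
        coords = coords[indices]
        radii = radii[indices]
    unit = _spiral_points(n_points)
    n_at = len(coords)
    per_atom = np.zeros(n_at)
    for i in range(n_at):
        pts = coords[i] + radii[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n_at):
            if j == i:
                continue
            gap = np.linalg.norm(coords[i] - coords[j])
            if gap >= radii[i] + radii[j]:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
            if not exposed.any():
                break
        per_atom[i] = 4.0 * math.pi * radii[i] ** 2 * exposed.mean()
    return SurfaceArea(total=float(per_atom.sum()), per_atom=per_atom)


def delta_msa(
    receptor: AtomSelection,
    ligand: AtomSelection,
    probe: float = 1.4,
    rho: float = 1.1,
    n_points: int = 960,
    frame: np.ndarray | None = None,
) -> float:
    """Surface-area change upon binding: MSA(complex) - MSA(receptor) -
    MSA(ligand), A^2; non-positive whenever any cross pair of spheres
    overlaps (burial)."""
    system = _check_partition(receptor, ligand)
    args = dict(probe=probe, rho=rho, n_points=n_points, frame=frame)
    msa_c = molecular_surface_area(system, **args).total
    msa_r = molecular_surface_area(system, indices=receptor.indices, **args).total
    msa_l = molecular_surface_area(system, indices=ligand.indices, **args).total
    return msa_c - msa_r - msa_l


def solvate(
    system: MolecularSystem,
    d_in: float = 2.25,
    d_solv: float = 78.5,
    rho: float = 1.1,
    probe: float = 1.4,
    n_points: int = 960,
    grid: GridSpec | None = None,
    frame: np.ndarray | None = None,
) -> SolvationResult:
    """Reaction field plus surface area for a single system."""
    rf = reaction_field_energy(system, d_in, d_solv, rho, grid, frame)
    sa = molecular_surface_area(system, probe, rho, n_points, frame)
    return SolvationResult(
        reaction_field=rf,
        surface_area=sa.total,
        boundary_scaling=rho,
        solute_dielectric=d_in,
        solvent_dielectric=d_solv,
    )
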