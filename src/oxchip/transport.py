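"""Steady and transient oxygen transport across the chip cross section.

The oxygen field is solved in partial-pressure form: phi is the oxygen
tension in %O2 (21 = ambient air).  Writing Henry's law as c = S * p, the
diffusion problem in a multi-material domain becomes

    steady:     div( k grad phi ) = 0,        k = D * S   (permeability)
    transient:  S dphi/dt = div( k grad phi )

with phi continuous everywhere.  This formulation makes the partition
condition at material interfaces (equal partial pressure, concentration
jumping by the solubility ratio) automatic: a finite-volume discretization
with harmonic-mean face permeability conserves flux exactly across the
jump, and per-cell solubility gives each material its proper capacitance
in time stepping.

Boundary conditions: the gas channels are fixed-composition (Dirichlet)
surfaces — valid when the gas supply Peclet number is >= 10, which the
device always satisfies in operation; the outer surface (sides and top)
sees ambient air at 21 %O2; the glass floor is zero flux.  Advection is
not solved in the cross section: the media channels hold static medium in
the cellular experiments, and the gas supply enters only through its
Dirichlet value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import MATERIALS, DeviceSpec, Material, MaterialGrid, build_cross_section

__all__ = [
    "FlowSpec",
    "BoundarySet",
    "OxygenField",
    "pe_to_flow",
    "solve_steady",
    "solve_transient",
    "sweep_steady",
    "gel_gradient_profile",
    "channel_axis_model",
    "slab_series_solution",
    "equilibration_time",
    "region_flux_balance",
    "CONDITIONS",
]

ATM_MM3_PER_S_TO_ML_PER_MIN = 1e6 * 60.0  # m^3/s -> ml/min


@dataclass(frozen=True)
class FlowSpec:
    """Channel flow parameterized by the Peclet number Pe = U * W / D.

    The characteristic length is the channel *width* W (this is the only
    choice that reproduces the published velocity/flow-rate conversions for
    both the 500 um media and 1000 um gas channels).
    """

    Pe: float
    fluid: Material
    width: float
    height: float
    U: float  # mean velocity, m/s
    Q: float  # volumetric flow, ml/min


def pe_to_flow(Pe: float, fluid: Material | str, width: float, height: float) -> FlowSpec:
    """Convert a Peclet number into mean velocity and volumetric flow.

    U = Pe * D_fluid / W;  Q = U * W * h  (reported in ml/min, per channel).
    """
    if isinstance(fluid, str):
        try:
            fluid = Material[fluid.upper()]
        except KeyError:
            raise ValueError(f"unknown fluid {fluid!r}") from None
    if fluid not in (Material.MEDIUM, Material.GAS):
        raise ValueError(f"fluid must be medium or gas, got {fluid.name}")
    if Pe < 0:
        raise ValueError("Pe must be >= 0")
    D = MATERIALS[fluid].diffusivity
    U = Pe * D / width
    Q = U * width * height * ATM_MM3_PER_S_TO_ML_PER_MIN
    return FlowSpec(Pe=Pe, fluid=fluid, width=width, height=height, U=U, Q=Q)


@dataclass(frozen=True)
class BoundarySet:
    """Oxygen boundary values, in %O2.

    gas_left / gas_right are the supply compositions imposed on the two gas
    channels; ambient is the atmosphere seen by the outer PDMS surface.
    The floor is glass and takes no flux.
    """

    gas_left: float = 21.0
    gas_right: float = 21.0
    ambient: float = 21.0
    floor_no_flux: bool = True
    gas_pe: float = 100.0  # supply Peclet number; Dirichlet valid for >= 10
    # which outer surfaces see the ambient atmosphere; the glass floor never
    # does ("top", "left", "right")
    ambient_surfaces: tuple = ("top", "left", "right")

    def __post_init__(self) -> None:
        for name in ("gas_left", "gas_right", "ambient"):
            val = getattr(self, name)
            if not (0.0 <= val <= 21.0):
                raise ValueError(f"{name} = {val} outside [0, 21] %O2")
        if self.gas_pe < 10:
            warnings.warn(
                "gas supply Pe < 10: the fixed-composition gas-channel "
                "boundary is not a good approximation at low supply rates",
                stacklevel=2,
            )

    @property
    def extremes(self) -> tuple[float, float]:
        vals = (self.gas_left, self.gas_right, self.ambient)
        return min(vals), max(vals)


# Standard supply conditions used in the study: uniform hypoxia Hn supplies
# n %O2 to both gas channels, N is normoxia, G/G2 are gradients.
CONDITIONS: dict[str, BoundarySet] = {
    "H0": BoundarySet(0.0, 0.0),
    "H1": BoundarySet(1.0, 1.0),
    "H3": BoundarySet(3.0, 3.0),
    "H5": BoundarySet(5.0, 5.0),
    "H10": BoundarySet(10.0, 10.0),
    "N": BoundarySet(21.0, 21.0),
    "G": BoundarySet(0.0, 21.0),
    "G2": BoundarySet(0.0, 10.0),
}


@dataclass
class OxygenField:
    """Oxygen tension on a material grid, steady or time-resolved.

    ``phi`` is %O2 per cell, shape (nz, nx) for a steady field or
    (nt, nz, nx) for snapshots at ``times``.  ``trace_times`` /
    ``trace_center`` hold the finely-sampled gel-center history of a
    transient solve (every accepted step, not just snapshot times).
    """

    grid: MaterialGrid
    phi: np.ndarray
    times: np.ndarray | None = None
    trace_times: np.ndarray | None = None
    trace_center: np.ndarray | None = None

    @property
    def is_transient(self) -> bool:
        return self.phi.ndim == 3

    def concentration(self) -> np.ndarray:
        """Dissolved-oxygen concentration in mM: c = S * (phi/100) * 1 atm.

        Equal partial pressure on both sides of an interface maps to
        concentrations differing by the solubility ratio.
        """
        return self.grid.solubility * (self.phi / 100.0)

    def at(self, x: float, z: float, snapshot: int = -1) -> float:
        """phi at the cell containing (x, z) (last snapshot if transient)."""
        iz, ix = self.grid.cell_index(x, z)
        frame = self.phi[snapshot] if self.is_transient else self.phi
        return float(frame[iz, ix])

    def center_gel(self, snapshot: int = -1) -> float:
        """phi at the gel center, mid-height of the aqueous layer."""
        return self.at(0.0, self.grid.spec.channel_height / 2, snapshot)


# ---------------------------------------------------------------------------
# finite-volume assembly


def _face_conductance(k1, k2, d1, d2, area):
    """Harmonic-mean conductance of the two half-cells meeting at a face."""
    with np.errstate(divide="ignore", invalid="ignore"):
        g = area / (0.5 * d1 / k1 + 0.5 * d2 / k2)
    return np.where((k1 > 0) & (k2 > 0), g, 0.0)


def _face_conductances(grid: MaterialGrid):
    """Harmonic-mean conductances on internal faces: (gx, gz) with
    gx[iz, ix] between cells (iz, ix)-(iz, ix+1), gz between rows."""
    k = grid.permeability
    dx, dz = grid.dx, grid.dz
    gx = _face_conductance(k[:, :-1], k[:, 1:], dx[None, :-1], dx[None, 1:], dz[:, None])
    gz = _face_conductance(k[:-1, :], k[1:, :], dz[:-1, None], dz[1:, None], dx[None, :])
    return gx, gz


def _assemble(grid: MaterialGrid, bc: BoundarySet):
    """Build the FV operator A (so that A phi = b at steady state) with
    Dirichlet rows for gas-channel cells, plus the rhs b and the Dirichlet
    mask.  Sign convention: A = -div(k grad) discretized, SPD-like."""
    nx, nz = grid.nx, grid.nz
    n = nx * nz
    k = grid.permeability
    dx, dz = grid.dx, grid.dz

    idx = np.arange(n).reshape(nz, nx)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    b = np.zeros(n)

    gx, gz = _face_conductances(grid)

    # Horizontal internal faces between (iz, ix) and (iz, ix+1).
    i1, i2 = idx[:, :-1].ravel(), idx[:, 1:].ravel()
    g = gx.ravel()
    rows += [i1, i2]
    cols += [i2, i1]
    vals += [-g, -g]
    np.add.at(diag, i1, g)
    np.add.at(diag, i2, g)

    # Vertical internal faces between (iz, ix) and (iz+1, ix).
    i1, i2 = idx[:-1, :].ravel(), idx[1:, :].ravel()
    g = gz.ravel()
    rows += [i1, i2]
    cols += [i2, i1]
    vals += [-g, -g]
    np.add.at(diag, i1, g)
    np.add.at(diag, i2, g)

    # Ambient Dirichlet on the outer surface: top row and both side columns.
    # Half-cell conductance from the cell center to the boundary face.
    def add_boundary(cell_idx, k_cell, d_half, area, value):
        g = np.where(k_cell > 0, area / (0.5 * d_half / np.where(k_cell > 0, k_cell, 1.0)), 0.0)
        np.add.at(diag, cell_idx, g)
        np.add.at(b, cell_idx, g * value)

    if "top" in bc.ambient_surfaces:
        add_boundary(idx[-1, :], k[-1, :], np.full(nx, dz[-1]), dx, bc.ambient)
    if "left" in bc.ambient_surfaces:
        add_boundary(idx[:, 0], k[:, 0], np.full(nz, dx[0]), dz, bc.ambient)
    if "right" in bc.ambient_surfaces:
        add_boundary(idx[:, -1], k[:, -1], np.full(nz, dx[-1]), dz, bc.ambient)
    # Floor z = 0: glass, zero flux — no terms.

    A = sp.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (np.concatenate(rows + [np.arange(n)]), np.concatenate(cols + [np.arange(n)])),
        ),
        shape=(n, n),
    ).tocsr()

    # Gas channels: Dirichlet cells at the supply composition.
    gas = grid.material == int(Material.GAS)
    xc = grid.x_centers
    dirichlet = np.zeros(n, dtype=bool)
    dirichlet_vals = np.zeros(n)
    if gas.any():
        gas_flat = gas.ravel()
        left = (gas & (xc[None, :] < 0)).ravel()
        right = (gas & (xc[None, :] >= 0)).ravel()
        dirichlet |= gas_flat
        dirichlet_vals[left] = bc.gas_left
        dirichlet_vals[right] = bc.gas_right

    return A, b, dirichlet, dirichlet_vals


def _apply_dirichlet(A, b, dirichlet, values):
    """Replace Dirichlet rows by identity (keeps the matrix square/simple)."""
    A = A.tolil()
    d = np.nonzero(dirichlet)[0]
    for i in d:
        A.rows[i] = [i]
        A.data[i] = [1.0]
    b = b.copy()
    b[d] = values[d]
    return A.tocsr(), b


def solve_steady(
    grid: MaterialGrid,
    bc: BoundarySet,
    rtol: float = 1e-10,
    check_bounds: bool = True,
) -> OxygenField:
    """Steady oxygen tension: direct sparse solve of the FV system.

    Raises if no Dirichlet surface exists (singular), if the residual
    exceeds ``rtol`` relative to the rhs, or (optionally) if the discrete
    maximum principle is violated beyond round-off.
    """
    A, b, dirichlet, dvals = _assemble(grid, bc)
    if not dirichlet.any() and not np.any(b):
        raise ValueError("singular system: no Dirichlet surface anywhere")
    A, b = _apply_dirichlet(A, b, dirichlet, dvals)
    lu = splu(A.tocsc())
    phi = lu.solve(b)
    resid = np.linalg.norm(A @ phi - b)
    scale = max(np.linalg.norm(b), 1e-30)
    if resid > max(rtol * scale, 1e-8):
        raise RuntimeError(f"steady solve did not converge: residual {resid:.3e}")
    lo, hi = bc.extremes
    if check_bounds:
        tol = 1e-8 * max(1.0, hi)
        if phi.min() < lo - tol or phi.max() > hi + tol:
            raise RuntimeError(
                "discrete maximum principle violated: "
                f"phi in [{phi.min():.6g}, {phi.max():.6g}], bc in [{lo}, {hi}]"
            )
    return OxygenField(grid=grid, phi=phi.reshape(grid.nz, grid.nx))


def solve_transient(
    grid: MaterialGrid,
    bc: BoundarySet,
    initial: OxygenField | float,
    t_end: float,
    dt: float = 1.0,
    snapshot_times=None,
) -> OxygenField:
    """Implicit (backward-Euler) time stepping of S dphi/dt = div(k grad phi).

    The accumulation term uses per-cell solubility times cell volume, so
    partial pressure relaxes with each material's true capacitance.  The
    system matrix is factorized once and reused for every step.  The
    gel-center value is recorded at every step (``trace_*``); full-field
    snapshots are kept at ``snapshot_times`` (default: t=0 and t_end).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end < dt:
        raise ValueError("t_end must be >= dt")

    if isinstance(initial, OxygenField):
        phi = np.asarray(initial.phi, dtype=float).ravel().copy()
    else:
        phi = np.full(grid.nz * grid.nx, float(initial))

    A, b, dirichlet, dvals = _assemble(grid, bc)
    cap = (grid.solubility * grid.cell_areas).ravel() / dt  # S * V / dt
    M = A + sp.diags(cap)
    M, _ = _apply_dirichlet(M, b, dirichlet, dvals)
    lu = splu(M.tocsc())

    # Dirichlet values take effect immediately at the first step.
    iz, ix = grid.cell_index(0.0, grid.spec.channel_height / 2)
    center = iz * grid.nx + ix

    n_steps = int(np.ceil(t_end / dt - 1e-9))
    times = [0.0]
    trace = [phi[center]]
    if snapshot_times is None:
        snapshot_times = [0.0, n_steps * dt]
    snapshot_times = np.asarray(sorted(snapshot_times), dtype=float)
    snaps, snap_t = [], []
    if snapshot_times.size and snapshot_times[0] <= 0.0:
        snaps.append(phi.reshape(grid.nz, grid.nx).copy())
        snap_t.append(0.0)

    for step in range(1, n_steps + 1):
        rhs = cap * phi + b
        rhs[dirichlet] = dvals[dirichlet]
        phi = lu.solve(rhs)
        t = step * dt
        times.append(t)
        trace.append(phi[center])
        due = (snapshot_times > t - dt + 1e-12) & (snapshot_times <= t + 1e-12)
        if due.any():
            snaps.append(phi.reshape(grid.nz, grid.nx).copy())
            snap_t.append(t)

    if not snaps or snap_t[-1] < n_steps * dt - 1e-9:
        snaps.append(phi.reshape(grid.nz, grid.nx).copy())
        snap_t.append(n_steps * dt)

    return OxygenField(
        grid=grid,
        phi=np.stack(snaps),
        times=np.asarray(snap_t),
        trace_times=np.asarray(times),
        trace_center=np.asarray(trace),
    )


def equilibration_time(field: OxygenField, steady_value: float, tol: float) -> float:
    """First time the gel-center trace stays within ``tol`` of the steady
    value (in seconds); inf if never reached."""
    if field.trace_times is None:
        raise ValueError("field has no transient trace")
    inside = np.abs(field.trace_center - steady_value) <= tol
    # Require the trace to remain inside from that time on (monotone
    # approach makes this equal to first crossing, but be safe).
    ok = np.flip(np.logical_and.accumulate(np.flip(inside)))
    hits = np.nonzero(ok)[0]
    return float(field.trace_times[hits[0]]) if hits.size else float("inf")


# ---------------------------------------------------------------------------
# higher-level operations


def gel_gradient_profile(field: OxygenField) -> dict:
    """Oxygen profile across the gel at mid-height of the aqueous layer.

    Returns a dict with a tidy (x_um, phi) table over the gel span, the
    least-squares slope in %O2/mm, and the endpoint values at the gel
    edges.
    """
    grid = field.grid
    spec = grid.spec
    z_mid = spec.channel_height / 2
    iz, _ = grid.cell_index(0.0, z_mid)
    xc = grid.x_centers
    mask = np.abs(xc) <= spec.gel_half + 1e-12
    frame = field.phi[-1] if field.is_transient else field.phi
    x = xc[mask]
    phi = frame[iz, mask]
    slope_per_m, intercept = np.polyfit(x, phi, 1)
    table = pd.DataFrame({"x_um": x / 1e-6, "phi": phi})
    return {
        "table": table,
        "slope_per_mm": float(slope_per_m * 1e-3),
        "intercept": float(intercept),
        "endpoints": (float(phi[0]), float(phi[-1])),
    }


def sweep_steady(
    specs,
    conditions,
    resolution: float = 25e-6,
) -> pd.DataFrame:
    """Steady solves over a (geometry, boundary-condition) design sweep.

    ``conditions`` maps label -> BoundarySet (or is an iterable of
    (label, BoundarySet) pairs).  One row per (spec, condition) with the
    gel-center value and the gel profile; a solver failure annotates the
    row instead of aborting the sweep.
    """
    if isinstance(conditions, dict):
        cond_items = list(conditions.items())
    else:
        cond_items = list(conditions)
    rows = []
    for spec in specs:
        grid = build_cross_section(spec, resolution)
        for label, bc in cond_items:
            row = {
                "H_g_mm": spec.H_g / 1e-3,
                "H_f_mm": spec.H_f / 1e-3,
                "condition": label,
            }
            try:
                fld = solve_steady(grid, bc)
                prof = gel_gradient_profile(fld)
                row.update(
                    center_phi=fld.center_gel(),
                    slope_per_mm=prof["slope_per_mm"],
                    gel_profile=prof["table"],
                    error=None,
                )
            except Exception as exc:  # annotate, don't abort the sweep
                row.update(
                    center_phi=np.nan,
                    slope_per_mm=np.nan,
                    gel_profile=None,
                    error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def region_flux_balance(field: OxygenField, materials) -> dict:
    """Net vs gross oxygen flux across a material region's boundary.

    Sums the face fluxes G * dphi over every internal face separating the
    region (cells whose material is in ``materials``) from the rest.  At
    steady state the net must vanish relative to the gross exchange —
    the conservation statement that what diffuses into the aqueous layer
    leaves it again through the PDMS.
    """
    grid = field.grid
    phi = field.phi[-1] if field.is_transient else field.phi
    in_region = np.isin(grid.material, [int(m) for m in materials])
    gx, gz = _face_conductances(grid)

    net = 0.0
    gross = 0.0
    # horizontal faces crossing the region boundary
    cross = in_region[:, :-1] != in_region[:, 1:]
    sign = np.where(in_region[:, :-1], 1.0, -1.0)  # flux into region > 0
    f = gx * (phi[:, 1:] - phi[:, :-1]) * sign
    net += f[cross].sum()
    gross += np.abs(f[cross]).sum()
    # vertical faces
    cross = in_region[:-1, :] != in_region[1:, :]
    sign = np.where(in_region[:-1, :], 1.0, -1.0)
    f = gz * (phi[1:, :] - phi[:-1, :]) * sign
    net += f[cross].sum()
    gross += np.abs(f[cross]).sum()
    return {"net": float(net), "gross": float(gross)}


def slab_series_solution(thicknesses, permeabilities, phi_left, phi_right):
    """Closed-form steady profile through a 1-D stack of slabs.

    With fixed partial pressures at both ends, the flux is
    J = (phi_right - phi_left) / sum(t_i / k_i) and phi at each internal
    interface follows from the cumulative resistance.  Returns the
    interface values (including both ends), length n_slabs + 1.
    """
    t = np.asarray(thicknesses, dtype=float)
    k = np.asarray(permeabilities, dtype=float)
    R = t / k
    total = R.sum()
    cum = np.concatenate([[0.0], np.cumsum(R)])
    return phi_left + (phi_right - phi_left) * cum / total


def channel_axis_model(
    flow: FlowSpec,
    wall_value: float,
    inlet_value: float,
    length: float,
    k_ex: float | None = None,
    n_points: int = 201,
) -> pd.DataFrame:
    """Quasi-1-D axial oxygen profile in a flowing channel.

    Models the competition between axial advection and wall exchange:

        U dphi/dy = (k_ex / (S h)) (wall_value - phi)

    i.e. exponential relaxation toward the wall composition with decay
    length lambda = U S h / k_ex.  ``k_ex`` is an effective wall
    mass-transfer conductance per unit area; the default uses the
    half-channel diffusion resistance of the fluid, k_ex = k_fluid/(h/2),
    which reproduces the qualitative supply-rate thresholds (slow supply
    equilibrates with the walls; fast supply carries its inlet composition
    to the outlet).  Integrates numerically (RK4) — the closed form is the
    test oracle, not the implementation.
    """
    props = MATERIALS[flow.fluid]
    S, h = props.solubility, flow.height
    if k_ex is None:
        k_ex = props.permeability / (h / 2)
    y = np.linspace(0.0, length, n_points)
    if flow.U == 0:
        phi = np.full_like(y, wall_value)
        return pd.DataFrame({"y": y, "phi": phi})
    rate = k_ex / (S * h * flow.U)  # 1/lambda

    phi = np.empty_like(y)
    phi[0] = inlet_value
    f = lambda p: rate * (wall_value - p)
    for i in range(1, len(y)):
        dy = y[i] - y[i - 1]
        k1 = f(phi[i - 1])
        k2 = f(phi[i - 1] + 0.5 * dy * k1)
        k3 = f(phi[i - 1] + 0.5 * dy * k2)
        k4 = f(phi[i - 1] + dy * k3)
        phi[i] = phi[i - 1] + dy * (k1 + 2 * k2 + 2 * k3 + k4) / 6
    return pd.DataFrame({"y": y, "phi": phi})
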