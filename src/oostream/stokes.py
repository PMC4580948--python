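"""Incompressible Stokes flow driven by Kinesin forces on the MT network.

Cytoplasmic streaming in the stage 9 oocyte is creeping flow: with
viscosity >= that of water and the 0.5 um/s velocity scale, the Reynolds
number is bounded by 2.5e-4, so inertia is neglected and the steady Stokes
equations hold,

    0 = -grad p + lap u + f,    div u = 0,   f = a' * v_m,

in nondimensional form (pressure scale mu V / L, force scale mu V / L^2).
The volumetric force is proportional to the motor-velocity field with
coupling ``a'``; ``a' = 45`` (geometry-1) reproduces the experimentally
measured ~14.5 nm/s mean speeds.  No-slip holds on the oocyte surface and,
optionally, on a sphere representing the nucleus.

Discretization: marker-and-cell (MAC) staggered finite differences on the
cell grid, with the curved boundary represented by the staircase of interior
cells.  Velocity unknowns live on faces between two interior cells; all
other faces are no-slip.  The saddle-point system is solved exactly in the
discrete sense via the pressure Schur complement (Uzawa/CG) with sparse LU
factorizations of the three component Laplacians, which are cached so that
ensembles of force fields reuse one factorization.  Discrete divergence is
driven below 1e-10 of the velocity scale; flows are linear in ``a'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import splu

from .fields import CoarseGrid, MotorVelocityField
from .geometry import OocyteGeometry

__all__ = [
    "FlowParams",
    "FlowField",
    "StokesSolver",
    "solve_stokes",
    "calibrate_a_prime",
    "speed_stats",
]


@dataclass(frozen=True)
class FlowParams:
    """Physical scales and the force-velocity coupling.

    ``a_prime`` converts motor velocities to nondimensional force density.
    Scales: L = 50 um, V = 0.5 um/s, tau = L/V = 100 s.  The Reynolds bound
    uses water viscosity and 10x water density as worst cases.
    """

    a_prime: float = 45.0
    L_um: float = 50.0
    V_um_s: float = 0.5

    @property
    def tau_s(self) -> float:
        return self.L_um / self.V_um_s

    @property
    def reynolds_bound(self) -> float:
        rho, mu = 1.0e4, 1.0e-3  # kg/m^3, Pa s
        return rho * (self.V_um_s * 1e-6) * (self.L_um * 1e-6) / mu

    @property
    def V_nm_s(self) -> float:
        return self.V_um_s * 1e3


@dataclass
class FlowField:
    """Stokes solution sampled at cell centers of the coarse grid.

    ``velocity`` is the nondimensional u' (nx, ny, nz, 3); cells outside
    the domain hold zeros.  ``div_max`` records the maximal discrete
    divergence on the solver mesh.
    """

    grid: CoarseGrid
    velocity: np.ndarray
    mask: np.ndarray
    a_prime: float
    div_max: float
    pressure: np.ndarray | None = None


class StokesSolver:
    """MAC Stokes solver for one geometry/resolution; reusable across
    force fields.

    Parameters
    ----------
    geom : OocyteGeometry
    h : float
        Solver mesh spacing (nondimensional).  Defaults to the coarse-grid
        cell size 0.04.
    nucleus : tuple ((cx, cy, cz), r) or None
        Optional spherical excluded volume with no-slip surface.
    """

    def __init__(
        self,
        geom: OocyteGeometry,
        h: float = 0.04,
        nucleus: tuple[tuple[float, float, float], float] | None = None,
    ) -> None:
        self.geom = geom
        self.h = h
        self.grid = CoarseGrid(geom, dG=h)
        mask = self.grid.interior_mask()
        if nucleus is not None:
            (cx, cy, cz), r = nucleus
            centers = self.grid.centers()
            d2 = (
                (centers[..., 0] - cx) ** 2
                + (centers[..., 1] - cy) ** 2
                + (centers[..., 2] - cz) ** 2
            )
            mask &= d2 > r**2
        self.mask = mask
        self.nucleus = nucleus
        self._assemble()

    # -- assembly ----------------------------------------------------------

    def _assemble(self) -> None:
        h, mask = self.h, self.mask
        shape = mask.shape
        ncell = int(mask.sum())
        cell_id = -np.ones(shape, dtype=np.int64)
        cell_id[mask] = np.arange(ncell)
        self._cell_id = cell_id
        self._ncell = ncell

        self._face_idx = []  # per axis: (N_faces, 3) index of the minus-side cell
        self._face_id = []  # per axis: lattice of face ids, -1 where no-slip
        self._lap_lu = []
        div_rows, div_cols, div_vals = [], [], []

        for ax in range(3):
            # interior faces: between interior cell pairs along axis ax
            lo = mask.take(range(0, shape[ax] - 1), axis=ax)
            hi = mask.take(range(1, shape[ax]), axis=ax)
            fmask = lo & hi
            fshape = fmask.shape
            nfaces = int(fmask.sum())
            fid = -np.ones(fshape, dtype=np.int64)
            fid[fmask] = np.arange(nfaces)
            self._face_id.append(fid)
            self._face_idx.append(np.argwhere(fmask))

            # component Laplacian (7-point, Dirichlet 0 on missing neighbours)
            rows, cols, vals = [], [], []
            ids = fid[fmask]
            rows.append(ids)
            cols.append(ids)
            vals.append(np.full(nfaces, 6.0 / h**2))
            coords = np.argwhere(fmask)
            for d in range(3):
                for step in (-1, 1):
                    nb = coords.copy()
                    nb[:, d] += step
                    ok = (nb[:, d] >= 0) & (nb[:, d] < fshape[d])
                    nb_ids = np.full(nfaces, -1, dtype=np.int64)
                    nb_ids[ok] = fid[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
                    good = nb_ids >= 0
                    rows.append(ids[good])
                    cols.append(nb_ids[good])
                    vals.append(np.full(good.sum(), -1.0 / h**2))
                    if d != ax:
                        # tangential wall at h/2: reflected ghost u_g = -u
                        # stiffens the diagonal by 1/h^2 per missing side
                        wall = ~good
                        rows.append(ids[wall])
                        cols.append(ids[wall])
                        vals.append(np.full(wall.sum(), 1.0 / h**2))
            A = sp.csc_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(nfaces, nfaces),
            )
            self._lap_lu.append(splu(A))

            # divergence: cell c gets +u(face at + side)/h, -u(face at - side)/h
            coords_c = np.argwhere(mask)
            cids = cell_id[mask]
            minus = coords_c.copy()
            minus[:, ax] -= 1
            okm = minus[:, ax] >= 0
            fm = np.full(ncell, -1, dtype=np.int64)
            fm[okm] = fid[minus[okm, 0], minus[okm, 1], minus[okm, 2]]
            fp = np.full(ncell, -1, dtype=np.int64)
            inb = coords_c[:, ax] <= fshape[ax] - 1
            sel = coords_c[inb]
            fp[inb] = fid[sel[:, 0], sel[:, 1], sel[:, 2]]
            good = fp >= 0
            div_rows.append(cids[good])
            div_cols.append(fp[good] + self._axis_offset(ax))
            div_vals.append(np.full(good.sum(), 1.0 / h))
            good = fm >= 0
            div_rows.append(cids[good])
            div_cols.append(fm[good] + self._axis_offset(ax))
            div_vals.append(np.full(good.sum(), -1.0 / h))

        nf_total = sum(f.shape[0] for f in self._face_idx)
        self._B = sp.csr_matrix(
            (
                np.concatenate(div_vals),
                (np.concatenate(div_rows), np.concatenate(div_cols)),
            ),
            shape=(ncell, nf_total),
        )

    def _axis_offset(self, ax: int) -> int:
        return sum(self._face_idx[a].shape[0] for a in range(ax))

    def _apply_Ainv(self, v: np.ndarray) -> np.ndarray:
        out = np.empty_like(v)
        for ax in range(3):
            o = self._axis_offset(ax)
            n = self._face_idx[ax].shape[0]
            out[o : o + n] = self._lap_lu[ax].solve(v[o : o + n])
        return out

    # -- solve -------------------------------------------------------------

    def _face_forces(self, motor: MotorVelocityField, a_prime: float) -> np.ndarray:
        """Trilinear interpolation of the cell-centered force a'*v_m to the
        staggered face centers."""
        x, y, z = motor.grid.axes()
        axes_solver = self.grid.axes()
        h = self.h
        parts = []
        for ax in range(3):
            interp = RegularGridInterpolator(
                (x, y, z), motor.vectors[..., ax], bounds_error=False, fill_value=0.0
            )
            idx = self._face_idx[ax]
            pts = np.empty((idx.shape[0], 3))
            for d in range(3):
                coord = axes_solver[d][idx[:, d]]
                if d == ax:
                    coord = coord + h / 2.0
                pts[:, d] = coord
            parts.append(a_prime * interp(pts))
        return np.concatenate(parts)

    def solve(
        self,
        motor: MotorVelocityField,
        a_prime: float = 45.0,
        tol: float = 1e-12,
        max_iter: int = 800,
    ) -> FlowField:
        """Solve steady Stokes with f' = a' * v_m'; returns cell-centered u'.

        Uzawa/CG on the pressure Schur complement ``B A^-1 B^T``; raises if
        the divergence tolerance is not reached.
        """
        f = self._face_forces(motor, a_prime)
        if not np.any(f):
            u_faces = np.zeros_like(f)
            p = np.zeros(self._ncell)
        else:
            B = self._B
            Ainv_f = self._apply_Ainv(f)
            # continuity B u = B A^-1 (f + B^T p) = 0  =>  S p = -B A^-1 f
            rhs = -(B @ Ainv_f)
            p = np.zeros(self._ncell)
            r = rhs.copy()
            d = r.copy()
            rr = r @ r
            rhs_norm = np.sqrt(rr)
            for _ in range(max_iter):
                if np.sqrt(rr) <= tol * max(rhs_norm, 1e-300):
                    break
                Sd = B @ self._apply_Ainv(B.T @ d)
                alpha = rr / (d @ Sd)
                p += alpha * d
                r -= alpha * Sd
                rr_new = r @ r
                d = r + (rr_new / rr) * d
                rr = rr_new
            p -= p.mean()
            u_faces = self._apply_Ainv(f + B.T @ p)
            div = B @ u_faces
            div_max = float(np.max(np.abs(div)))
            # the force term covers hydrostatically balanced loads, whose
            # velocity vanishes but whose pressure leaves round-off in div
            allowed = 1e-6 * float(np.max(np.abs(u_faces))) + 1e-9 * float(
                np.max(np.abs(f))
            )
            if div_max > allowed:
                raise RuntimeError(
                    f"Stokes solve did not converge: max|div u| = {div_max:.3e} "
                    f"vs velocity scale {scale:.3e}"
                )
            return self._package(u_faces, p, a_prime, div_max)
        return self._package(u_faces, p, a_prime, 0.0)

    def _package(self, u_faces, p, a_prime, div_max) -> FlowField:
        shape = self.mask.shape
        vel = np.zeros(shape + (3,))
        for ax in range(3):
            o = self._axis_offset(ax)
            n = self._face_idx[ax].shape[0]
            lattice = np.zeros(np.array(shape) - np.eye(3, dtype=int)[ax])
            fid = self._face_id[ax]
            lattice[fid >= 0] = u_faces[o : o + n][fid[fid >= 0]]
            # average the two faces of each cell (missing faces are no-slip 0)
            lo = np.zeros(shape)
            hi = np.zeros(shape)
            sl_lo = [slice(None)] * 3
            sl_lo[ax] = slice(1, None)
            lo[tuple(sl_lo)] = lattice
            sl_hi = [slice(None)] * 3
            sl_hi[ax] = slice(0, shape[ax] - 1)
            hi[tuple(sl_hi)] = lattice
            vel[..., ax] = 0.5 * (lo + hi)
        vel[~self.mask] = 0.0
        press = np.full(shape, np.nan)
        press[self.mask] = p
        return FlowField(
            grid=self.grid,
            velocity=vel,
            mask=self.mask,
            a_prime=a_prime,
            div_max=div_max,
            pressure=press,
        )


def solve_stokes(
    motor: MotorVelocityField,
    a_prime: float = 45.0,
    geom: OocyteGeometry | None = None,
    h: float | None = None,
    nucleus=None,
    solver: StokesSolver | None = None,
) -> FlowField:
    """One-shot Stokes solve; build (or reuse) a solver and run it."""
    if solver is None:
        geom = geom if geom is not None else motor.grid.geometry
        solver = StokesSolver(geom, h=h if h is not None else motor.grid.dG, nucleus=nucleus)
    return solver.solve(motor, a_prime)


def _volume_weights(grid: CoarseGrid, n_sub: int = 3) -> np.ndarray:
    """Fraction of each cell's volume inside the smooth oocyte surface,
    estimated by subsampling ``n_sub^3`` points per cell.

    Used to turn cell averages into quadratures of (1/V) int |u| dV over
    the true curved domain: boundary-straddling cells enter with partial
    weight (their velocities are near-wall and small), instead of the
    all-or-nothing staircase of cell-center masking.
    """
    centers = grid.centers()
    offs = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    w = np.zeros(grid.shape)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                pts = centers + grid.dG * np.array([ox, oy, oz])
                w += grid.geometry.contains(pts)
    return w / n_sub**3


def speed_stats(
    flows: FlowField | list[FlowField],
    mode: str = "3D",
    params: FlowParams | None = None,
) -> dict:
    """Mean/sd of dimensional speeds (nm/s), volume-weighted over the
    smooth domain.

    ``mode='3D'``: |u| over the oocyte volume.  ``mode='2D'``: |u| over
    the mid cross-section plane y ~ 0 (the speeds a confocal section of
    the 3D field shows); ``mode='2D-inplane'``: same plane but only the
    in-plane (x, z) components, what particle-image velocimetry of that
    plane would measure.
    """
    if params is None:
        params = FlowParams()
    if isinstance(flows, FlowField):
        flows = [flows]
    weights = _volume_weights(flows[0].grid)
    per_field = []
    for fl in flows:
        if mode == "3D":
            mags = np.linalg.norm(fl.velocity, axis=-1)
            w = weights
        elif mode in ("2D", "2D-inplane"):
            _, y, _ = fl.grid.axes()
            j = int(np.argmin(np.abs(y)))
            v = fl.velocity[:, j, :, :]
            if mode == "2D":
                mags = np.linalg.norm(v, axis=-1)
            else:
                mags = np.hypot(v[..., 0], v[..., 2])
            w = weights[:, j, :]
        else:
            raise ValueError("mode must be '3D', '2D' or '2D-inplane'")
        per_field.append(np.sum(w * mags) / np.sum(w) * params.V_nm_s)
    per_field = np.asarray(per_field)
    return {
        "mean_nm_s": float(per_field.mean()),
        "sd_nm_s": float(per_field.std(ddof=1)) if per_field.size > 1 else 0.0,
        "n_fields": per_field.size,
    }


def calibrate_a_prime(
    motors: list[MotorVelocityField],
    target_nm_s: float,
    solver: StokesSolver,
    a0: float = 45.0,
    mode: str = "3D",
    params: FlowParams | None = None,
) -> dict:
    """Coupling a' that makes the ensemble mean speed match the target.

    Stokes is linear in the force, so one solve per field at a reference
    coupling suffices: ``a' = a0 * target / speed(a0)``.
    """
    if not motors:
        raise ValueError("need at least one motor field")
    if target_nm_s <= 0:
        raise ValueError("target speed must be positive")
    flows = [solver.solve(m, a0) for m in motors]
    achieved = speed_stats(flows, mode=mode, params=params)["mean_nm_s"]
    if achieved == 0.0:
        raise ValueError("zero flow speed at reference coupling; empty forcing?")
    a_cal = a0 * target_nm_s / achieved
    return {
        "a_prime": float(a_cal),
        "reference_a": a0,
        "reference_speed_nm_s": achieved,
        "target_nm_s": target_nm_s,
        "n_fields": len(motors),
    }
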