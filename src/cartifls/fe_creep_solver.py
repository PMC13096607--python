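"""Axisymmetric displacement/pore-pressure FE solver for unconfined creep.

Solves the coupled finite-strain Biot problem for a cartilage layer
compressed by a rigid impermeable platen at constant axial load:

* total Cauchy stress = Neo-Hookean matrix + tension-only viscoelastic
  fibril network - pore pressure,
* Darcy flow with deformation-dependent permeability k = k0 J^M,
* fluid continuity dJ/dt = Div( J k C^{-1} Grad p ) in the reference
  configuration.

Discretization: structured bilinear quadrilateral elements with
equal-order interpolation for displacement and pressure (the classic
4-node axisymmetric pore-pressure element), 2x2 Gauss quadrature,
backward-Euler time stepping and Newton iteration.  Equal-order u/p
pairs require pressure stabilization at time steps short compared to
the element consolidation time; a local pressure-projection term
(Bochev-Dohrmann type, scaled by ``stab_alpha / 2G``) acting on the
pressure increment is used.

Boundary conditions (defaults):

* bottom (cartilage-bone): fixed in both directions, impermeable;
* axis of symmetry: zero radial displacement, zero flux;
* outer edge: traction-free, free-draining (p = 0);
* top: rigid impermeable platen — every surface node shares one axial
  degree of freedom, radial slip is free (frictionless), and the axial
  load is applied to the shared degree of freedom as a linear ramp
  followed by a constant hold.

The element tangent is obtained by forward differencing the element
residual with respect to its 12 degrees of freedom, batched over all
elements at once; this linearizes the viscoelastic update and the
tension gate consistently without hand-derived moduli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .constitutive import FibrilNetworkLayout, MaterialParams

__all__ = [
    "Geometry",
    "LoadingProtocol",
    "SolverOptions",
    "Mesh",
    "CreepSolution",
    "build_mesh",
    "run_creep",
    "SolverError",
]

_MM = 1.0e-3
_MPA = 1.0e6


class SolverError(RuntimeError):
    """Newton failure that survived time-step halving, or element inversion."""


@dataclass
class Geometry:
    """Plug geometry: radius and effective layer thickness [mm].

    ``thickness`` is the average thickness of the two articulating
    plugs; ``n_r`` x ``n_z`` structured elements (default 60 x 40 =
    2,400 elements).
    """

    radius: float = 3.5
    thickness: float = 1.7
    n_r: int = 60
    n_z: int = 40

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.thickness <= 0:
            raise ValueError("radius and thickness must be positive")
        if self.n_r < 1 or self.n_z < 1:
            raise ValueError("element counts must be >= 1")


@dataclass
class LoadingProtocol:
    """Creep loading: linear force ramp to ``applied_stress`` then hold.

    applied_stress [MPa] (nominal load / plug area), ramp_duration [s],
    hold_duration [s] = total simulated time, output_times optional
    monotone sampling grid [s].
    """

    applied_stress: float = 0.78
    ramp_duration: float = 0.5
    hold_duration: float = 10_000.0
    output_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.applied_stress <= 0:
            raise ValueError("applied_stress must be > 0")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be > 0")
        if self.hold_duration <= self.ramp_duration:
            raise ValueError("hold_duration must exceed ramp_duration")
        if self.output_times is not None:
            ot = np.asarray(self.output_times, dtype=float)
            if ot.ndim != 1 or np.any(np.diff(ot) <= 0):
                raise ValueError("output_times must be strictly increasing")
            self.output_times = ot


@dataclass
class SolverOptions:
    """Numerical controls; every default is deliberate and documented
    in the package methods note."""

    dt0: float = 0.01                 # first time step [s]
    dt_growth: float = 1.3            # geometric step growth
    max_dt: float = 100.0             # cap on the step [s]
    rtol: float = 1e-6                # Newton: scaled residual tolerance
    newton_max_iter: int = 30
    max_step_halvings: int = 20
    stab_alpha: float = 1.0           # pressure-projection magnitude
    frictionless_base: bool = False   # bottom slip (oracle comparisons)
    por_mode: str = "surface"         # "surface" | "volume" average
    small_strain: bool = False        # linear kinematics (oracle mode)
    reuse_tangent: bool = True        # modified Newton across iterations
    tangent_refresh_iters: int = 3    # rebuild tangent after this many iters
    equilibrium_rate: Optional[float] = None  # stop when |du/dt| < rate [m/s]
    max_extend_factor: float = 10.0   # allowed extension of the hold
    max_steps: Optional[int] = None   # accepted-step budget (None = unlimited)
    layout: FibrilNetworkLayout = field(default_factory=FibrilNetworkLayout)
    fd_eps_u: float = 1e-9            # tangent FD step, displacement [m]
    fd_eps_p: float = 1.0             # tangent FD step, pressure [Pa]


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Structured quadrilateral mesh of the meridional section.

    Nodes ordered row-major in z; element node order counterclockwise
    starting at the lower-left corner.  Boundary tags are node-index
    arrays.
    """

    coords: np.ndarray          # (n_nodes, 2) reference (R, Z) [m]
    elements: np.ndarray        # (n_el, 4) node ids
    axis_nodes: np.ndarray
    outer_nodes: np.ndarray
    bottom_nodes: np.ndarray
    top_nodes: np.ndarray
    n_r: int
    n_z: int

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)


def build_mesh(geometry: Geometry) -> Mesh:
    """Build the structured mesh spanning [0, radius] x [0, thickness]."""
    n_r, n_z = geometry.n_r, geometry.n_z
    R = np.linspace(0.0, geometry.radius * _MM, n_r + 1)
    Z = np.linspace(0.0, geometry.thickness * _MM, n_z + 1)
    RR, ZZ = np.meshgrid(R, Z, indexing="xy")  # rows: z, cols: r
    coords = np.column_stack([RR.ravel(), ZZ.ravel()])

    def nid(ir: int | np.ndarray, iz: int | np.ndarray):
        return iz * (n_r + 1) + ir

    ir, iz = np.meshgrid(np.arange(n_r), np.arange(n_z), indexing="xy")
    ir, iz = ir.ravel(), iz.ravel()
    elements = np.column_stack([
        nid(ir, iz), nid(ir + 1, iz), nid(ir + 1, iz + 1), nid(ir, iz + 1)])

    all_ir = np.arange(n_r + 1)
    all_iz = np.arange(n_z + 1)
    return Mesh(
        coords=coords,
        elements=elements.astype(np.int64),
        axis_nodes=nid(0, all_iz),
        outer_nodes=nid(n_r, all_iz),
        bottom_nodes=nid(all_ir, 0),
        top_nodes=nid(all_ir, n_z),
        n_r=n_r,
        n_z=n_z,
    )


# ---------------------------------------------------------------------------
# Solution container
# ---------------------------------------------------------------------------

@dataclass
class CreepSolution:
    """Time history of one creep simulation.

    Scalar series are sampled at the accepted solver steps (or at
    ``protocol.output_times`` when given); ``pore_pressure_field`` holds
    the nodal pressure [MPa] at the same times.  Displacement and
    strain are compressive magnitudes.
    """

    times: np.ndarray                 # [s]
    axial_displacement: np.ndarray    # [mm], >= 0
    axial_strain: np.ndarray          # displacement / thickness
    por: np.ndarray                   # average pore pressure [MPa]
    ifls: np.ndarray                  # POR / applied_stress
    reaction_force: np.ndarray        # [N]
    pore_pressure_field: np.ndarray   # (n_t, n_nodes) [MPa]
    mesh: Mesh
    geometry: Geometry
    protocol: LoadingProtocol
    params: MaterialParams
    diagnostics: dict

    def _interp(self, series: np.ndarray, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("requested times outside the solution span")
        return np.interp(t, self.times, series)

    def displacement_at(self, t) -> np.ndarray:
        return self._interp(self.axial_displacement, t)

    def strain_at(self, t) -> np.ndarray:
        return self._interp(self.axial_strain, t)

    def ifls_at(self, t) -> np.ndarray:
        return self._interp(self.ifls, t)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy export: time, displacement, strain, POR, IFLS, reaction."""
        return pd.DataFrame({
            "time_s": self.times,
            "displacement_mm": self.axial_displacement,
            "strain": self.axial_strain,
            "por_MPa": self.por,
            "ifls": self.ifls,
            "reaction_N": self.reaction_force,
        })


# ---------------------------------------------------------------------------
# Element machinery
# ---------------------------------------------------------------------------

_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
_GW = np.ones(4)
_CORNERS = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def _shape_functions():
    """Bilinear shape functions and local gradients at the Gauss points."""
    xi, eta = _GP[:, 0][:, None], _GP[:, 1][:, None]
    cx, ce = _CORNERS[:, 0][None, :], _CORNERS[:, 1][None, :]
    N = 0.25 * (1 + xi * cx) * (1 + eta * ce)            # (4gp, 4n)
    dN = np.empty((4, 4, 2))
    dN[:, :, 0] = 0.25 * cx * (1 + eta * ce)
    dN[:, :, 1] = 0.25 * ce * (1 + xi * cx)
    return N, dN


class _FEWork:
    """Precomputed mesh/quadrature data and constraint maps for one run."""

    def __init__(self, mesh: Mesh, params: MaterialParams,
                 opts: SolverOptions, applied_stress_pa: float):
        self.mesh = mesh
        self.opts = opts
        n_nodes = mesh.n_nodes
        self.n_nodes = n_nodes
        X = mesh.coords[mesh.elements]          # (n_el, 4, 2)
        N, dN = _shape_functions()
        self.N = N
        # reference Jacobian per element/gp
        Jref = np.einsum("eak,gaj->egkj", X, dN)        # (n_el,4gp,2,2)
        detJ = (Jref[..., 0, 0] * Jref[..., 1, 1]
                - Jref[..., 0, 1] * Jref[..., 1, 0])
        if np.any(detJ <= 0):
            raise SolverError("degenerate reference element")
        inv = np.empty_like(Jref)
        inv[..., 0, 0] = Jref[..., 1, 1]
        inv[..., 0, 1] = -Jref[..., 0, 1]
        inv[..., 1, 0] = -Jref[..., 1, 0]
        inv[..., 1, 1] = Jref[..., 0, 0]
        inv /= detJ[..., None, None]
        self.dNdX = np.einsum("gak,egkj->egaj", dN, inv)  # (n_el,4gp,4,2)
        self.Rg = np.einsum("ga,ea->eg", N, X[..., 0])    # gp radii
        self.wv = _GW[None, :] * detJ * 2.0 * np.pi * self.Rg  # gp ref volume
        self.Vel = self.wv.sum(axis=1)
        self.V_total = float(self.Vel.sum())

        # material constants, SI
        self.mu_s = params.mu_s
        self.lam_s = params.lambda_s
        self.Ef0 = params.E_f0 * _MPA
        self.Efeps = params.E_feps * _MPA
        self.eta = params.eta_fibril * _MPA
        self.k0 = params.k0
        self.Mexp = params.M
        layout = opts.layout
        dirs = layout.directions
        self.w_dir = layout.weights
        self.dir_r = dirs[:, 0]
        self.dir_z = dirs[:, 1]
        self.dir_t = dirs[:, 2]
        self.n_dir = len(dirs)
        # pressure-projection scale: representative shear stiffness
        self.G_stab = self.mu_s + 0.5 * self.Ef0 + 1e3

        # dof maps -------------------------------------------------------
        el = mesh.elements
        self.el_dofs = np.concatenate(
            [el, el + n_nodes, el + 2 * n_nodes], axis=1)  # (n_el, 12)

        n_full = 3 * n_nodes
        red = np.full(n_full, -1, dtype=np.int64)
        fixed = np.zeros(n_full, dtype=bool)
        # u_r fixed on axis; and on bottom unless frictionless base
        fixed[mesh.axis_nodes] = True
        if not opts.frictionless_base:
            fixed[mesh.bottom_nodes] = True
        # u_z fixed on bottom
        fixed[n_nodes + mesh.bottom_nodes] = True
        # p fixed (0) on outer edge
        fixed[2 * n_nodes + mesh.outer_nodes] = True
        # platen tie: top u_z dofs share one reduced dof
        top_uz = n_nodes + mesh.top_nodes
        nxt = 0
        self.platen_red = nxt
        nxt += 1
        red[top_uz] = self.platen_red
        for d in range(n_full):
            if red[d] == -1 and not fixed[d]:
                red[d] = nxt
                nxt += 1
        self.n_red = nxt
        keep = red >= 0
        self.T = sp.csr_matrix(
            (np.ones(keep.sum()), (np.nonzero(keep)[0], red[keep])),
            shape=(n_full, self.n_red))
        self.red = red
        self.n_full = n_full

        # COO index pattern for the tangent
        rows_k = np.broadcast_to(self.el_dofs[:, :, None],
                                 (mesh.n_elements, 12, 12))
        cols_k = np.broadcast_to(self.el_dofs[:, None, :],
                                 (mesh.n_elements, 12, 12))
        self.k_rows = rows_k.ravel()
        self.k_cols = cols_k.ravel()

        # FD steps per element dof
        self.fd_delta = np.concatenate([
            np.full(8, opts.fd_eps_u), np.full(4, opts.fd_eps_p)])

        # platen contact-surface weights for POR (reference annuli)
        top = mesh.top_nodes
        w = np.zeros(len(top))
        Rtop = mesh.coords[top, 0]
        for s in range(len(top) - 1):
            r1, r2 = Rtop[s], Rtop[s + 1]
            h = r2 - r1
            # 2-pt Gauss, exact for the linear-in-R integrand x R
            for xi, wq in ((-1 / np.sqrt(3), 1.0), (1 / np.sqrt(3), 1.0)):
                Rq = 0.5 * (r1 + r2) + 0.5 * h * xi
                N1 = (r2 - Rq) / h
                w[s] += wq * 0.5 * h * 2 * np.pi * Rq * N1
                w[s + 1] += wq * 0.5 * h * 2 * np.pi * Rq * (1 - N1)
        self.top_weights = w
        self.area = np.pi * (mesh.coords[:, 0].max()) ** 2
        self.sigma_ref = applied_stress_pa
        self.F_ref = applied_stress_pa * self.area
        # mass-residual scale: total volume x representative strain
        H_ref = self.lam_s + 2 * self.mu_s + self.Ef0 + 1e3
        self.Q_ref = self.V_total * applied_stress_pa / H_ref
        # reduced dofs belonging to the pressure block
        mask_p = np.zeros(self.n_full)
        mask_p[2 * n_nodes:] = 1.0
        self.red_is_p = (self.T.T @ mask_p) > 0.5

    # -- residual ---------------------------------------------------------
    def element_residual(self, d, state, dt):
        """Element residual vectors, broadcasting over leading axes of ``d``.

        ``d``: (..., n_el, 12) element dof values [m, m, Pa].
        ``state``: dict with committed J, fibril strain/overstress and
        nodal pressure of the previous step.
        Returns (..., n_el, 12) residuals and the trial state arrays
        (J, eps_f, q) evaluated at ``d`` (leading axes preserved).
        """
        N, dNdX, Rg = self.N, self.dNdX, self.Rg
        ur = d[..., 0:4]
        uz = d[..., 4:8]
        pe = d[..., 8:12]
        u = np.stack([ur, uz], axis=-1)                     # (...,e,4,2)
        Gu = np.einsum("egaj,...eai->...egij", dNdX, u)     # (...,e,g,2,2)
        ur_gp = np.einsum("ga,...ea->...eg", N, ur)
        p_gp = np.einsum("ga,...ea->...eg", N, pe)

        mu, lam = self.mu_s, self.lam_s
        small = self.opts.small_strain

        if small:
            e11 = Gu[..., 0, 0]
            e22 = Gu[..., 1, 1]
            e12 = 0.5 * (Gu[..., 0, 1] + Gu[..., 1, 0])
            ett = ur_gp / Rg
            tr = e11 + e22 + ett
            J = 1.0 + tr
            s11 = lam * tr + 2 * mu * e11
            s22 = lam * tr + 2 * mu * e22
            s12 = 2 * mu * e12
            stt = lam * tr + 2 * mu * ett
            eps_d = (self.dir_r**2 * e11[..., None]
                     + self.dir_z**2 * e22[..., None]
                     + 2 * self.dir_r * self.dir_z * e12[..., None]
                     + self.dir_t**2 * ett[..., None])
        else:
            F11 = 1.0 + Gu[..., 0, 0]
            F12 = Gu[..., 0, 1]
            F21 = Gu[..., 1, 0]
            F22 = 1.0 + Gu[..., 1, 1]
            Ft = 1.0 + ur_gp / Rg
            detF2 = F11 * F22 - F12 * F21
            J = detF2 * Ft
            if np.any(J <= 0.05):
                raise SolverError("element inversion (J <= 0)")
            lnJ = np.log(J)
            # Neo-Hookean
            s11 = (mu / J) * (F11**2 + F12**2 - 1.0) + (lam / J) * lnJ
            s22 = (mu / J) * (F21**2 + F22**2 - 1.0) + (lam / J) * lnJ
            s12 = (mu / J) * (F11 * F21 + F12 * F22)
            stt = (mu / J) * (Ft**2 - 1.0) + (lam / J) * lnJ
            # fibril line elements
            m1 = F11[..., None] * self.dir_r + F12[..., None] * self.dir_z
            m2 = F21[..., None] * self.dir_r + F22[..., None] * self.dir_z
            mt = Ft[..., None] * self.dir_t
            lam2 = m1**2 + m2**2 + mt**2
            eps_d = 0.5 * np.log(lam2)

        # viscoelastic fibril update (tension-only gate)
        E_tan = self.Ef0 + self.Efeps * eps_d
        d_eps = eps_d - np.maximum(state["eps_f"], 0.0)
        q = (state["q"] + E_tan * d_eps) / (1.0 + dt * E_tan / self.eta)
        sig_eq = self.Ef0 * eps_d + 0.5 * self.Efeps * eps_d**2
        active = eps_d > 0.0
        sig_d = np.where(active, sig_eq + q, 0.0)
        q = np.where(active, q, 0.0)

        if small:
            coef = self.w_dir * sig_d
            sf11 = np.sum(coef * self.dir_r**2, axis=-1)
            sf22 = np.sum(coef * self.dir_z**2, axis=-1)
            sf12 = np.sum(coef * self.dir_r * self.dir_z, axis=-1)
            sftt = np.sum(coef * self.dir_t**2, axis=-1)
        else:
            coef = self.w_dir * sig_d / lam2
            sf11 = np.sum(coef * m1 * m1, axis=-1)
            sf22 = np.sum(coef * m2 * m2, axis=-1)
            sf12 = np.sum(coef * m1 * m2, axis=-1)
            sftt = np.sum(coef * mt * mt, axis=-1)

        t11 = s11 + sf11 - p_gp
        t22 = s22 + sf22 - p_gp
        t12 = s12 + sf12
        ttt = stt + sftt - p_gp

        if small:
            P11, P12, P21, P22, Pt = t11, t12, t12, t22, ttt
        else:
            idet = 1.0 / detF2
            iT11 = F22 * idet
            iT12 = -F21 * idet
            iT21 = -F12 * idet
            iT22 = F11 * idet
            P11 = J * (t11 * iT11 + t12 * iT21)
            P12 = J * (t11 * iT12 + t12 * iT22)
            P21 = J * (t12 * iT11 + t22 * iT21)
            P22 = J * (t12 * iT12 + t22 * iT22)
            Pt = J * ttt / Ft

        wv = self.wv
        f_ur = (np.einsum("...eg,ega->...ea", wv * P11, dNdX[..., 0])
                + np.einsum("...eg,ega->...ea", wv * P12, dNdX[..., 1])
                + np.einsum("...eg,ga->...ea", wv * Pt / Rg, N))
        f_uz = (np.einsum("...eg,ega->...ea", wv * P21, dNdX[..., 0])
                + np.einsum("...eg,ega->...ea", wv * P22, dNdX[..., 1]))

        # mass balance (integrated over the step)
        Gp = np.einsum("egaj,...ea->...egj", dNdX, pe)
        kq = self.k0 * J**self.Mexp
        if small:
            v0 = kq * Gp[..., 0]
            v1 = kq * Gp[..., 1]
        else:
            # J k C^{-1} Grad p with C = F^T F (theta block decouples)
            d2 = detF2**2
            ic11 = (F22**2 + F12**2) / d2
            ic12 = -(F22 * F21 + F12 * F11) / d2
            ic22 = (F21**2 + F11**2) / d2
            v0 = J * kq * (ic11 * Gp[..., 0] + ic12 * Gp[..., 1])
            v1 = J * kq * (ic12 * Gp[..., 0] + ic22 * Gp[..., 1])
        f_p = (np.einsum("...eg,ga->...ea", wv * (J - state["J"]), N)
               + dt * (np.einsum("...eg,ega->...ea", wv * v0, dNdX[..., 0])
                       + np.einsum("...eg,ega->...ea", wv * v1, dNdX[..., 1])))

        # local pressure projection on the increment
        alpha = self.opts.stab_alpha
        if alpha > 0.0:
            dp_gp = p_gp - np.einsum("ga,ea->eg", N,
                                     state["p_nodal"][self.mesh.elements])
            dp_bar = np.einsum("eg,...eg->...e", wv, dp_gp) / self.Vel
            Nbar = np.einsum("eg,ga->ea", wv, N) / self.Vel[:, None]
            fluct_p = dp_gp - dp_bar[..., None]
            f_p = f_p + (alpha / (2.0 * self.G_stab)) * np.einsum(
                "...eg,ega->...ea", wv * fluct_p,
                (N[None, :, :] - Nbar[:, None, :]))

        r = np.concatenate([f_ur, f_uz, f_p], axis=-1)
        return r, {"J": J, "eps_f": eps_d, "q": q}

    def assemble_residual(self, x_full, state, dt):
        d = x_full[self.el_dofs]                        # (n_el, 12)
        r, trial = self.element_residual(d, state, dt)
        R = np.zeros(self.n_full)
        np.add.at(R, self.el_dofs, r)
        return R, r, trial

    def assemble_tangent(self, x_full, state, dt, r0):
        d0 = x_full[self.el_dofs]
        pert = d0[None, :, :] + (np.eye(12)[:, None, :]
                                 * self.fd_delta[:, None, None])
        r_pert, _ = self.element_residual(pert, state, dt)
        # K_el[e, i, j] = dR_i/dd_j
        K_el = (r_pert - r0[None]) / self.fd_delta[:, None, None]
        K_el = np.moveaxis(K_el, 0, 2)                  # (n_el, 12, 12)
        K = sp.coo_matrix((K_el.ravel(), (self.k_rows, self.k_cols)),
                          shape=(self.n_full, self.n_full)).tocsr()
        return (self.T.T @ K @ self.T).tocsc()

    # -- derived quantities ----------------------------------------------
    def por(self, p_nodal: np.ndarray) -> float:
        if self.opts.por_mode == "volume":
            p_el = p_nodal[self.mesh.elements]
            p_gp = np.einsum("ga,ea->eg", self.N, p_el)
            return float(np.sum(self.wv * p_gp) / self.V_total)
        w = self.top_weights
        return float(w @ p_nodal[self.mesh.top_nodes] / w.sum())

    def reaction(self, R_int_full: np.ndarray) -> float:
        """Axial reaction transmitted through the platen [N]."""
        return float(-np.sum(R_int_full[self.n_nodes + self.mesh.top_nodes]))

    def edge_outflow(self, x_full: np.ndarray) -> float:
        """Darcy volume outflow [m^3/s] through the free-draining edge,
        post-processed from the FE pressure gradient at the Gauss points
        of the outermost element column (independent of the residual's
        constrained-row fluxes)."""
        mesh = self.mesh
        col = np.arange(mesh.n_elements).reshape(mesh.n_z, mesh.n_r)[:, -1]
        d = x_full[self.el_dofs[col]]
        pe = d[:, 8:12]
        Gp = np.einsum("egaj,ea->egj", self.dNdX[col], pe)
        # outer-face area per element: 2 pi R * dz; use gp pairs nearest edge
        Redge = mesh.coords[mesh.outer_nodes[0], 0]
        z = mesh.coords[mesh.elements[col][:, [0, 3]], 1]
        dz = z[:, 1] - z[:, 0]
        ur = d[:, 0:4]
        uz = d[:, 4:8]
        u = np.stack([ur, uz], axis=-1)
        Gu = np.einsum("egaj,eai->egij", self.dNdX[col], u)
        ur_gp = np.einsum("ga,ea->eg", self.N, ur)
        if self.opts.small_strain:
            J = 1.0 + Gu[..., 0, 0] + Gu[..., 1, 1] + ur_gp / self.Rg[col]
            dpdr = Gp[..., 0]
        else:
            F11 = 1.0 + Gu[..., 0, 0]
            F12 = Gu[..., 0, 1]
            F21 = Gu[..., 1, 0]
            F22 = 1.0 + Gu[..., 1, 1]
            Ft = 1.0 + ur_gp / self.Rg[col]
            J = (F11 * F22 - F12 * F21) * Ft
            dpdr = Gp[..., 0]
        kq = self.k0 * J**self.Mexp
        q_r = -kq * dpdr                      # Darcy flux w_r = -k dp/dr
        # Gauss points at xi = -+1/sqrt(3): cols (0,3) inner, (1,2) outer;
        # the flux is linear in xi within the element, so extrapolate to
        # the face (xi = 1) exactly
        q_in = 0.5 * (q_r[:, 0] + q_r[:, 3])
        q_out = 0.5 * (q_r[:, 1] + q_r[:, 2])
        s3 = np.sqrt(3.0)
        q_face = 0.5 * (1.0 + s3) * q_out + 0.5 * (1.0 - s3) * q_in
        return float(np.sum(q_face * 2 * np.pi * Redge * dz))


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_creep(params: MaterialParams, geometry: Geometry,
              protocol: LoadingProtocol,
              solver_opts: Optional[SolverOptions] = None) -> CreepSolution:
    """Simulate unconfined creep of the cartilage layer.

    Returns a :class:`CreepSolution` sampled at the accepted time steps
    (or interpolated onto ``protocol.output_times`` when provided).
    Raises :class:`SolverError` if Newton fails after exhausting
    time-step halvings.
    """
    opts = solver_opts or SolverOptions()
    mesh = build_mesh(geometry)
    sigma_a = protocol.applied_stress * _MPA
    work = _FEWork(mesh, params, opts, sigma_a)
    F_total = sigma_a * work.area

    n_gp, n_dir = 4, work.n_dir
    state = {
        "J": np.ones((mesh.n_elements, n_gp)),
        "eps_f": np.zeros((mesh.n_elements, n_gp, n_dir)),
        "q": np.zeros((mesh.n_elements, n_gp, n_dir)),
        "p_nodal": np.zeros(mesh.n_nodes),
    }

    x_red = np.zeros(work.n_red)
    t = 0.0
    dt = opts.dt0
    t_end = protocol.hold_duration
    t_max = protocol.hold_duration * (opts.max_extend_factor
                                      if opts.equilibrium_rate else 1.0)

    times = [0.0]
    u_hist = [0.0]
    por_hist = [0.0]
    reac_hist = [0.0]
    p_fields = [np.zeros(mesh.n_nodes)]
    newton_iters = []
    mass_storage = []
    mass_outflow = []

    lu = None
    thickness_m = geometry.thickness * _MM

    def newton_step(x0_red, dt_step, t_new):
        nonlocal lu
        load = F_total * min(t_new / protocol.ramp_duration, 1.0)
        x = x0_red.copy()
        r_prev = np.inf
        for it in range(opts.newton_max_iter):
            x_full = work.T @ x
            R_full, r_el, trial = work.assemble_residual(x_full, state, dt_step)
            G = work.T.T @ R_full
            G[work.platen_red] += load  # external axial force (downward)
            # block-scaled residual norm
            e_u = np.linalg.norm(G[~work.red_is_p]) / work.F_ref
            e_p = np.linalg.norm(G[work.red_is_p]) / max(work.Q_ref, 1e-30)
            err = max(e_u, e_p)
            if err < opts.rtol:
                return x, x_full, R_full, trial, it
            rebuild = (lu is None or not opts.reuse_tangent
                       or it >= opts.tangent_refresh_iters
                       or err > 0.5 * r_prev and it > 0)
            if rebuild:
                K = work.assemble_tangent(x_full, state, dt_step, r_el)
                lu = splu(K)
            dx = lu.solve(-G)
            if not np.all(np.isfinite(dx)):
                return None
            x = x + dx
            r_prev = err
        return None

    halvings_total = 0
    while t < t_end - 1e-12:
        if opts.max_steps is not None and len(times) > opts.max_steps:
            raise SolverError(
                f"step budget {opts.max_steps} exhausted at t={t:.4g}s")
        dt_try = min(dt, t_end - t)
        if t < protocol.ramp_duration:
            dt_try = min(dt_try, protocol.ramp_duration - t)
        ok = None
        halved = 0
        while ok is None:
            t_new = t + dt_try
            try:
                ok = newton_step(x_red, dt_try, t_new)
            except SolverError:
                ok = None
            if ok is None:
                halved += 1
                halvings_total += 1
                lu = None
                if halved > opts.max_step_halvings:
                    raise SolverError(
                        f"Newton failed at t={t:.4g}s after "
                        f"{opts.max_step_halvings} halvings")
                dt_try *= 0.5
        x_red, x_full, R_full, trial, iters = ok
        # commit
        state["J"] = trial["J"]
        state["eps_f"] = trial["eps_f"]
        state["q"] = trial["q"]
        p_nodal = x_full[2 * work.n_nodes:]
        outflow = work.edge_outflow(x_full)
        state["p_nodal"] = p_nodal.copy()
        t = t_new
        u_plat = x_red[work.platen_red]
        times.append(t)
        u_hist.append(u_plat)
        por_hist.append(work.por(p_nodal))
        reac_hist.append(work.reaction(R_full))
        p_fields.append(p_nodal.copy())
        newton_iters.append(iters)
        mass_storage.append((dt_try,
                             float(np.sum(work.wv * (trial["J"] - 1.0)))))
        mass_outflow.append(outflow)
        dt = min(dt_try * opts.dt_growth, opts.max_dt)
        if (opts.equilibrium_rate is not None and t > protocol.ramp_duration
                and len(u_hist) > 2):
            rate = abs(u_hist[-1] - u_hist[-2]) / dt_try
            if rate < opts.equilibrium_rate:
                break
            if t >= t_end - 1e-9 and t_end < t_max:
                t_end = min(t_end * 2.0, t_max)

    times = np.asarray(times)
    u = np.asarray(u_hist)
    por = np.asarray(por_hist) / _MPA
    reac = np.asarray(reac_hist)
    p_fields = np.asarray(p_fields) / _MPA
    disp_mm = np.maximum(-u, 0.0) / _MM
    strain = disp_mm * _MM / thickness_m
    ifls = por / protocol.applied_stress

    diagnostics = {
        "newton_iters": np.asarray(newton_iters),
        "step_dt": np.asarray([m[0] for m in mass_storage]),
        "volume_change": np.asarray([m[1] for m in mass_storage]),
        "edge_outflow": np.asarray(mass_outflow),
        "halvings": halvings_total,
        "n_red_dofs": work.n_red,
    }

    if protocol.output_times is not None:
        ot = protocol.output_times
        if ot[-1] > times[-1] + 1e-9:
            raise ValueError("output_times extend beyond the simulated span")
        interp = lambda y: np.interp(ot, times, y)
        p_out = np.empty((len(ot), mesh.n_nodes))
        for j in range(mesh.n_nodes):
            p_out[:, j] = np.interp(ot, times, p_fields[:, j])
        sol = CreepSolution(ot, interp(disp_mm), interp(strain), interp(por),
                            interp(ifls), interp(reac), p_out, mesh, geometry,
                            protocol, params, diagnostics)
    else:
        sol = CreepSolution(times, disp_mm, strain, por, ifls, reac, p_fields,
                            mesh, geometry, protocol, params, diagnostics)
    return sol
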