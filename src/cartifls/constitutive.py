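"""Pointwise material laws of the fibril-reinforced poroviscoelastic cartilage model.

The solid skeleton is split into an isotropic nonfibrillar matrix
(proteoglycan gel, compressible Neo-Hookean) and a tension-only
viscoelastic collagen-fibril network with linearly strain-dependent
stiffening.  Interstitial fluid flow is Darcian with a permeability
that depends on the local dilatation through the void ratio.

Conventions
-----------
* Moduli in the user-facing :class:`MaterialParams` are in MPa, the
  permeability in m^4/(N s); internal computations are SI (Pa, m, s).
* The fibril strain measure is the logarithmic strain of a material
  line element along the fibril direction; it reduces to engineering
  strain for small stretches.
* Tension-only gate: fibril stress and viscous overstress are
  identically zero whenever the fibril strain is non-positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = [
    "MaterialParams",
    "FibrilState",
    "FibrilNetworkLayout",
    "neo_hookean_stress",
    "fibril_stress_update",
    "permeability",
    "water_fraction",
]

MPA = 1.0e6  # Pa per MPa


class DegenerateDeformationError(ValueError):
    """Raised when a deformation state has non-positive volume ratio."""


@dataclass
class MaterialParams:
    """Constitutive parameter set.

    Five parameters are identified per specimen pair from a creep
    experiment; the remaining three are fixed tissue constants.

    Attributes
    ----------
    E_nf : float
        Nonfibrillar matrix modulus [MPa].
    E_f0 : float
        Initial (zero-strain) fibril network modulus [MPa].
    E_feps : float
        Strain-dependent fibril network modulus [MPa per unit strain];
        the network tangent modulus is ``E_f0 + E_feps * eps``.
    k0 : float
        Initial permeability [m^4/(N s)].
    M : float
        Exponent of the strain dependence of permeability.
    nu : float
        Poisson's ratio of the nonfibrillar matrix (fixed, 0.47).
    eta_fibril : float
        Damping coefficient of the viscoelastic fibrils [MPa s]
        (fixed, 947).
    e0 : float
        Initial void ratio (fixed, 3.5; water fraction 78%).
    """

    E_nf: float
    E_f0: float
    E_feps: float
    k0: float
    M: float
    nu: float = 0.47
    eta_fibril: float = 947.0
    e0: float = 3.5

    def __post_init__(self) -> None:
        if self.E_nf <= 0:
            raise ValueError(f"E_nf must be > 0, got {self.E_nf}")
        if self.E_f0 < 0 or self.E_feps < 0:
            raise ValueError("fibril moduli must be >= 0")
        if self.k0 <= 0:
            raise ValueError(f"k0 must be > 0, got {self.k0}")
        if self.M < 0:
            raise ValueError(f"M must be >= 0, got {self.M}")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError(f"nu must be in [0, 0.5), got {self.nu}")
        if self.eta_fibril <= 0:
            raise ValueError("eta_fibril must be > 0")
        if self.e0 <= 0:
            raise ValueError("e0 must be > 0")

    # -- Lame constants of the nonfibrillar matrix, SI ------------------
    @property
    def mu_s(self) -> float:
        """Shear modulus of the nonfibrillar matrix [Pa]."""
        return self.E_nf * MPA / (2.0 * (1.0 + self.nu))

    @property
    def lambda_s(self) -> float:
        """First Lame constant of the nonfibrillar matrix [Pa]."""
        return (
            self.E_nf * MPA * self.nu
            / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        )

    def with_(self, **kwargs) -> "MaterialParams":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return {
            "E_nf_MPa": d["E_nf"],
            "E_f0_MPa": d["E_f0"],
            "E_feps_MPa_per_strain": d["E_feps"],
            "k0_m4_per_Ns": d["k0"],
            "M": d["M"],
            "nu": d["nu"],
            "eta_fibril_MPa_s": d["eta_fibril"],
            "e0": d["e0"],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParams":
        return cls(
            E_nf=d["E_nf_MPa"],
            E_f0=d["E_f0_MPa"],
            E_feps=d["E_feps_MPa_per_strain"],
            k0=d["k0_m4_per_Ns"],
            M=d["M"],
            nu=d.get("nu", 0.47),
            eta_fibril=d.get("eta_fibril_MPa_s", 947.0),
            e0=d.get("e0", 3.5),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "MaterialParams":
        return cls.from_dict(json.loads(s))


def water_fraction(e0: float) -> float:
    """Porosity (fluid volume fraction) corresponding to a void ratio.

    ``phi = e / (1 + e)``; e0 = 3.5 gives 0.778, i.e. a 78% water
    fraction typical of articular cartilage.
    """
    if e0 <= 0:
        raise ValueError("void ratio must be > 0")
    return e0 / (1.0 + e0)


# ---------------------------------------------------------------------------
# Nonfibrillar matrix: compressible Neo-Hookean
# ---------------------------------------------------------------------------

def neo_hookean_stress(F: np.ndarray, E_nf: float, nu: float) -> np.ndarray:
    """Effective Cauchy stress of the compressible Neo-Hookean matrix.

    sigma = (mu/J) (B - I) + (lambda/J) ln(J) I, with B = F F^T and
    J = det F.  Units of the result follow the units of ``E_nf``.

    Parameters
    ----------
    F : (3, 3) array
        Deformation gradient, det(F) > 0.
    E_nf, nu : float
        Young's modulus and Poisson's ratio of the matrix.

    Returns
    -------
    (3, 3) ndarray — symmetric Cauchy stress (same units as E_nf).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0.0:
        raise DegenerateDeformationError(f"det(F) must be > 0, got {J}")
    mu = E_nf / (2.0 * (1.0 + nu))
    lam = E_nf * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    B = F @ F.T
    I = np.eye(3)
    sigma = (mu / J) * (B - I) + (lam / J) * np.log(J) * I
    return 0.5 * (sigma + sigma.T)


# ---------------------------------------------------------------------------
# Fibril network
# ---------------------------------------------------------------------------

@dataclass
class FibrilState:
    """Internal state of one fibril (direction): strain and Maxwell overstress."""

    direction: np.ndarray
    eps_f: float = 0.0
    overstress_q: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, rtol=1e-8):
            raise ValueError("fibril direction must be a unit vector")
        self.direction = d


def fibril_equilibrium_stress(eps: float | np.ndarray,
                              params: MaterialParams) -> float | np.ndarray:
    """Equilibrium (long-time) fibril stress sigma_eq = E_f0 e + E_feps e^2 / 2 [MPa].

    Integrates the tangent modulus E_f0 + E_feps*e from zero strain;
    tension only (zero for e <= 0).
    """
    eps = np.asarray(eps, dtype=float)
    s = params.E_f0 * eps + 0.5 * params.E_feps * eps**2
    return np.where(eps > 0.0, s, 0.0)[()]


def fibril_stress_update(eps_f_new: float, dt: float, state: FibrilState,
                         params: MaterialParams) -> tuple[float, FibrilState]:
    """Backward-Euler update of one tension-only viscoelastic fibril.

    The fibril is an equilibrium nonlinear spring (tangent modulus
    ``E_f0 + E_feps * eps``) in parallel with a Maxwell branch carrying
    a viscous overstress q governed by

        dq/dt = E_tan(eps) deps/dt - (E_tan(eps)/eta) q .

    When the new fibril strain is non-positive the fibril is slack:
    the stress is zero and the overstress is reset.

    Returns
    -------
    (sigma_f, new_state) — fibril stress [MPa] and the updated state.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    eta = params.eta_fibril
    if eps_f_new <= 0.0:
        new = FibrilState(state.direction, eps_f=eps_f_new, overstress_q=0.0)
        return 0.0, new
    E_tan = params.E_f0 + params.E_feps * eps_f_new
    d_eps = eps_f_new - max(state.eps_f, 0.0)
    q_new = (state.overstress_q + E_tan * d_eps) / (1.0 + dt * E_tan / eta)
    sigma = float(fibril_equilibrium_stress(eps_f_new, params)) + q_new
    new = FibrilState(state.direction, eps_f=eps_f_new, overstress_q=q_new)
    return sigma, new


# vectorized version used by the FE solver ---------------------------------

def fibril_overstress_step(eps_new: np.ndarray, eps_old: np.ndarray,
                           q_old: np.ndarray, dt: float,
                           E_f0: float, E_feps: float,
                           eta: float) -> np.ndarray:
    """Vectorized Maxwell-overstress update (units follow the moduli).

    Broadcasts over arbitrary leading axes; the tension gate zeroes the
    overstress wherever the new strain is non-positive.
    """
    E_tan = E_f0 + E_feps * eps_new
    d_eps = eps_new - np.maximum(eps_old, 0.0)
    q = (q_old + E_tan * d_eps) / (1.0 + dt * E_tan / eta)
    return np.where(eps_new > 0.0, q, 0.0)


@dataclass
class FibrilNetworkLayout:
    """Discrete direction set of the homogeneous fibril network.

    Primary fibrils lie parallel to the articular surface (the r-theta
    plane of the axisymmetric frame); secondary fibrils approximate an
    isotropic background.  Weights are normalized so that the uniaxial
    tangent modulus of the assembled network along a primary direction
    at zero strain equals E_f0.
    """

    primary_directions: np.ndarray = field(default=None)
    secondary_directions: np.ndarray = field(default=None)
    primary_weight_ratio: float = 3.0

    def __post_init__(self) -> None:
        s2 = 1.0 / np.sqrt(2.0)
        if self.primary_directions is None:
            # vectors in the (r, z, theta) frame
            self.primary_directions = np.array([
                [1.0, 0.0, 0.0],   # e_r
                [0.0, 0.0, 1.0],   # e_theta
            ])
        if self.secondary_directions is None:
            self.secondary_directions = np.array([
                [1.0, 0.0, 0.0],
                [0.0, 1.0, 0.0],
                [0.0, 0.0, 1.0],
                [s2, s2, 0.0],
                [s2, -s2, 0.0],
                [0.0, s2, s2],
                [0.0, -s2, s2],
            ])
        if self.primary_weight_ratio <= 0:
            raise ValueError("primary_weight_ratio must be > 0")
        self.primary_directions = np.asarray(self.primary_directions, float)
        self.secondary_directions = np.asarray(self.secondary_directions, float)
        for d in (*self.primary_directions, *self.secondary_directions):
            if not np.isclose(np.linalg.norm(d), 1.0):
                raise ValueError("all fibril directions must be unit vectors")

    @property
    def directions(self) -> np.ndarray:
        """All directions, primaries first, shape (n_dir, 3)."""
        return np.vstack([self.primary_directions, self.secondary_directions])

    @property
    def weights(self) -> np.ndarray:
        """Per-direction weights, normalized (see class docstring)."""
        dirs = self.directions
        n_p = len(self.primary_directions)
        rel = np.ones(len(dirs))
        rel[:n_p] = self.primary_weight_ratio
        # Uniaxial strain eps along a primary direction m strains fibril d by
        # eps (d.m)^2 and contributes stress w (d.m)^2 * E_tan * (d.m)^2 along
        # m; require sum_d w (d.m)^4 = 1 for the first primary direction.
        m = dirs[0]
        proj4 = (dirs @ m) ** 4
        scale = float(rel @ proj4)
        return rel / scale

    def uniaxial_tangent_modulus(self, direction: np.ndarray,
                                 params: MaterialParams,
                                 eps: float = 0.0) -> float:
        """Network tangent stiffness [MPa] along ``direction`` for a
        uniaxial strain increment about a homogeneous tensile strain ``eps``.

        Only fibrils with positive strain contribute (tension gate).
        """
        m = np.asarray(direction, float)
        m = m / np.linalg.norm(m)
        dirs = self.directions
        w = self.weights
        c2 = (dirs @ m) ** 2
        eps_d = eps * c2
        E_tan = params.E_f0 + params.E_feps * eps_d
        active = (eps_d > 0.0) | ((eps_d == 0.0) & (c2 > 0.0))
        return float(np.sum(w * E_tan * c2**2 * active))


# ---------------------------------------------------------------------------
# Permeability
# ---------------------------------------------------------------------------

def permeability(J: float | np.ndarray, params: MaterialParams):
    """Strain-dependent permeability k = k0 * J^M [m^4/(N s)].

    Derived from the void-ratio form k = k0 ((1+e)/(1+e0))^M with
    1 + e = J (1 + e0): the current void ratio follows the volume
    ratio of the mixture when the constituents are incompressible.
    """
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0.0):
        raise DegenerateDeformationError("volume ratio J must be > 0")
    return (params.k0 * J**params.M)[()]
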