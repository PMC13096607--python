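"""Closed-form linear biphasic unconfined-compression creep.

Independent verification oracle for the finite-element solver in its
degenerate limit (no fibrils, constant permeability, small strain).

A saturated linear poroelastic cylinder of radius ``a`` (drained
modulus E, Poisson ratio nu, permeability k) is compressed between
frictionless impermeable platens by a step axial stress sigma0; the
lateral surface is traction-free and free-draining.  Radial
consolidation then relaxes the axial strain from the instantaneous
(incompressible) response sigma0/(3 mu) to the drained equilibrium
sigma0/E.

The axial creep strain admits the classical Bessel-series form

    eps(t) = sigma0/E + sum_n c_n exp(-c beta_n^2 t / a^2),

where c = k H_A is the consolidation coefficient (H_A the aggregate
modulus) and the beta_n are the positive roots of the characteristic
equation

    3 H_A J0(beta) - 8 mu J1(beta)/beta = 0,

equivalently J0(beta) = [4(1-2 nu)/(3(1-nu))] J1(beta)/beta.  The
coefficients c_n are the pole residues of the Laplace-domain solution

    eps_hat(s) = -(sigma0/(mu s)) *
                 (H_A I0(x) - 2 mu I1(x)/x) / (3 H_A I0(x) - 8 mu I1(x)/x),

with x = a sqrt(s/c).  Both the s -> 0 limit (sigma0/E) and the
s -> inf limit (sigma0/(3 mu)) are recovered exactly, and the series
is verified in the test suite against a brute-force radial
finite-difference consolidation solve (:func:`fd_reference_creep`)
that shares no code with it.

All strains returned here are compressive magnitudes (positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1

__all__ = [
    "LinearBiphasicParams",
    "characteristic_roots",
    "biphasic_unconfined_creep",
    "fd_reference_creep",
]

_MPA = 1.0e6
_MM = 1.0e-3


@dataclass
class LinearBiphasicParams:
    """Linear biphasic cylinder in unconfined compression.

    E_s [MPa], nu_s [-], k [m^4/(N s)], radius [mm], sigma0 [MPa]
    (compressive magnitude of the applied axial stress).
    """

    E_s: float
    nu_s: float
    k: float
    radius: float
    sigma0: float

    def __post_init__(self) -> None:
        if self.E_s <= 0 or self.k <= 0 or self.radius <= 0:
            raise ValueError("E_s, k and radius must be positive")
        if not 0.0 <= self.nu_s < 0.5:
            raise ValueError("nu_s must be in [0, 0.5)")

    @property
    def mu(self) -> float:
        return self.E_s * _MPA / (2.0 * (1.0 + self.nu_s))

    @property
    def lam(self) -> float:
        return (self.E_s * _MPA * self.nu_s
                / ((1.0 + self.nu_s) * (1.0 - 2.0 * self.nu_s)))

    @property
    def H_A(self) -> float:
        """Aggregate (confined) modulus [Pa]."""
        return self.lam + 2.0 * self.mu

    @property
    def consolidation_coefficient(self) -> float:
        """c = k H_A [m^2/s]."""
        return self.k * self.H_A

    @property
    def char_time(self) -> float:
        """a^2 / (H_A k): radial consolidation time scale [s]."""
        return (self.radius * _MM) ** 2 / self.consolidation_coefficient

    @property
    def eps_equilibrium(self) -> float:
        """Drained equilibrium strain sigma0 / E."""
        return self.sigma0 / self.E_s

    @property
    def eps_instant(self) -> float:
        """Instantaneous (undrained incompressible) strain sigma0/(3 mu)."""
        return self.sigma0 * _MPA / (3.0 * self.mu)


def characteristic_roots(nu_s: float, n_roots: int = 50) -> np.ndarray:
    """First ``n_roots`` positive roots of the creep characteristic equation.

    f(beta) = J0(beta) - [4 (1-2 nu)/(3 (1-nu))] J1(beta)/beta = 0.

    Roots are located by scanning for sign changes and polished with
    Brent's method; they interlace the zeros of J0 so a scan step well
    below pi is sufficient.
    """
    coef = 4.0 * (1.0 - 2.0 * nu_s) / (3.0 * (1.0 - nu_s))

    def f(b: float) -> float:
        return j0(b) - coef * j1(b) / b

    roots: list[float] = []
    step = 0.02
    b_lo = 1e-6
    f_lo = f(b_lo)
    b = b_lo
    while len(roots) < n_roots:
        b_next = b + step
        f_next = f(b_next)
        if f_lo == 0.0:
            roots.append(b)
        elif np.sign(f_next) != np.sign(f_lo):
            roots.append(brentq(f, b, b_next, xtol=1e-14, rtol=1e-15))
        b, f_lo = b_next, f_next
    return np.asarray(roots[:n_roots])


def _series_terms(params: LinearBiphasicParams, n_roots: int):
    """Decay rates s_n [1/s] and residue coefficients c_n [strain]."""
    mu, H_A = params.mu, params.H_A
    a = params.radius * _MM
    c = params.consolidation_coefficient
    beta = characteristic_roots(params.nu_s, n_roots)
    s_n = -c * beta**2 / a**2
    # N and dD/ds evaluated on the negative real axis (x = i beta)
    N = H_A * j0(beta) - 2.0 * mu * j1(beta) / beta
    dD_dbeta = (-3.0 * H_A * j1(beta)
                - 8.0 * mu * (j0(beta) / beta - 2.0 * j1(beta) / beta**2))
    dD_ds = dD_dbeta * (-(a**2) / (2.0 * c * beta))
    sigma0 = params.sigma0 * _MPA
    c_n = -(sigma0 / (mu * s_n)) * N / dD_ds
    return s_n, c_n


def biphasic_unconfined_creep(params: LinearBiphasicParams,
                              t: np.ndarray,
                              n_roots: int = 50,
                              tail_tol: float = 1e-8) -> np.ndarray:
    """Axial creep strain magnitude eps(t) of the Bessel series solution.

    Parameters
    ----------
    t : array of times [s], t >= 0.
    n_roots : number of characteristic roots; doubled automatically
        until the last retained term is below ``tail_tol`` of the
        partial sum at the earliest strictly positive time.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0.0):
        raise ValueError("times must be >= 0")
    while True:
        s_n, c_n = _series_terms(params, n_roots)
        tpos = t[t > 0]
        t_min = tpos.min() if tpos.size else params.char_time * 1e-6
        last = abs(c_n[-1] * np.exp(s_n[-1] * t_min))
        if last <= tail_tol * max(params.eps_equilibrium, 1e-30) or n_roots >= 3200:
            break
        n_roots *= 2
    # eps(t) (compression magnitude); signs: residues c_n computed on the
    # compressive branch already carry the correct sign.
    eps = params.eps_equilibrium - np.sum(
        c_n[None, :] * np.exp(np.outer(t, s_n)), axis=1)
    return eps


# ---------------------------------------------------------------------------
# Brute-force radial finite-difference reference
# ---------------------------------------------------------------------------

def fd_reference_creep(params: LinearBiphasicParams, t_out: np.ndarray,
                       n_r: int = 120, n_steps: int = 400) -> np.ndarray:
    """Radial finite-difference solve of the same linear biphasic problem.

    Discretizes the primal fields — radial displacement u(r), uniform
    axial strain eps, pore pressure p(r) — with second-order stencils
    and backward-Euler time stepping on a geometric time grid, then
    interpolates the axial strain onto ``t_out``.  Used only to verify
    the series solution; shares no derivation with it.
    """
    t_out = np.atleast_1d(np.asarray(t_out, dtype=float))
    mu, lam, H_A = params.mu, params.lam, params.H_A
    k = params.k
    a = params.radius * _MM
    sigma0 = params.sigma0 * _MPA
    n = n_r
    h = a / n
    r = np.linspace(0.0, a, n + 1)

    # unknown ordering: u_1..u_n (n), eps (1), p_0..p_{n-1} (n)
    iu = lambda i: i - 1          # u_i, i = 1..n
    ieps = n
    ip = lambda i: n + 1 + i      # p_i, i = 0..n-1
    nun = 2 * n + 1

    A_static = np.zeros((nun, nun))
    # storage operator: row -> e_i coefficient map (continuity rows)
    C_store = np.zeros((nun, nun))
    rhs_static = np.zeros(nun)

    def u_coef(row: int, i: int, val: float, mat=None) -> None:
        m = A_static if mat is None else mat
        if i >= 1:
            m[row, iu(i)] += val  # u_0 = 0

    def p_coef(row: int, i: int, val: float, mat=None) -> None:
        m = A_static if mat is None else mat
        if i <= n - 1:
            m[row, ip(i)] += val  # p_n = 0

    # momentum at interior nodes i = 1..n-1:
    # H_A (u'' + u'/r - u/r^2) - p' = 0
    for i in range(1, n):
        row = i - 1
        u_coef(row, i + 1, H_A * (1.0 / h**2 + 1.0 / (2 * h * r[i])))
        u_coef(row, i, H_A * (-2.0 / h**2 - 1.0 / r[i] ** 2))
        u_coef(row, i - 1, H_A * (1.0 / h**2 - 1.0 / (2 * h * r[i])))
        p_coef(row, i + 1, -1.0 / (2 * h))
        p_coef(row, i - 1, 1.0 / (2 * h))

    # radial traction at r = a (row n-1):
    # H_A u'(a) + lam (u(a)/a + eps) = 0   (p(a) = 0)
    row = n - 1
    u_coef(row, n, H_A * 3.0 / (2 * h) + lam / a)
    u_coef(row, n - 1, -H_A * 4.0 / (2 * h))
    u_coef(row, n - 2, H_A * 1.0 / (2 * h))
    A_static[row, ieps] += lam

    # continuity at i = 0..n-1 (rows n..2n-1):
    # e_i/dt - k Lap_r p_i = e_i^old/dt
    for i in range(0, n):
        row = n + i
        # e_i = u'_i + u_i/r_i + eps  (at r=0: e = 2 u'(0) + eps)
        if i == 0:
            # u'(0) via one-sided: (4 u_1 - u_2)/(2h), u_0 = 0
            u_coef(row, 1, 2.0 * 4.0 / (2 * h), C_store)
            u_coef(row, 2, -2.0 / (2 * h), C_store)
        else:
            u_coef(row, i + 1, 1.0 / (2 * h), C_store)
            u_coef(row, i - 1, -1.0 / (2 * h), C_store)
            u_coef(row, i, 1.0 / r[i], C_store)
        C_store[row, ieps] += 1.0
        # Laplacian (1/r)(r p')'
        if i == 0:
            p_coef(row, 1, -k * 4.0 / h**2)
            p_coef(row, 0, k * 4.0 / h**2)
        else:
            rp = 0.5 * (r[i] + r[i + 1])
            rm = 0.5 * (r[i] + r[i - 1])
            p_coef(row, i + 1, -k * rp / (r[i] * h**2))
            p_coef(row, i, k * (rp + rm) / (r[i] * h**2))
            p_coef(row, i - 1, -k * rm / (r[i] * h**2))

    # axial force (row 2n): (2/a^2) int r (lam e + 2 mu eps - p) dr = -sigma0
    row = 2 * n
    w_tr = np.full(n + 1, h)
    w_tr[0] = w_tr[-1] = h / 2.0
    for i in range(0, n + 1):
        wi = (2.0 / a**2) * w_tr[i] * r[i]
        # e_i
        if i == 0:
            continue  # r=0: zero weight
        if i == n:
            u_coef(row, n, wi * lam * 3.0 / (2 * h))
            u_coef(row, n - 1, -wi * lam * 4.0 / (2 * h))
            u_coef(row, n - 2, wi * lam * 1.0 / (2 * h))
            u_coef(row, n, wi * lam / r[i])
        else:
            u_coef(row, i + 1, wi * lam / (2 * h))
            u_coef(row, i - 1, -wi * lam / (2 * h))
            u_coef(row, i, wi * lam / r[i])
        A_static[row, ieps] += wi * (lam + 2.0 * mu)
        p_coef(row, i, -wi)
    rhs_static[row] = -sigma0

    # geometric time stepping
    t_end = max(t_out.max(), params.char_time * 6.0)
    t0 = min(params.char_time * 1e-6, max(t_out[t_out > 0].min(), 1e-12)
             if np.any(t_out > 0) else params.char_time * 1e-6)
    g = (t_end / t0) ** (1.0 / (n_steps - 1))
    times = t0 * g ** np.arange(n_steps)

    x = np.zeros(nun)
    t_prev = 0.0
    eps_hist = [0.0]
    t_hist = [0.0]
    for tm in times:
        dt = tm - t_prev
        A = A_static + C_store / dt
        rhs = rhs_static + (C_store @ x) / dt
        x = np.linalg.solve(A, rhs)
        eps_hist.append(-x[ieps])  # compression magnitude
        t_hist.append(tm)
        t_prev = tm
    return np.interp(t_out, np.asarray(t_hist), np.asarray(eps_hist))
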