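"""Identification of the five constitutive parameters from creep records.

The five free parameters of the fibril-reinforced poroviscoelastic
model — nonfibrillar modulus E_nf, initial and strain-dependent fibril
network moduli E_f0 and E_feps, initial permeability k0 and its strain
dependence M — are identified per specimen pair by minimizing the RMS
error between the simulated platen displacement and the (half of the)
measured pair creep displacement.  The optimizer is a bounded
Nelder-Mead simplex restarted from Latin-hypercube points; uniqueness
is assessed from the per-start result table, mirroring the
restart-verification practice used with this model family.

The modelled layer represents both cartilage layers of the pair:
its thickness is the average of the two plug thicknesses and it is
assigned ``model_share`` (default 50%) of the measured pair
displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc
from sklearn.isotonic import isotonic_regression

from .constitutive import MaterialParams
from .fe_creep_solver import (
    CreepSolution,
    Geometry,
    LoadingProtocol,
    SolverError,
    SolverOptions,
    run_creep,
)

__all__ = [
    "FitProblem",
    "FitResult",
    "DEFAULT_BOUNDS",
    "fit_parameters",
    "creep_rmse",
    "sensitivity_sweep",
    "sweep_table",
]

#: Per-parameter search boxes spanning reported healthy and degraded
#: cartilage ranges.  k0 is searched in log10 coordinates.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "E_nf": (0.01, 5.0),        # MPa
    "E_f0": (0.0, 20.0),        # MPa
    "E_feps": (0.0, 1000.0),    # MPa per unit strain
    "k0": (1e-16, 1e-13),       # m^4/(N s)
    "M": (0.0, 15.0),
}

_PARAM_ORDER = ("E_nf", "E_f0", "E_feps", "k0", "M")
_FAIL_COST = 1.0e6


@dataclass
class FitProblem:
    """One specimen pair's creep-identification problem.

    target_times [s] and target_displacement [mm] are the measured
    *pair* displacement (both layers); the model carries
    ``model_share`` of it.  The target is projected onto the monotone
    cone (isotonic regression), since creep under constant load cannot
    recover; unlike a running maximum this projection is unbiased
    under symmetric noise.  ``time_unit`` may be "s" or "ms"; inputs
    are normalized to seconds on construction.
    """

    target_times: np.ndarray
    target_displacement: np.ndarray
    geometry: Geometry
    protocol: LoadingProtocol
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 8
    model_share: float = 0.5
    time_unit: str = "s"
    weighting: str = "uniform"    # "uniform" | "log_time"

    def __post_init__(self) -> None:
        t = np.asarray(self.target_times, dtype=float)
        d = np.asarray(self.target_displacement, dtype=float)
        if self.time_unit == "ms":
            t = t / 1000.0
        elif self.time_unit != "s":
            raise ValueError(f"unknown time_unit {self.time_unit!r}")
        self.time_unit = "s"
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("target series must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("target times must be strictly increasing")
        if not 0.0 < self.model_share <= 1.0:
            raise ValueError("model_share must be in (0, 1]")
        for name, (lo, hi) in self.bounds.items():
            if not np.isfinite([lo, hi]).all() or hi <= lo:
                raise ValueError(f"invalid bounds for {name}")
        if self.weighting not in ("uniform", "log_time"):
            raise ValueError("weighting must be 'uniform' or 'log_time'")
        self.target_times = t
        self.target_displacement = isotonic_regression(d, increasing=True)

    @property
    def scaled_target(self) -> np.ndarray:
        """Displacement assigned to the modelled layer [mm]."""
        return self.model_share * self.target_displacement

    def weights(self) -> np.ndarray:
        if self.weighting == "uniform":
            return np.ones_like(self.target_times)
        t = np.maximum(self.target_times, self.protocol.ramp_duration * 0.1)
        lt = np.log(t)
        w = np.gradient(lt)
        return w / w.mean()


@dataclass
class FitResult:
    """Best-fit parameters with goodness of fit and the restart table."""

    params: MaterialParams
    rmse: float                     # [mm], on the experimental grid
    r_squared: float
    per_start: pd.DataFrame
    converged: bool
    n_eval: int


def _unit_to_params(x: np.ndarray, bounds: dict,
                    constants: dict) -> MaterialParams:
    vals = {}
    for xi, name in zip(x, _PARAM_ORDER):
        lo, hi = bounds[name]
        xi = float(np.clip(xi, 0.0, 1.0))
        if name == "k0":
            vals[name] = 10.0 ** (np.log10(lo) + xi * (np.log10(hi)
                                                       - np.log10(lo)))
        else:
            vals[name] = lo + xi * (hi - lo)
    # the matrix modulus must be strictly positive
    vals["E_nf"] = max(vals["E_nf"], 1e-6)
    return MaterialParams(**vals, **constants)


def _params_to_unit(p: MaterialParams, bounds: dict) -> np.ndarray:
    x = []
    for name in _PARAM_ORDER:
        lo, hi = bounds[name]
        v = getattr(p, name)
        if name == "k0":
            x.append((np.log10(v) - np.log10(lo))
                     / (np.log10(hi) - np.log10(lo)))
        else:
            x.append((v - lo) / (hi - lo))
    return np.asarray(x)


def creep_rmse(problem: FitProblem, params: MaterialParams,
               solver_opts: Optional[SolverOptions] = None,
               fit_mesh: Optional[tuple[int, int]] = None,
               return_solution: bool = False):
    """Weighted RMSE [mm] between simulated displacement and the target.

    This is the optimization objective; it is exposed so that a
    reported fit can be recomputed independently of the optimizer.
    """
    geo = problem.geometry
    if fit_mesh is not None:
        geo = replace(geo, n_r=fit_mesh[0], n_z=fit_mesh[1])
    proto = replace(problem.protocol,
                    hold_duration=max(problem.protocol.hold_duration,
                                      problem.target_times[-1] * 1.0001),
                    output_times=None)
    sol = run_creep(params, geo, proto, solver_opts)
    u = sol.displacement_at(problem.target_times)
    resid = u - problem.scaled_target
    w = problem.weights()
    rmse = float(np.sqrt(np.sum(w * resid**2) / np.sum(w)))
    if return_solution:
        return rmse, sol
    return rmse


def fit_parameters(problem: FitProblem,
                   solver_opts: Optional[SolverOptions] = None,
                   fit_mesh: tuple[int, int] = (15, 10),
                   maxfev_per_start: int = 60,
                   polish_max_nfev: int = 40,
                   seed: int = 0,
                   constants: Optional[dict] = None) -> FitResult:
    """Multi-start identification of the 5 parameters.

    Each Latin-hypercube start is explored with a bounded Nelder-Mead
    simplex (derivative-free, robust to solver failures); the best
    point is then refined with a bounded trust-region Gauss-Newton
    solve on the displacement residual vector, which resolves the
    narrow valley traded off between the two fibril moduli far faster
    than the simplex alone.

    Parameters
    ----------
    fit_mesh : element counts used during optimization (coarse by default;
        agreement between the coarse and full meshes is verified in the
        test suite rather than re-polished here).
    maxfev_per_start : objective-evaluation cap per simplex start.
    polish_max_nfev : outer-iteration cap of the least-squares polish
        (each outer iteration costs up to 6 simulations); 0 disables it.
    constants : overrides for the fixed constitutive constants
        (nu, eta_fibril, e0).
    """
    constants = {"nu": 0.47, "eta_fibril": 947.0, "e0": 3.5,
                 **(constants or {})}
    bounds = problem.bounds
    if solver_opts is None:
        # fail fast on hopeless parameter regions during the search
        solver_opts = SolverOptions(max_step_halvings=8, newton_max_iter=20,
                                    max_steps=400)

    n_eval = 0
    w_sqrt = np.sqrt(problem.weights() / problem.weights().sum())
    target = problem.scaled_target

    def simulate(x: np.ndarray):
        nonlocal n_eval
        n_eval += 1
        p = _unit_to_params(x, bounds, constants)
        geo = replace(problem.geometry, n_r=fit_mesh[0], n_z=fit_mesh[1])
        proto = replace(problem.protocol,
                        hold_duration=max(problem.protocol.hold_duration,
                                          problem.target_times[-1] * 1.0001),
                        output_times=None)
        sol = run_creep(p, geo, proto, solver_opts)
        return sol.displacement_at(problem.target_times)

    def cost(x: np.ndarray) -> float:
        # |w_sqrt|^2 sums to 1, so this is the weighted RMSE [mm]
        try:
            return float(np.linalg.norm(w_sqrt * (simulate(x) - target)))
        except (SolverError, ValueError):
            return _FAIL_COST

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            return w_sqrt * (simulate(x) - target) * np.sqrt(len(target))
        except (SolverError, ValueError):
            return np.full(len(target), 10.0)

    sampler = qmc.LatinHypercube(d=5, seed=seed)
    starts = sampler.random(problem.n_starts)

    rows = []
    x_best, f_best = None, np.inf
    for i, x0 in enumerate(starts):
        # derivative-free exploration localizes the basin ...
        res = minimize(cost, x0, method="Nelder-Mead",
                       bounds=[(0.0, 1.0)] * 5,
                       options={"maxfev": maxfev_per_start,
                                "xatol": 1e-4, "fatol": 1e-9})
        ok = res.fun < _FAIL_COST
        x_i, f_i, nfev_i = res.x, res.fun, res.nfev
        # ... then a Gauss-Newton trust-region solve resolves the
        # narrow valley traded off between the two fibril moduli
        if ok and polish_max_nfev > 0:
            pol = least_squares(residuals, x_i, bounds=(0.0, 1.0),
                                method="trf", diff_step=1e-4,
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=polish_max_nfev)
            f_pol = float(np.sqrt(2.0 * pol.cost / len(target)))
            if f_pol < f_i:
                x_i, f_i = pol.x, f_pol
        p = _unit_to_params(x_i, bounds, constants)
        rows.append({"start": i, "rmse_mm": f_i, "converged": ok,
                     "nfev": nfev_i,
                     **{k: getattr(p, k) for k in _PARAM_ORDER}})
        if ok and f_i < f_best:
            x_best, f_best = x_i, f_i
    per_start = pd.DataFrame(rows)
    if x_best is None:
        raise SolverError("all optimization starts failed")

    p_best = _unit_to_params(x_best, bounds, constants)
    rmse, sol = creep_rmse(problem, p_best, solver_opts, fit_mesh,
                           return_solution=True)
    u = sol.displacement_at(problem.target_times)
    target = problem.scaled_target
    ss_res = float(np.sum((u - target) ** 2))
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return FitResult(params=p_best, rmse=rmse,
                     r_squared=max(min(r2, 1.0), 0.0),
                     per_start=per_start,
                     converged=bool(per_start["converged"].any()),
                     n_eval=n_eval)


# ---------------------------------------------------------------------------
# Sensitivity sweeps
# ---------------------------------------------------------------------------

def sensitivity_sweep(params: MaterialParams, geometry: Geometry,
                      protocol: LoadingProtocol, param_name: str,
                      values: Sequence[float],
                      solver_opts: Optional[SolverOptions] = None,
                      ) -> dict[float, CreepSolution]:
    """One creep simulation per parameter value, all else held fixed.

    Used for the Poisson-ratio sensitivity study (nu in {0.15, 0.37,
    0.47}) and for consolidation-time checks over k0.
    """
    if not hasattr(params, param_name):
        raise ValueError(f"unknown parameter {param_name!r}")
    out: dict[float, CreepSolution] = {}
    for v in values:
        p = params.with_(**{param_name: float(v)})
        out[float(v)] = run_creep(p, geometry, protocol, solver_opts)
    return out


def sweep_table(solutions: dict[float, CreepSolution],
                param_name: str) -> pd.DataFrame:
    """Tidy table of IFLS vs time and vs displacement for a sweep."""
    frames = []
    for v, sol in solutions.items():
        df = sol.to_dataframe()
        df[param_name] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
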