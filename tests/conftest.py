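"""Shared fixtures: expensive simulations and fits are session-scoped
and reused across module tests and the acceptance suite."""

import numpy as np
import pytest

import cartifls as cf
from cartifls.fe_creep_solver import SolverOptions
from cartifls.param_fit import FitProblem, fit_parameters

#: Healthy-group generating medians (the synthetic module's defaults).
HEALTHY = dict(E_nf=0.3, E_f0=2.0, E_feps=100.0, k0=2e-15, M=5.0)

#: Truth used by the identification fixtures.
FIT_TRUTH = dict(HEALTHY)


@pytest.fixture(scope="session")
def healthy_params():
    return cf.MaterialParams(**HEALTHY)


@pytest.fixture(scope="session")
def healthy_solution(healthy_params):
    """Default healthy creep on the coarse mesh, run to displacement-rate
    equilibrium (< 1e-9 m/s)."""
    geo = cf.Geometry(radius=3.5, thickness=1.7, n_r=15, n_z=10)
    return cf.run_creep(healthy_params, geo, cf.LoadingProtocol(),
                        SolverOptions(equilibrium_rate=1e-9))


@pytest.fixture(scope="session")
def oracle_pair():
    """FE solve in the no-fibril small-strain limit paired with the
    matching linear biphasic closed-form parameters."""
    params = cf.MaterialParams(E_nf=0.5, E_f0=0.0, E_feps=0.0, k0=1e-14,
                               M=0.0, nu=0.1)
    oracle = cf.LinearBiphasicParams(E_s=0.5, nu_s=0.1, k=1e-14,
                                     radius=3.5, sigma0=0.005)
    geo = cf.Geometry(radius=3.5, thickness=1.75, n_r=15, n_z=10)
    proto = cf.LoadingProtocol(applied_stress=0.005, ramp_duration=0.05,
                               hold_duration=oracle.char_time * 5)
    opts = SolverOptions(frictionless_base=True, small_strain=True,
                         max_dt=1e9, dt_growth=1.35)
    sol = cf.run_creep(params, geo, proto, opts)
    return sol, oracle


def _fit_target(noise_sigma_mm: float = 0.0, seed: int = 1234):
    """Synthetic pair-displacement creep target from known parameters.

    The fit later uses a different time-step sequence than the
    generator, so recovery is not an exact inverse crime.
    """
    truth = cf.MaterialParams(**FIT_TRUTH)
    geo = cf.Geometry(radius=3.5, thickness=1.7, n_r=10, n_z=6)
    proto = cf.LoadingProtocol(hold_duration=3500.0)
    sol = cf.run_creep(truth, geo, proto)
    tt = np.unique(np.concatenate([np.arange(0.2, 10, 0.2),
                                   np.geomspace(10, 3500, 100)]))
    target = sol.displacement_at(tt) / 0.5       # pair displacement
    if noise_sigma_mm > 0:
        rng = np.random.default_rng(seed)
        target = target + noise_sigma_mm * rng.standard_normal(len(tt))
    return truth, geo, proto, tt, target


FIT_SOLVER_OPTS = SolverOptions(max_step_halvings=8, newton_max_iter=20,
                                max_steps=400, dt_growth=1.4)


def _run_fit(noise_sigma_mm: float, n_starts: int, maxfev: int = 90,
             polish: int = 40):
    truth, geo, proto, tt, target = _fit_target(noise_sigma_mm)
    problem = FitProblem(target_times=tt, target_displacement=target,
                         geometry=geo, protocol=proto, n_starts=n_starts)
    fit = fit_parameters(problem, solver_opts=FIT_SOLVER_OPTS,
                         fit_mesh=(10, 6), maxfev_per_start=maxfev,
                         polish_max_nfev=polish, seed=0)
    return {"truth": truth, "problem": problem, "fit": fit,
            "noise_sigma_mm": noise_sigma_mm}


@pytest.fixture(scope="session")
def noiseless_fit():
    """Self-recovery identification on a noiseless synthetic target."""
    return _run_fit(0.0, n_starts=5)


@pytest.fixture(scope="session")
def noisy_fit():
    """Identification with 2-um displacement noise."""
    return _run_fit(2.0e-3, n_starts=2)


@pytest.fixture(scope="session")
def noisier_fit():
    """Identification with 40-um displacement noise (same noise stream)."""
    return _run_fit(40.0e-3, n_starts=2)
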