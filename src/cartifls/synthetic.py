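"""Synthetic tribo-rheometer experiments for the four study groups.

Generates complete, statistically plausible experiments — creep
displacement of a poroviscoelastic plug pair under 0.78 MPa, torque
consistent with a ground-truth mu(IFLS) law, 10-s lift-off gaps
between rotation blocks, instrument noise — so that every pipeline
stage can be exercised end-to-end with known ground truth.

Group structure mirrors the study design: healthy/degraded x
saline/bovine synovial fluid (BSF), three specimen pairs per group,
four angular velocities per pair.  Degraded specimens are softer by a
factor of three and correspondingly more permeable; their friction
law carries an extra quadratic IFLS term reproducing the stronger
nonlinearity reported for enzymatically degraded tissue.

The per-velocity friction-law medians default to the study's
regression table (mu = mu_IFLS * IFLS + mu_0 per group x velocity).
Within-group parameter dispersion is log-normal; its magnitude is a
documented guess (the source reports only group contrasts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .constitutive import MaterialParams
from .fe_creep_solver import (
    CreepSolution,
    Geometry,
    LoadingProtocol,
    SolverOptions,
    run_creep,
)
from .friction import TribologyRecord, write_record
from .param_fit import DEFAULT_BOUNDS

__all__ = [
    "GroupSpec",
    "SyntheticExperiment",
    "default_group_specs",
    "sample_group_params",
    "synthesize_record",
    "write_fixture_set",
    "ROTATION_BLOCKS",
]

#: Angular velocity [deg/s] -> rotations per block between lift-offs.
ROTATION_BLOCKS = {36.0: 18, 108.0: 124, 360.0: 180, 1080.0: 516}

_HEALTHY_MEDIANS = dict(E_nf=0.3, E_f0=2.0, E_feps=100.0, k0=2e-15, M=5.0)
_DEGRADATION = 3.0   # softening / permeability factor for degraded groups

#: mu = mu_IFLS * IFLS + mu_0 medians per group and angular velocity.
_FRICTION_TABLE = {
    "healthy-saline": {36.0: (-0.15, 0.11), 108.0: (-0.14, 0.10),
                       360.0: (-0.08, 0.06), 1080.0: (-0.07, 0.06)},
    "healthy-BSF": {36.0: (-0.08, 0.07), 108.0: (-0.07, 0.06),
                    360.0: (-0.07, 0.06), 1080.0: (-0.06, 0.06)},
    "degraded-saline": {36.0: (-0.08, 0.05), 108.0: (-0.13, 0.09),
                        360.0: (-0.08, 0.06), 1080.0: (-0.07, 0.06)},
    "degraded-BSF": {36.0: (-0.04, 0.04), 108.0: (-0.08, 0.06),
                     360.0: (-0.03, 0.03), 1080.0: (-0.06, 0.05)},
}


@dataclass
class GroupSpec:
    """Generating distributions of one experimental group.

    medians: the five identified parameters (MPa / SI units as in
    :class:`MaterialParams`); log_dispersion: sigma of log-normal
    within-group variation; friction_laws: angular velocity ->
    (mu_IFLS, mu_0); quadratic_coef: extra + c * IFLS^2 term;
    noise sigmas: displacement [mm], torque [N m], force [N];
    thickness per plug: normal(mean, sd) [mm].
    """

    label: str
    medians: dict = field(default_factory=lambda: dict(_HEALTHY_MEDIANS))
    log_dispersion: float = 0.15
    friction_laws: dict = field(default_factory=dict)
    quadratic_coef: float = 0.0
    displacement_noise: float = 2.0e-3    # 2 um
    torque_noise: float = 2.0e-4          # N m, well under cell range
    force_noise: float = 0.1              # N
    thickness_mean: float = 1.7
    thickness_sd: float = 0.2
    lubricant_name: str = "saline"
    lubricant_viscosity: float = 0.9      # mPa s

    def __post_init__(self) -> None:
        if self.log_dispersion < 0 or self.displacement_noise < 0 \
                or self.torque_noise < 0 or self.force_noise < 0:
            raise ValueError("noise/dispersion parameters must be >= 0")
        for name, (lo, hi) in DEFAULT_BOUNDS.items():
            if not lo <= self.medians[name] <= hi:
                raise ValueError(
                    f"median {name}={self.medians[name]} outside fit bounds")

    def friction_law(self, omega: float):
        """Callable mu(IFLS) for one angular velocity [deg/s]."""
        slope, icpt = self.friction_laws[float(omega)]
        c2 = self.quadratic_coef

        def law(ifls):
            mu = slope * np.asarray(ifls, float) + icpt \
                + c2 * np.asarray(ifls, float) ** 2
            # friction cannot be negative: the fitted lines extrapolate
            # below zero at the highest IFLS, a physical generator clamps
            return np.maximum(mu, 0.0)

        law.slope, law.intercept, law.quadratic = slope, icpt, c2
        return law


def default_group_specs() -> dict[str, GroupSpec]:
    """The four study groups with their generating conditions."""
    specs = {}
    for label in _FRICTION_TABLE:
        degraded = label.startswith("degraded")
        med = dict(_HEALTHY_MEDIANS)
        if degraded:
            med["E_nf"] /= _DEGRADATION
            med["E_f0"] /= _DEGRADATION
            med["E_feps"] /= _DEGRADATION
            med["k0"] *= _DEGRADATION
        bsf = label.endswith("BSF")
        specs[label] = GroupSpec(
            label=label,
            medians=med,
            friction_laws=dict(_FRICTION_TABLE[label]),
            quadratic_coef=0.03 if degraded else 0.0,
            thickness_mean=2.1 if degraded else 1.7,
            thickness_sd=0.4 if degraded else 0.2,
            lubricant_name="BSF" if bsf else "saline",
            lubricant_viscosity=3.5 if bsf else 0.9,
        )
    return specs


@dataclass
class SyntheticExperiment:
    """One generated record with its ground truth."""

    record: TribologyRecord
    true_params: MaterialParams
    true_law: dict                 # {"mu_ifls", "mu_0", "quadratic"}
    seed: int
    solution: Optional[CreepSolution] = None


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def sample_group_params(spec: GroupSpec, n: int, seed: int = 0,
                        max_attempts: int = 100):
    """Draw ``n`` parameter sets and plug-thickness pairs for a group.

    Parameters are log-normal about the group medians (so the sample
    median converges to the group median); draws falling outside the
    identification bounds are redrawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng_for(seed, 0xA)
    out = []
    for _ in range(n):
        vals = {}
        for name, med in spec.medians.items():
            lo, hi = DEFAULT_BOUNDS[name]
            for attempt in range(max_attempts):
                v = med * np.exp(spec.log_dispersion * rng.standard_normal())
                if lo <= v <= hi:
                    break
            else:
                raise RuntimeError(
                    f"could not draw {name} inside bounds "
                    f"after {max_attempts} attempts")
            vals[name] = float(v)
        th = tuple(float(max(t, 0.8)) for t in
                   rng.normal(spec.thickness_mean, spec.thickness_sd, 2))
        out.append((MaterialParams(**vals), th))
    return out


def _liftoff_schedule(omega: float, t_start: float, t_end: float,
                      liftoff_duration: float = 10.0):
    """(start, end) of each 10-s lift-off between rotation blocks."""
    n_rot = ROTATION_BLOCKS[float(omega)]
    block = n_rot * 360.0 / omega
    windows = []
    t = t_start + block
    while t + liftoff_duration < t_end:
        windows.append((t, t + liftoff_duration))
        t += liftoff_duration + block
    return windows


def synthesize_record(params: MaterialParams,
                      thicknesses: tuple[float, float],
                      spec: GroupSpec,
                      omega: float,
                      protocol: Optional[LoadingProtocol] = None,
                      seed: int = 0,
                      mesh: tuple[int, int] = (15, 10),
                      plug_radius: float = 3.5,
                      model_share: float = 0.5,
                      sample_id: str = "",
                      solution: Optional[CreepSolution] = None,
                      include_liftoffs: bool = True,
                      sampling_rate: float = 10.0) -> SyntheticExperiment:
    """Forward-simulate one experiment and emit its 10-Hz signal log.

    The creep displacement comes from the FE model (coarse mesh by
    default) for the averaged layer thickness; the logged pair
    displacement is the model displacement divided by ``model_share``.
    Torque is generated by inverting mu = (3/2) tau/(N r) with the
    ground-truth mu(IFLS) law, so the pipeline recovers the law
    exactly in the noiseless case.  Lift-offs drop the axial force to
    near zero for 10 s after each rotation block.
    """
    if float(omega) not in ROTATION_BLOCKS:
        raise ValueError(f"angular velocity must be one of "
                         f"{sorted(ROTATION_BLOCKS)} deg/s")
    protocol = protocol or LoadingProtocol()
    rng = _rng_for(seed, 0xB)
    if solution is None:
        geo = Geometry(radius=plug_radius,
                       thickness=0.5 * sum(thicknesses),
                       n_r=mesh[0], n_z=mesh[1])
        solution = run_creep(params, geo, protocol, SolverOptions())

    fs = sampling_rate
    t = np.arange(0.0, protocol.hold_duration, 1.0 / fs)
    t = t[t <= solution.times[-1]]

    r_m = plug_radius * 1e-3
    area = np.pi * r_m**2
    N_nom = protocol.applied_stress * 1e6 * area
    ramp = np.minimum(t / protocol.ramp_duration, 1.0)

    u_model = solution.displacement_at(t)
    disp = u_model / model_share \
        + spec.displacement_noise * rng.standard_normal(len(t))
    force = np.maximum(
        N_nom * ramp + spec.force_noise * rng.standard_normal(len(t)), 0.02)

    ifls = np.clip(solution._interp(solution.por, t)
                   / protocol.applied_stress, 0.0, 1.0)
    law = spec.friction_law(omega)
    mu_true = law(ifls)
    torque = mu_true * force * (2.0 / 3.0) * r_m \
        + spec.torque_noise * rng.standard_normal(len(t))

    if include_liftoffs:
        for a, b in _liftoff_schedule(omega, protocol.ramp_duration,
                                      t[-1]):
            w = (t >= a) & (t < b)
            force[w] = np.abs(
                0.3 + 0.05 * rng.standard_normal(int(w.sum())))
            torque[w] = spec.torque_noise * rng.standard_normal(
                int(w.sum()))

    record = TribologyRecord(
        time=t, axial_force=force, axial_displacement=disp, torque=torque,
        plug_radius=plug_radius, pair_thicknesses=thicknesses,
        angular_velocity=float(omega), lubricant_name=spec.lubricant_name,
        lubricant_viscosity=spec.lubricant_viscosity, group=spec.label,
        sample_id=sample_id)
    return SyntheticExperiment(
        record=record, true_params=params,
        true_law={"mu_ifls": law.slope, "mu_0": law.intercept,
                  "quadratic": law.quadratic},
        seed=seed, solution=solution)


def write_fixture_set(out_dir: str | Path, seed: int = 0,
                      n_pairs: int = 3,
                      velocities: tuple = (36.0, 108.0, 360.0, 1080.0),
                      protocol: Optional[LoadingProtocol] = None,
                      specs: Optional[dict[str, GroupSpec]] = None,
                      mesh: tuple[int, int] = (15, 10)) -> dict:
    """Emit the full fixture set: groups x pairs x velocities.

    With the defaults this writes 4 x 3 x 4 = 48 record CSVs (plus
    JSON sidecars) and a ``manifest.json`` holding the per-record
    ground truth and content hashes.  The creep simulation is shared
    across the four velocities of a pair (rotation does not enter the
    creep model).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = specs or default_group_specs()
    protocol = protocol or LoadingProtocol()
    manifest = {"seed": int(seed), "records": []}
    for gi, (label, spec) in enumerate(sorted(specs.items())):
        draws = sample_group_params(spec, n_pairs, seed=seed * 1000 + gi)
        for pi, (params, th) in enumerate(draws):
            geo = Geometry(radius=3.5, thickness=0.5 * sum(th),
                           n_r=mesh[0], n_z=mesh[1])
            sol = run_creep(params, geo, protocol, SolverOptions())
            for vi, omega in enumerate(velocities):
                sample_id = f"{label}_p{pi}_w{int(omega)}"
                rec_seed = ((seed * 1000 + gi) * 10 + pi) * 10 + vi
                exp = synthesize_record(
                    params, th, spec, omega, protocol, seed=rec_seed,
                    mesh=mesh, sample_id=sample_id, solution=sol)
                fname = out_dir / f"{sample_id}.csv"
                write_record(exp.record, fname)
                digest = hashlib.sha256(fname.read_bytes()).hexdigest()
                manifest["records"].append({
                    "file": fname.name,
                    "group": label,
                    "pair": pi,
                    "angular_velocity_deg_s": float(omega),
                    "sample_id": sample_id,
                    "seed": rec_seed,
                    "sha256": digest,
                    "true_params": params.to_dict(),
                    "true_law": exp.true_law,
                    "pair_thicknesses_mm": list(th),
                })
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
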