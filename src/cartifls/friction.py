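"""Tribology signal processing, IFLS pairing, regressions and statistics.

Turns raw tribo-rheometer logs (axial force, axial displacement,
torque at 10 Hz) plus a creep simulation into the study's derived
quantities:

* lift-off exclusion and 10-s moving-average torque filtering,
* coefficient of friction mu = (3/2) tau / (N r) for annular rotating
  contact,
* effective velocity (r_eff = 2r/3) and Hersey number,
* mu-IFLS and strain-IFLS ordinary-least-squares regressions
  (mu = mu_IFLS * IFLS + mu_0),
* Stribeck surfaces mu(IFLS, log10 Hersey),
* nonparametric group statistics (Kolmogorov-Smirnov screen,
  Kruskal-Wallis, Friedman, Pearson correlations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fe_creep_solver import CreepSolution

__all__ = [
    "TribologyRecord",
    "LiftoffOptions",
    "FrictionSeries",
    "RegressionResult",
    "StribeckSurface",
    "StatsReport",
    "read_record",
    "write_record",
    "preprocess_signals",
    "compute_cof",
    "kinematics",
    "compute_ifls_series",
    "linear_regression",
    "mu_ifls_analysis",
    "build_stribeck_surface",
    "group_stats",
]

GROUPS = ("healthy-saline", "healthy-BSF", "degraded-saline", "degraded-BSF")


@dataclass
class TribologyRecord:
    """One experiment's raw signals and metadata.

    Signals are uniformly sampled (10 Hz in the study).  Units:
    time [s], axial_force [N], axial_displacement [mm], torque [N m],
    plug_radius [mm], pair_thicknesses [mm], angular_velocity [deg/s],
    lubricant_viscosity [mPa s].
    """

    time: np.ndarray
    axial_force: np.ndarray
    axial_displacement: np.ndarray
    torque: np.ndarray
    plug_radius: float
    pair_thicknesses: tuple[float, float]
    angular_velocity: float
    lubricant_name: str
    lubricant_viscosity: float
    group: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        for name in ("axial_force", "axial_displacement", "torque"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise ValueError(f"{name} length does not match time base")
            setattr(self, name, arr)
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")
        if self.plug_radius <= 0:
            raise ValueError("plug_radius must be > 0")
        if min(self.pair_thicknesses) <= 0:
            raise ValueError("thicknesses must be > 0")
        if self.lubricant_viscosity <= 0:
            raise ValueError("lubricant_viscosity must be > 0")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        self.time = t

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    @property
    def mean_thickness(self) -> float:
        return 0.5 * sum(self.pair_thicknesses)


def write_record(record: TribologyRecord, csv_path: str | Path) -> None:
    """Write signals as CSV with a JSON metadata sidecar (same stem)."""
    csv_path = Path(csv_path)
    pd.DataFrame({
        "time_s": record.time,
        "axial_force_N": record.axial_force,
        "axial_disp_mm": record.axial_displacement,
        "torque_Nm": record.torque,
    }).to_csv(csv_path, index=False, float_format="%.8g")
    meta = {
        "plug_radius_mm": record.plug_radius,
        "pair_thicknesses_mm": list(record.pair_thicknesses),
        "angular_velocity_deg_s": record.angular_velocity,
        "lubricant_name": record.lubricant_name,
        "lubricant_viscosity_mPas": record.lubricant_viscosity,
        "group": record.group,
        "sample_id": record.sample_id,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_record(csv_path: str | Path) -> TribologyRecord:
    """Read a record CSV and its JSON sidecar."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return TribologyRecord(
        time=df["time_s"].to_numpy(),
        axial_force=df["axial_force_N"].to_numpy(),
        axial_displacement=df["axial_disp_mm"].to_numpy(),
        torque=df["torque_Nm"].to_numpy(),
        plug_radius=meta["plug_radius_mm"],
        pair_thicknesses=tuple(meta["pair_thicknesses_mm"]),
        angular_velocity=meta["angular_velocity_deg_s"],
        lubricant_name=meta["lubricant_name"],
        lubricant_viscosity=meta["lubricant_viscosity_mPas"],
        group=meta["group"],
        sample_id=meta.get("sample_id", ""),
    )


# ---------------------------------------------------------------------------
# Signal preprocessing
# ---------------------------------------------------------------------------

@dataclass
class LiftoffOptions:
    """Lift-off detection thresholds (config-exposed).

    An interval is flagged when the axial force stays below
    ``threshold_fraction`` of the nominal load for at least
    ``min_duration`` seconds; flagged intervals are widened by
    ``guard`` seconds on both sides.
    """

    threshold_fraction: float = 0.2
    min_duration: float = 5.0
    guard: float = 2.0
    max_excluded_fraction: float = 0.5
    nominal_load: Optional[float] = None   # [N]; default: 90th percentile


class RecordRejected(ValueError):
    """Raised when lift-off exclusion removes too much of a record."""


def _merge_intervals(iv: list[tuple[float, float]]):
    out: list[tuple[float, float]] = []
    for a, b in sorted(iv):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def preprocess_signals(record: TribologyRecord,
                       liftoff_opts: Optional[LiftoffOptions] = None,
                       window_s: float = 10.0,
                       extra_exclusions: Optional[list] = None):
    """Excise lift-off events and moving-average filter the torque.

    Lift-offs are detected from the force signal, excluded with a
    guard margin, and the remaining torque samples are stitched
    together before applying a centered moving average of width
    ``window_s`` so that the filter never mixes loaded and unloaded
    data.

    ``extra_exclusions`` are additional (t_start, t_end) windows to
    excise (e.g. the load-application transient).

    Returns
    -------
    (tau_filtered, excluded_intervals) — filtered torque aligned with
    ``record.time`` (NaN inside excluded intervals), and the list of
    excluded (t_start, t_end) windows.
    """
    opts = liftoff_opts or LiftoffOptions()
    t = record.time
    f = record.axial_force
    fs = record.sampling_rate
    # a high quantile is robust even when much of the record is unloaded
    nominal = (opts.nominal_load if opts.nominal_load is not None
               else float(np.percentile(f, 90)))
    low = f < opts.threshold_fraction * nominal

    intervals: list[tuple[float, float]] = []
    if low.any():
        idx = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8),
                                                     [0]))))
        for a, b in idx.reshape(-1, 2):
            dur = (b - a) / fs
            if dur >= opts.min_duration:
                intervals.append((t[a] - opts.guard,
                                  t[min(b, len(t) - 1)] + opts.guard))
    if extra_exclusions:
        intervals.extend((float(a), float(b)) for a, b in extra_exclusions)
    intervals = _merge_intervals(intervals)

    mask = np.zeros(len(t), dtype=bool)
    for a, b in intervals:
        mask |= (t >= a) & (t <= b)
    if mask.mean() > opts.max_excluded_fraction:
        raise RecordRejected(
            f"{mask.mean():.0%} of samples excluded by lift-off detection")

    tau = record.torque
    kept = ~mask
    stitched = tau[kept]
    win = max(int(round(window_s * fs)), 1)
    filt = (pd.Series(stitched)
            .rolling(win, center=True, min_periods=1).mean().to_numpy())
    out = np.full(len(t), np.nan)
    out[kept] = filt
    return out, intervals


def compute_cof(torque, load, radius: float):
    """Coefficient of friction mu = (3/2) |tau| / (N r) for annular contact.

    ``torque`` [N m], ``load`` [N] (> 0 outside lift-offs),
    ``radius`` [m].  Accepts scalars or arrays; NaNs propagate.
    """
    torque = np.asarray(torque, dtype=float)
    load = np.asarray(load, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    valid = np.isnan(torque) | np.isnan(load)
    if np.any((load <= 0) & ~valid):
        raise ValueError(
            "non-positive load outside excluded intervals: "
            "lift-off detection failed")
    return (1.5 * np.abs(torque) / (load * radius))[()]


@dataclass
class FrictionSeries:
    """Filtered friction series of one record."""

    time: np.ndarray
    mu: np.ndarray                       # NaN inside excluded intervals
    excluded_intervals: list
    v_eff: float                         # [mm/s]
    hersey: float

    def __post_init__(self) -> None:
        for a, b in zip(self.excluded_intervals, self.excluded_intervals[1:]):
            if a[1] > b[0]:
                raise ValueError("excluded intervals overlap")
        if np.any(self.mu[~np.isnan(self.mu)] < 0):
            raise ValueError("mu must be >= 0 outside excluded intervals")

    @property
    def retained(self) -> np.ndarray:
        return ~np.isnan(self.mu)


def friction_series(record: TribologyRecord,
                    applied_stress: float,
                    liftoff_opts: Optional[LiftoffOptions] = None,
                    window_s: float = 10.0,
                    settle_s: float = 15.0) -> FrictionSeries:
    """Full preprocessing of one record into a :class:`FrictionSeries`.

    ``settle_s`` excises the load-application transient (ramp plus
    filter width) at the start of the record before friction analysis.
    """
    extra = ([(record.time[0] - 1.0, record.time[0] + settle_s)]
             if settle_s > 0 else None)
    tau_f, intervals = preprocess_signals(record, liftoff_opts, window_s,
                                          extra_exclusions=extra)
    load = record.axial_force.copy()
    load[np.isnan(tau_f)] = np.nan
    mu = compute_cof(tau_f, load, record.plug_radius * 1e-3)
    v_eff, H = kinematics(record.angular_velocity, record.plug_radius,
                          record.lubricant_viscosity, applied_stress)
    return FrictionSeries(record.time, mu, intervals, v_eff, H)


# ---------------------------------------------------------------------------
# Kinematics / lubrication numbers
# ---------------------------------------------------------------------------

def kinematics(omega_deg_s: float, radius_mm: float, viscosity_mPas: float,
               applied_stress_MPa: float,
               convention: str = "W_over_2reff") -> tuple[float, float]:
    """Effective sliding velocity and Hersey number of a rotating contact.

    The effective radius of a circular contact spinning about its axis
    is r_eff = (2/3) r (area-average of the speed distribution), so
    v_eff = omega * r_eff.  The Hersey number is
    H = v_eff [m/s] * viscosity [Pa s] / (load per unit length [N/m])
    with the load per unit length taken as W / (2 r_eff) by default
    (alternatives: "W_over_2r", "W_over_pi2r").

    Returns (v_eff [mm/s], H [-]).
    """
    if min(omega_deg_s, radius_mm, viscosity_mPas, applied_stress_MPa) <= 0:
        raise ValueError("all inputs must be > 0")
    r = radius_mm * 1e-3
    r_eff = (2.0 / 3.0) * r
    v_eff = np.deg2rad(omega_deg_s) * r_eff           # m/s
    W = applied_stress_MPa * 1e6 * np.pi * r**2       # N
    if convention == "W_over_2reff":
        L_w = W / (2.0 * r_eff)
    elif convention == "W_over_2r":
        L_w = W / (2.0 * r)
    elif convention == "W_over_pi2r":
        L_w = W / (np.pi * 2.0 * r)
    else:
        raise ValueError(f"unknown Hersey convention {convention!r}")
    H = v_eff * (viscosity_mPas * 1e-3) / L_w
    return v_eff * 1e3, float(H)


# ---------------------------------------------------------------------------
# IFLS pairing
# ---------------------------------------------------------------------------

def compute_ifls_series(solution: CreepSolution, applied_stress: float,
                        at_times: Optional[np.ndarray] = None):
    """IFLS(t) = POR(t)/applied stress (clipped to [0, 1]) and strain(t).

    ``applied_stress`` [MPa] is the nominal contact pressure
    (load/area).  With ``at_times`` given, both series are linearly
    interpolated onto that grid; times outside the simulated span
    raise.
    """
    if applied_stress <= 0:
        raise ValueError("applied_stress must be > 0")
    if at_times is None:
        ifls = solution.por / applied_stress
        return np.clip(ifls, 0.0, 1.0), solution.axial_strain.copy()
    at_times = np.asarray(at_times, dtype=float)
    por = solution._interp(solution.por, at_times)
    strain = solution.strain_at(at_times)
    return np.clip(por / applied_stress, 0.0, 1.0), strain


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """OLS slope/intercept with standard errors and R^2."""

    slope: float
    intercept: float
    r_squared: float
    slope_sd: float
    intercept_sd: float
    n_points: int
    context: str = ""

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return asdict(self)


def linear_regression(x, y, context: str = "") -> RegressionResult:
    """Ordinary least squares y = slope * x + intercept.

    Constant-y input returns slope 0 with R^2 = 0 (convention);
    constant-x input is a degenerate design and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0.0:
        raise ValueError("constant x: degenerate design")
    if np.ptp(y) == 0.0:
        return RegressionResult(0.0, float(y[0]), 0.0, 0.0, 0.0, len(x),
                                context)
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), slope_sd=float(res.stderr),
        intercept_sd=float(res.intercept_stderr), n_points=len(x),
        context=context)


def mu_ifls_analysis(friction: FrictionSeries, ifls: np.ndarray,
                     strain: np.ndarray, low_n: int = 100,
                     ifls_range: Optional[tuple[float, float]] = None,
                     se_inflation: float = 1.0):
    """Pair retained mu samples with IFLS and strain; fit both regressions.

    ``ifls`` and ``strain`` must already be aligned with
    ``friction.time`` (use :func:`compute_ifls_series` with
    ``at_times=friction.time``; both clocks zeroed at load onset).

    ``ifls_range`` optionally restricts the mu-IFLS fit to an IFLS
    band (e.g. the linear regime below the zero-friction intercept of
    the law; the study evaluated group differences for IFLS between
    0.25 and 0.7).  ``se_inflation`` scales the reported standard
    errors to account for serial correlation introduced by the
    moving-average filter (an effective-sample-size correction of
    sqrt(window x rate) is appropriate for 10-s filtered 10-Hz data).

    Returns (mu-IFLS regression, mu-strain regression, paired table).
    The mu-IFLS R^2 doubles as the linearity diagnostic used to
    compare healthy and degraded behavior.
    """
    if not (len(ifls) == len(strain) == len(friction.time)):
        raise ValueError("series must share the friction time base")
    keep = friction.retained
    table = pd.DataFrame({
        "time_s": friction.time[keep],
        "mu": friction.mu[keep],
        "ifls": np.asarray(ifls)[keep],
        "strain": np.asarray(strain)[keep],
    })
    flag_low_n = len(table) < low_n
    sub = table
    if ifls_range is not None:
        sub = table[(table["ifls"] >= ifls_range[0])
                    & (table["ifls"] <= ifls_range[1])]
    reg_ifls = linear_regression(sub["ifls"], sub["mu"],
                                 context="mu_vs_ifls")
    reg_eps = linear_regression(sub["strain"], sub["mu"],
                                context="mu_vs_strain")
    if se_inflation != 1.0:
        for reg in (reg_ifls, reg_eps):
            reg.slope_sd *= se_inflation
            reg.intercept_sd *= se_inflation
    table.attrs["low_n"] = flag_low_n
    return reg_ifls, reg_eps, table


# ---------------------------------------------------------------------------
# Stribeck surface
# ---------------------------------------------------------------------------

@dataclass
class StribeckSurface:
    """mu as a bivariate function of IFLS and log10 Hersey number.

    Built from per-velocity mu-IFLS regressions; linear interpolation
    across log10(H) between the source regressions.
    """

    ifls_grid: np.ndarray
    log_hersey: np.ndarray              # sorted knots
    mu: np.ndarray                      # (n_ifls, n_hersey)
    sources: list                       # (hersey, RegressionResult)

    def evaluate(self, ifls, hersey):
        """Bilinear lookup: linear in IFLS and in log10(Hersey)."""
        ifls_b, lh_b = np.broadcast_arrays(
            np.asarray(ifls, dtype=float),
            np.log10(np.asarray(hersey, dtype=float)))
        shape = ifls_b.shape
        fi = ifls_b.ravel()
        lh = np.clip(lh_b.ravel(), self.log_hersey[0], self.log_hersey[-1])
        j1 = np.clip(np.searchsorted(self.log_hersey, lh, side="right"),
                     1, len(self.log_hersey) - 1)
        j0 = j1 - 1
        span = self.log_hersey[j1] - self.log_hersey[j0]
        w = np.where(span > 0, (lh - self.log_hersey[j0])
                     / np.where(span > 0, span, 1.0), 0.0)
        lo = np.array([np.interp(f, self.ifls_grid, self.mu[:, j])
                       for f, j in zip(fi, j0)])
        hi = np.array([np.interp(f, self.ifls_grid, self.mu[:, j])
                       for f, j in zip(fi, j1)])
        return ((1.0 - w) * lo + w * hi).reshape(shape)[()]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.ifls_grid):
            for j, lh in enumerate(self.log_hersey):
                rows.append({"ifls": f, "log10_hersey": lh,
                             "mu": self.mu[i, j]})
        return pd.DataFrame(rows)


def build_stribeck_surface(regressions: Sequence[tuple[float,
                                                       RegressionResult]],
                           ifls_grid: Optional[np.ndarray] = None,
                           ) -> StribeckSurface:
    """Assemble a Stribeck surface from (hersey, regression) pairs.

    Duplicate Hersey values are collapsed by averaging the regression
    coefficients (with a warning).  At a source Hersey knot the
    surface reproduces the source regression exactly.
    """
    import warnings

    if len(regressions) < 2:
        raise ValueError("need regressions for at least 2 velocities")
    if ifls_grid is None:
        ifls_grid = np.linspace(0.0, 1.0, 51)
    by_h: dict[float, list[RegressionResult]] = {}
    for h, reg in regressions:
        by_h.setdefault(float(h), []).append(reg)
    knots = []
    for h, regs in sorted(by_h.items()):
        if len(regs) > 1:
            warnings.warn(f"duplicate Hersey value {h:g}: averaging "
                          f"{len(regs)} regressions")
            slope = np.mean([r.slope for r in regs])
            icpt = np.mean([r.intercept for r in regs])
            reg = RegressionResult(slope, icpt,
                                   float(np.mean([r.r_squared
                                                  for r in regs])),
                                   0.0, 0.0,
                                   sum(r.n_points for r in regs),
                                   regs[0].context)
        else:
            reg = regs[0]
        knots.append((h, reg))
    log_h = np.log10([h for h, _ in knots])
    mu = np.column_stack([reg.predict(ifls_grid) for _, reg in knots])
    return StribeckSurface(ifls_grid=np.asarray(ifls_grid),
                           log_hersey=log_h, mu=mu, sources=list(knots))


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

@dataclass
class StatsReport:
    """Nonparametric group comparison report.

    All tests are two-sided at alpha = 0.05.  ``excluded_conditions``
    records conditions removed before group comparisons (the study
    excluded the slowest velocity).
    """

    normality: dict = field(default_factory=dict)
    kruskal_wallis: dict = field(default_factory=dict)
    friedman: dict = field(default_factory=dict)
    pearson: dict = field(default_factory=dict)
    excluded_conditions: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        s = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(s)
        return s


def group_stats(outcomes: pd.DataFrame,
                outcome_cols: Sequence[str],
                group_col: str = "group",
                velocity_col: str = "v_eff",
                sample_col: str = "sample_id",
                exclude_slowest: bool = True,
                param_col: str = "E_nf") -> StatsReport:
    """Nonparametric statistics over the per-sample outcome table.

    Runs a Kolmogorov-Smirnov normality screen per outcome, a
    Kruskal-Wallis test across groups per outcome (after optionally
    excluding the slowest velocity), a Friedman test of the velocity
    effect within samples, and Pearson correlations of ``param_col``
    with mu_0 and mu_IFLS when those columns exist.
    """
    report = StatsReport()
    df = outcomes.copy()
    if exclude_slowest and velocity_col in df:
        v_min = df[velocity_col].min()
        report.excluded_conditions.append(
            {"condition": f"{velocity_col} == {v_min:g}",
             "n_removed": int((df[velocity_col] == v_min).sum())})
        df_cmp = df[df[velocity_col] != v_min]
    else:
        df_cmp = df

    for col in outcome_cols:
        vals = df_cmp[col].dropna().to_numpy()
        if len(vals) >= 3 and np.std(vals) > 0:
            z = (vals - vals.mean()) / vals.std(ddof=1)
            ks = stats.kstest(z, "norm")
            report.normality[col] = {"statistic": float(ks.statistic),
                                     "p_value": float(ks.pvalue),
                                     "n": len(vals)}
        groups = [g[col].dropna().to_numpy()
                  for _, g in df_cmp.groupby(group_col)]
        ns = [len(g) for g in groups]
        if len(groups) >= 2 and min(ns) >= 2:
            kw = stats.kruskal(*groups)
            report.kruskal_wallis[col] = {
                "statistic": float(kw.statistic),
                "p_value": float(kw.pvalue),
                "n_per_group": ns}
        else:
            report.skipped.append({"test": "kruskal_wallis", "outcome": col,
                                   "reason": "group n < 2"})
        # Friedman: velocity effect within samples (uses all velocities)
        try:
            pivot = df.pivot_table(index=sample_col, columns=velocity_col,
                                   values=col)
            pivot = pivot.dropna()
            if pivot.shape[0] >= 2 and pivot.shape[1] >= 3:
                with np.errstate(invalid="ignore"):
                    fr = stats.friedmanchisquare(
                        *[pivot[c].to_numpy() for c in pivot.columns])
                stat, pval = float(fr.statistic), float(fr.pvalue)
                if np.isnan(stat):
                    # fully tied blocks carry no velocity effect
                    stat, pval = 0.0, 1.0
                report.friedman[col] = {"statistic": stat,
                                        "p_value": pval,
                                        "n_samples": int(pivot.shape[0]),
                                        "n_velocities": int(pivot.shape[1])}
            else:
                report.skipped.append({"test": "friedman", "outcome": col,
                                       "reason": "insufficient blocks"})
        except KeyError:
            report.skipped.append({"test": "friedman", "outcome": col,
                                   "reason": "missing columns"})

    if param_col in df_cmp:
        for target in ("mu_0", "mu_ifls"):
            if target in df_cmp:
                sub = df_cmp[[param_col, target]].dropna()
                if len(sub) >= 3 and sub[param_col].std() > 0 \
                        and sub[target].std() > 0:
                    r, p = stats.pearsonr(sub[param_col], sub[target])
                    report.pearson[f"{param_col}_vs_{target}"] = {
                        "r": float(r), "r_squared": float(r**2),
                        "p_value": float(p), "n": len(sub)}
    return report
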