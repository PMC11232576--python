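"""Weighted, shift-aware, outlier-robust parameter estimation.

The observable is the adjusted relative isotope abundance (RIA),
``(I6 / (I0 + I6)) / n_leu``, of one *observation* — one peptide in one
chromatographic fraction at one charge state — tracked over the sampling
times. Fitting minimizes a weighted sum of squared errors between model RIA
curves and observed RIAs corrected by a per-fluid vertical shift, with
weights proportional to the light-channel intensity I0 (stronger signals are
more accurate). Robustness comes from a two-step procedure (fit, flag
outliers against a half-dynamic-range band, refit) and confidence intervals
from a nonparametric bootstrap over retained data points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .models import (get_model, integrate, integrate_two_bc_delay,
                     DelayParams, TwoBCParams, IntegrationError)
from .protocols import InfusionProtocol

__all__ = [
    "Observation", "FitResult", "FittingError", "compute_ria",
    "weighted_objective", "fit_bounded", "fit_joint", "robust_two_step_fit",
    "bootstrap_ci", "pool_protein", "PooledFit",
]

T_MAX = 36.2


class FittingError(RuntimeError):
    pass


def compute_ria(i0, i6, n_leu: int):
    """Adjusted RIA: ``(i6 / (i0 + i6)) / n_leu``.

    Zero total signal yields NaN (a missing value, not 0). Accepts scalars or
    arrays; intensities must be nonnegative and ``n_leu >= 1``.
    """
    if n_leu < 1:
        raise ValueError("n_leu must be >= 1")
    i0 = np.asarray(i0, float)
    i6 = np.asarray(i6, float)
    if np.any(i0 < 0) or np.any(i6 < 0):
        raise ValueError("intensities must be >= 0")
    total = i0 + i6
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, i6 / np.where(total > 0, total, 1.0), np.nan)
    return out / n_leu if out.ndim else float(out) / n_leu


@dataclass
class Observation:
    """One peptide x fraction x charge RIA time series in one fluid."""

    protein_id: str
    peptide_seq: str
    fraction: str
    charge: int
    fluid: str
    n_leu: int
    times: np.ndarray
    i0: np.ndarray
    i6: np.ndarray
    shared: bool = False        # peptide maps to more than one protein
    ria_offset: float = 0.0     # additive alignment offset (pooling)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.i0 = np.asarray(self.i0, float)
        self.i6 = np.asarray(self.i6, float)
        if self.n_leu < 0:
            raise ValueError("n_leu must be >= 0")
        # n_leu == 0 is allowed only so the leucine filter can see and
        # remove such peptides; RIA is undefined for them
        if self.fluid not in ("plasma", "csf"):
            raise ValueError(f"unknown fluid {self.fluid!r}")
        if np.any((self.times < 0) | (self.times > T_MAX)):
            raise ValueError(f"times must lie within [0, {T_MAX}]")

    @property
    def key(self) -> str:
        return f"{self.peptide_seq}|{self.fraction}|{self.charge}|{self.fluid}"

    @property
    def ria(self) -> np.ndarray:
        """Adjusted RIA minus the alignment offset; NaN where missing."""
        return compute_ria(self.i0, self.i6, self.n_leu) - self.ria_offset

    def n_usable(self) -> int:
        return int(np.sum(~np.isnan(self.ria)))


@dataclass
class FitResult:
    """Point estimates for one model on one set of observations."""

    model: str
    params: dict                      # rate (and tau) estimates by name
    shifts: dict                      # per-fluid vertical shift
    weighted_sse: float
    outlier_flags: dict = field(default_factory=dict)  # obs key -> bool array
    ci95: dict | None = None
    n_boot: int = 0
    boot_flagged: bool = False
    converged: bool = True
    message: str = ""
    n_points: int = 0
    fluids: tuple = ()

    @property
    def theta(self) -> np.ndarray:
        spec = get_model(self.model)
        vals = [self.params[k] for k in spec.rate_names]
        if spec.has_delay:
            vals.append(self.params["tau"])
        vals += [self.shifts[f] for f in (self.fluids or spec.fluids)]
        return np.array(vals, float)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "shifts": {k: float(v) for k, v in self.shifts.items()},
            "weighted_sse": float(self.weighted_sse),
            "converged": bool(self.converged),
            "message": self.message,
            "n_points": int(self.n_points),
            "n_boot": int(self.n_boot),
            "boot_flagged": bool(self.boot_flagged),
            "outlier_flags": {k: np.asarray(v).astype(bool).tolist()
                              for k, v in self.outlier_flags.items()},
        }
        if self.ci95 is not None:
            d["ci95"] = {k: [float(lo), float(hi)]
                         for k, (lo, hi) in self.ci95.items()}
        return d


# ---------------------------------------------------------------------------
# Assembled point data
# ---------------------------------------------------------------------------

@dataclass
class _PointData:
    """Stacked usable points of a set of observations, per fluid."""

    fluids: tuple
    t: dict           # fluid -> times
    ria: dict         # fluid -> adjusted (offset-corrected) RIA
    w: dict           # fluid -> normalized weights I0 / mean(I0)
    obs_key: dict     # fluid -> observation key per point
    point_idx: dict   # fluid -> index of the point within its observation

    @property
    def n_points(self) -> int:
        return int(sum(len(v) for v in self.t.values()))


def _assemble(observations, fluids, exclude: dict | None = None) -> _PointData:
    t, ria, w, keys, pidx = {}, {}, {}, {}, {}
    for fl in fluids:
        ts, rs, i0s, ks, ix = [], [], [], [], []
        for obs in observations:
            if obs.fluid != fl:
                continue
            r = obs.ria
            ok = ~np.isnan(r) & ~np.isnan(obs.i0)
            if exclude is not None and obs.key in exclude:
                ok &= ~np.asarray(exclude[obs.key], bool)
            ts.append(obs.times[ok])
            rs.append(r[ok])
            i0s.append(obs.i0[ok])
            ks.extend([obs.key] * int(ok.sum()))
            ix.extend(np.nonzero(ok)[0].tolist())
        if not ts or sum(len(x) for x in ts) == 0:
            raise FittingError(f"no usable data points for fluid {fl!r}")
        tt = np.concatenate(ts)
        i0 = np.concatenate(i0s)
        t[fl] = tt
        ria[fl] = np.concatenate(rs)
        w[fl] = i0 / np.mean(i0)
        keys[fl] = np.array(ks)
        pidx[fl] = np.array(ix, int)
    return _PointData(tuple(fluids), t, ria, w, keys, pidx)


def weighted_objective(model_curve, obs: Observation, shift: float) -> float:
    """Weighted SSE of one observation against a model trajectory.

    ``model_curve`` is a Trajectory evaluated at the observation times.
    Weights are I0 / mean(I0) over non-missing points. Raises if every point
    is missing.
    """
    r = obs.ria
    ok = ~np.isnan(r) & ~np.isnan(obs.i0)
    if not np.any(ok):
        raise FittingError("all points of the observation are missing")
    model = np.asarray(model_curve.r(obs.fluid), float)
    if model.shape != obs.times.shape:
        raise ValueError("model curve must be evaluated at observation times")
    w = obs.i0[ok] / np.mean(obs.i0[ok])
    res = model[ok] - (r[ok] - shift)
    return float(np.sum(w * res ** 2))


# ---------------------------------------------------------------------------
# Bounded optimization
# ---------------------------------------------------------------------------

def _model_fluid(spec, fluid: str) -> str:
    # the single-fluid model's one observed state fits either fluid's data
    return spec.fluids[0] if len(spec.fluids) == 1 else fluid


def _data_fluids(spec, observations) -> tuple:
    if len(spec.fluids) > 1:
        return spec.fluids
    present = sorted({o.fluid for o in observations})
    if len(present) != 1:
        raise FittingError(
            "the single-fluid model requires observations from one fluid")
    return tuple(present)


_PROPAGATOR_CACHE: dict = {}


def _curves_at(spec, rates, tau, protocol, times_by_fluid, method="expm"):
    fluids = tuple(times_by_fluid)
    if spec.name == "single":
        from .models import single_fluid_curve
        _, r = single_fluid_curve(rates[0], rates[1], protocol,
                                  times_by_fluid[fluids[0]])
        return {fluids[0]: r}
    all_t = np.unique(np.concatenate([[0.0]] + [times_by_fluid[f]
                                                for f in fluids]))
    if spec.has_delay:
        base = TwoBCParams(*rates)
        traj = integrate_two_bc_delay(DelayParams(base, tau), protocol, all_t)
        out = {}
        for fl in fluids:
            idx = np.searchsorted(all_t, times_by_fluid[fl])
            out[fl] = traj.r(_model_fluid(spec, fl))[idx]
        return out
    # repeated evaluations at the same grid share a cached propagator
    from .models import LinearPropagator
    key = (spec.name, protocol, all_t.tobytes())
    prop = _PROPAGATOR_CACHE.get(key)
    if prop is None:
        if len(_PROPAGATOR_CACHE) > 256:
            _PROPAGATOR_CACHE.clear()
        prop = LinearPropagator(spec, protocol, all_t)
        _PROPAGATOR_CACHE[key] = prop
    states = prop.states(rates)
    out = {}
    for fl in fluids:
        idx = np.searchsorted(all_t, times_by_fluid[fl])
        col = spec.state_names.index(_model_fluid(spec, fl))
        out[fl] = states[idx, col]
    return out


def _objective(theta, spec, data: _PointData, protocol):
    nr = spec.n_rates
    rates = theta[:nr]
    tau = theta[nr] if spec.has_delay else 0.0
    shifts = theta[nr + (1 if spec.has_delay else 0):]
    try:
        curves = _curves_at(spec, rates, tau, protocol, data.t)
    except IntegrationError:
        return 1e12
    sse = 0.0
    for i, fl in enumerate(data.fluids):
        res = curves[fl] - (data.ria[fl] - shifts[i])
        sse += float(np.sum(data.w[fl] * res ** 2))
    return sse


def _default_inits(spec, data) -> list:
    """Multi-start initial points; single-fluid estimates would normally seed
    joint models (see robust/pool paths), this is the generic fallback."""
    inits = []
    if spec.name == "single":
        # data-informed starts: a scales the curve amplitude toward the
        # observed RIA range, b sweeps slow-to-fast clearance
        fl = data.fluids[0]
        amp = max(float(np.nanmax(data.ria[fl]) - np.nanmin(data.ria[fl])),
                  1e-4)
        for b in (0.03, 0.1, 0.3, 1.0):
            a0 = min(max(amp * b / 0.6, 1e-4), 9.9)
            inits.append(np.array([a0, b, 0.0]))
    else:
        base = {"syn_plasma": 0.02, "syn_cns": 0.02, "a": 0.02}
        for scale in [0.05, 0.1, 0.3, 0.6, 1.2]:
            th = []
            for name in spec.rate_names:
                th.append(base.get(name, scale))
            if spec.has_delay:
                th.append(1.0)
            th += [0.0] * len(spec.fluids)
            inits.append(np.array(th))
    return inits


LOG_RATE_FLOOR = 1e-4
TIE_TOLERANCE = 0.05


def fit_bounded(model, observations, init=None, bounds=None,
                protocol: InfusionProtocol | None = None,
                exclude: dict | None = None, min_points: int = 4,
                multi_start: bool = True) -> FitResult:
    """Bound-constrained weighted least squares (quasi-Newton, L-BFGS-B).

    ``init`` may be a single parameter vector (rates [, tau], shifts) or a
    list of starting points; with ``multi_start`` the default start grid is
    appended. Deterministic given data and starting points. For joint
    (multi-compartment) models the rates are optimized on a log scale, which
    conditions the sloppy objective much better; near-tied objectives are
    resolved in favor of the earliest starting point so that estimates stay
    reproducible on flat ridges. Raises ``FittingError`` when a fluid has
    fewer than ``min_points`` usable points.
    """
    spec = get_model(model)
    protocol = protocol or InfusionProtocol()
    fluids = _data_fluids(spec, observations)
    data = _assemble(observations, fluids, exclude)
    for fl in fluids:
        if len(data.t[fl]) < min_points:
            raise FittingError(
                f"fluid {fl!r} has {len(data.t[fl])} usable points; "
                f"need >= {min_points}")
    if bounds is None:
        bounds = spec.default_bounds()
    ndim = spec.n_rates + (1 if spec.has_delay else 0) + len(fluids)
    if len(bounds) != ndim:
        raise ValueError(f"expected {ndim} bounds, got {len(bounds)}")

    starts = []
    if init is not None:
        init = np.atleast_2d(np.asarray(init, float))
        for row in init:
            starts.append(np.clip(row, [b[0] for b in bounds],
                                  [b[1] for b in bounds]))
    if multi_start or not starts:
        starts.extend(_default_inits(spec, data))

    log_rates = spec.name != "single"
    nr = spec.n_rates

    if log_rates:
        opt_bounds = [(np.log(max(lo, LOG_RATE_FLOOR)), np.log(max(hi, 2 * LOG_RATE_FLOOR)))
                      for lo, hi in bounds[:nr]] + list(bounds[nr:])

        def to_opt(theta):
            z = np.array(theta, float)
            z[:nr] = np.log(np.clip(z[:nr], LOG_RATE_FLOOR, None))
            return z

        def from_opt(z):
            theta = np.array(z, float)
            theta[:nr] = np.exp(theta[:nr])
            return theta

        def fun(z):
            return _objective(from_opt(z), spec, data, protocol)
    else:
        opt_bounds = bounds
        to_opt = from_opt = lambda v: np.asarray(v, float)

        def fun(x):
            return _objective(x, spec, data, protocol)

    options = dict(maxiter=500, ftol=1e-14, gtol=1e-10)
    results = []
    for x0 in starts:
        res = optimize.minimize(fun, to_opt(x0), method="L-BFGS-B",
                                bounds=opt_bounds, options=options)
        results.append(res)
    fmin = min(r.fun for r in results)
    best = next(r for r in results
                if r.fun <= fmin * (1 + TIE_TOLERANCE) + 1e-15)
    theta = from_opt(best.x)
    nr = spec.n_rates
    params = dict(zip(spec.rate_names, theta[:nr]))
    off = nr
    if spec.has_delay:
        params["tau"] = float(theta[nr])
        off += 1
    shifts = dict(zip(fluids, theta[off:]))
    return FitResult(
        model=spec.name, params=params, shifts=shifts,
        weighted_sse=float(best.fun), converged=bool(best.success),
        message=str(best.message), n_points=data.n_points, fluids=fluids)


def fit_joint(model, observations, protocol=None, n_boot: int = 0,
              seed=None, transfer_starts=(0.02, 0.05, 0.1, 0.2, 0.5),
              exclude: dict | None = None, **fit_kw) -> FitResult:
    """Joint plasma + CSF fit seeded by per-fluid single-fluid fits.

    Outlier handling follows the processing pipeline: points are flagged by
    the per-fluid single-fluid robust fits (including every t = 0 point)
    and the joint model is fitted on the retained points only — the joint
    models never re-flag data, so competing variants are always compared on
    the same point set. The plasma block (synthesis scale, elimination)
    starts at the plasma single-fluid estimates and the CNS block at the
    CSF ones; the transfer rates sweep a 5-point multi-start grid. When
    ``n_boot > 0`` the bootstrap runs on the retained points.
    """
    spec = get_model(model)
    protocol = protocol or InfusionProtocol()
    plasma = [o for o in observations if o.fluid == "plasma"]
    csf = [o for o in observations if o.fluid == "csf"]
    if not plasma or not csf:
        raise FittingError("joint fitting requires observations in both fluids")
    fp = robust_two_step_fit("single", plasma, protocol=protocol)
    fc = robust_two_step_fit("single", csf, protocol=protocol)
    if exclude is None:
        exclude = {**fp.outlier_flags, **fc.outlier_flags}
    seeded = {"syn_plasma": fp.params["a"], "elim_plasma": fp.params["b"],
              "syn_cns": fc.params["a"], "elim_cns": fc.params["b"],
              "a": fp.params["a"], "b": fp.params["b"]}
    inits = []
    for k in transfer_starts:
        row = [max(seeded.get(name, k), LOG_RATE_FLOOR)
               for name in spec.rate_names]
        if spec.has_delay:
            row.append(1.0)
        row += [fp.shifts["plasma"], fc.shifts["csf"]]
        inits.append(row)
    fit = fit_bounded(spec, observations, protocol=protocol, init=inits,
                      multi_start=False, exclude=exclude, **fit_kw)
    fit.outlier_flags = exclude
    if n_boot:
        fit = bootstrap_ci(spec, observations, n_boot=n_boot, seed=seed,
                           fit=fit, protocol=protocol)
    return fit


def evaluate_objective(model, result_or_theta, observations,
                       protocol: InfusionProtocol | None = None,
                       exclude: dict | None = None) -> float:
    """Weighted SSE of given parameters on (a subset of) the data."""
    spec = get_model(model)
    protocol = protocol or InfusionProtocol()
    data = _assemble(observations, _data_fluids(spec, observations), exclude)
    theta = (result_or_theta.theta if isinstance(result_or_theta, FitResult)
             else np.asarray(result_or_theta, float))
    return _objective(theta, spec, data, protocol)


# ---------------------------------------------------------------------------
# Robust two-step fit and bootstrap
# ---------------------------------------------------------------------------

def flag_outliers(model, result: FitResult, observations,
                  protocol: InfusionProtocol | None = None,
                  dense_step: float = 0.1) -> dict:
    """Half-dynamic-range outlier rule, plus all t = 0 points.

    A point is an outlier when its shift-corrected distance to the fitted
    curve exceeds half the curve's (max - min) over a dense grid. Points at
    t = 0 are always flagged (no tracer incorporated yet).
    """
    spec = get_model(model)
    protocol = protocol or InfusionProtocol()
    t_hi = max(float(np.max(o.times)) for o in observations)
    dense = np.arange(0.0, max(t_hi, T_MAX) + dense_step, dense_step)
    if spec.has_delay:
        base = TwoBCParams(*[result.params[k] for k in spec.rate_names])
        traj = integrate_two_bc_delay(
            DelayParams(base, result.params["tau"]), protocol, dense)
    else:
        traj = integrate(spec, [result.params[k] for k in spec.rate_names],
                         protocol, dense, method="expm")
    flags = {}
    for obs in observations:
        r = traj.r(_model_fluid(spec, obs.fluid))
        half_range = (np.max(r) - np.min(r)) / 2.0
        model_at = np.interp(obs.times, dense, r)
        ria = obs.ria
        dist = np.abs(ria - result.shifts[obs.fluid] - model_at)
        fl = (dist > half_range) | (obs.times == 0.0)
        fl = np.where(np.isnan(ria), False, fl)
        flags[obs.key] = fl.astype(bool)
    return flags


def robust_two_step_fit(model, observations, protocol=None,
                        **fit_kw) -> FitResult:
    """Two-step robust fit: fit, flag outliers, refit without them.

    Returns the step-2 result carrying the outlier flags. Raises when every
    point ends up flagged.
    """
    spec = get_model(model)
    step1 = fit_bounded(spec, observations, protocol=protocol, **fit_kw)
    flags = flag_outliers(spec, step1, observations, protocol=protocol)
    usable = 0
    for obs in observations:
        ok = ~np.isnan(obs.ria)
        usable += int(np.sum(ok & ~flags[obs.key]))
    if usable == 0:
        raise FittingError("every data point was flagged as an outlier")
    fit_kw.setdefault("min_points", 3)
    fit_kw["multi_start"] = False
    fit_kw.pop("init", None)
    step2 = fit_bounded(spec, observations, init=step1.theta,
                        protocol=protocol, exclude=flags, **fit_kw)
    step2.outlier_flags = flags
    return step2


def bootstrap_ci(model, observations, n_boot: int = 1000, seed=None,
                 fit: FitResult | None = None, protocol=None,
                 max_fail_frac: float = 0.2) -> FitResult:
    """Percentile bootstrap CI95 over retained (non-outlier) points.

    Points are resampled with replacement within each fluid; each replicate
    is refit starting from the point estimate. Reproducible under a fixed
    seed. The result is flagged when more than ``max_fail_frac`` of the
    replicate refits fail.
    """
    spec = get_model(model)
    protocol = protocol or InfusionProtocol()
    if fit is None:
        fit = robust_two_step_fit(spec, observations, protocol=protocol)
    rng = np.random.default_rng(seed)
    fluids = fit.fluids or _data_fluids(spec, observations)
    data = _assemble(observations, fluids, fit.outlier_flags or None)

    names = list(spec.rate_names) + (["tau"] if spec.has_delay else []) \
        + [f"shift_{f}" for f in fluids]
    bounds = spec.default_bounds()
    reps, failed = [], 0
    for _ in range(n_boot):
        bdata = _PointData(data.fluids, {}, {}, {}, {}, {})
        for fl in data.fluids:
            n = len(data.t[fl])
            idx = rng.integers(0, n, n)
            bdata.t[fl] = data.t[fl][idx]
            bdata.ria[fl] = data.ria[fl][idx]
            i0w = data.w[fl][idx]
            bdata.w[fl] = i0w / np.mean(i0w)
        res = optimize.minimize(
            _objective, fit.theta, args=(spec, bdata, protocol),
            method="L-BFGS-B", bounds=bounds)
        if res.success:
            reps.append(res.x)
        else:
            failed += 1
    if not reps:
        raise FittingError("all bootstrap refits failed")
    reps = np.array(reps)
    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    fit.ci95 = {name: (float(l), float(h))
                for name, l, h in zip(names, lo, hi)}
    fit.n_boot = n_boot
    fit.boot_flagged = failed > max_fail_frac * n_boot
    return fit


# ---------------------------------------------------------------------------
# Protein-level pooling
# ---------------------------------------------------------------------------

def tukey_outliers(values) -> np.ndarray:
    """Boolean mask of Tukey boxplot outliers (quartile +/- 1.5 IQR)."""
    v = np.asarray(values, float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


@dataclass
class PooledFit:
    """Protein-level pooled fit with the observations that survived."""

    protein_id: str
    fluid: str
    observations: list
    fit: FitResult
    dropped: list            # (obs key, reason)
    per_obs_fits: dict       # obs key -> FitResult (when computed)


def pool_protein(observations, model="single", n_boot: int = 1000,
                 seed=None, protocol=None, clearance_param: str = "b",
                 min_obs_for_outlier_check: int = 3) -> PooledFit:
    """Combine the validated observations of one protein in one fluid.

    Steps: (i) drop shared (non-unique) peptides; (ii) with three or more
    observations, fit each independently and drop those whose clearance-rate
    estimate is a Tukey boxplot outlier; (iii) align the remaining RIA series
    by an additive offset onto the observation with the highest median heavy
    signal; (iv) refit on the pooled data and bootstrap the CI95.
    """
    if not observations:
        raise FittingError("no observations supplied")
    protein = observations[0].protein_id
    fluid = observations[0].fluid
    if any(o.protein_id != protein or o.fluid != fluid for o in observations):
        raise ValueError("pooling expects one protein in one fluid")

    dropped = []
    obs = []
    for o in observations:
        if o.shared:
            dropped.append((o.key, "shared_peptide"))
        else:
            obs.append(o)
    if not obs:
        raise FittingError(
            f"protein {protein}: no unique-peptide observations left")

    per_obs = {}
    if len(obs) >= min_obs_for_outlier_check:
        fits, ok_obs = [], []
        for o in obs:
            try:
                f = robust_two_step_fit(model, [o], protocol=protocol)
                per_obs[o.key] = f
                fits.append(f.params[clearance_param])
                ok_obs.append(o)
            except FittingError:
                dropped.append((o.key, "per_observation_fit_failed"))
        if len(ok_obs) >= min_obs_for_outlier_check:
            bad = tukey_outliers(fits)
            for o, b in zip(ok_obs, bad):
                if b:
                    dropped.append((o.key, "clearance_outlier"))
            obs = [o for o, b in zip(ok_obs, bad) if not b]
        else:
            obs = ok_obs
    if not obs:
        raise FittingError(f"protein {protein}: all observations discarded")

    # alignment on the observation with the highest median heavy signal
    ref = max(obs, key=lambda o: np.nanmedian(o.i6))
    aligned = []
    for o in obs:
        if o is ref:
            aligned.append(replace_offset(o, 0.0))
            continue
        shared_t = np.intersect1d(o.times[~np.isnan(o.ria)],
                                  ref.times[~np.isnan(ref.ria)])
        if len(shared_t) == 0:
            offset = 0.0
        else:
            oi = np.isin(o.times, shared_t) & ~np.isnan(o.ria)
            ri = np.isin(ref.times, shared_t) & ~np.isnan(ref.ria)
            offset = float(np.median(o.ria[oi]) - np.median(ref.ria[ri]))
        aligned.append(replace_offset(o, o.ria_offset + offset))

    fit = robust_two_step_fit(model, aligned, protocol=protocol)
    if n_boot:
        fit = bootstrap_ci(model, aligned, n_boot=n_boot, seed=seed,
                           fit=fit, protocol=protocol)
    return PooledFit(protein_id=protein, fluid=fluid, observations=aligned,
                     fit=fit, dropped=dropped, per_obs_fits=per_obs)


def replace_offset(obs: Observation, offset: float) -> Observation:
    out = Observation(
        protein_id=obs.protein_id, peptide_seq=obs.peptide_seq,
        fraction=obs.fraction, charge=obs.charge, fluid=obs.fluid,
        n_leu=obs.n_leu, times=obs.times.copy(), i0=obs.i0.copy(),
        i6=obs.i6.copy(), shared=obs.shared, ria_offset=offset)
    return out
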