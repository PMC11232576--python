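"""Bayesian estimation of the joint plasma-CSF compartment models.

The likelihood assumes independent normal errors on the observed RIAs with a
per-fluid error precision scaled by the I0-proportional weight of each point
(stronger signals are more precise) and a per-fluid vertical shift applied to
the observations:

    ria_i ~ Normal(r_fluid(t_i) + s_fluid, 1 / (tau_fluid * w_i))

Rates carry normal priors on their logarithms (so they stay positive), the
shifts carry tight zero-centered normal priors (precision 5000), and the
error precisions carry vague Gamma(0.001, 0.001) priors. Prior means for the
rate logs come from the per-fluid single-fluid quasi-Newton fits where a
correspondence exists, and from a configurable empirical constant (0.1/h)
for the CNS-related and transfer rates.

Sampling uses an affine-invariant ensemble MCMC kernel (emcee); two
independent ensembles play the role of the two chains, and convergence is
diagnosed by comparing within- and between-chain variability (split-R̂,
flagged above 1.1). ``n_iter``/``n_burn`` count total posterior evaluations
so the conventional 200,000/100,000 defaults keep their meaning across
kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import emcee

from .fitting import _assemble, _curves_at, _data_fluids
from .models import get_model, IntegrationError
from .protocols import InfusionProtocol

__all__ = ["PriorSpec", "PosteriorResult", "default_priors", "run_mcmc",
           "posterior_curves", "detect_multimodality"]

EMPIRICAL_RATE_CONSTANT = 0.1   # 1/h; prior-mean fallback for hidden rates
RATE_PRECISION = 10.0
SHIFT_PRECISION = 5000.0
GAMMA_SHAPE = 0.001
GAMMA_RATE = 0.001
RHAT_THRESHOLD = 1.1


@dataclass
class PriorSpec:
    """Priors: normal on log-rates, normal shifts, vague gamma precisions."""

    rate_log_means: dict                 # rate name -> mean of log rate
    rate_precisions: dict                # rate name -> precision
    shift_means: dict = field(default_factory=dict)   # fluid -> mean
    shift_precision: float = SHIFT_PRECISION
    gamma_shape: float = GAMMA_SHAPE
    gamma_rate: float = GAMMA_RATE

    def __post_init__(self):
        if self.shift_precision <= 0 or self.gamma_shape <= 0 \
                or self.gamma_rate <= 0:
            raise ValueError("precisions and gamma parameters must be > 0")
        for v in self.rate_precisions.values():
            if v <= 0:
                raise ValueError("rate precisions must be > 0")


def default_priors(single_fluid_fits: dict | None, model,
                   empirical_constant: float = EMPIRICAL_RATE_CONSTANT,
                   rate_precision: float = RATE_PRECISION) -> PriorSpec:
    """Build the default prior from per-fluid single-fluid fits.

    ``single_fluid_fits`` maps fluid name to the FitResult of the
    single-fluid model in that fluid. The plasma synthesis/elimination prior
    means are the logs of the plasma estimates and the CNS ones the logs of
    the CSF estimates (the CSF curve is the observable shadow of the CNS
    compartment); transfer rates and the full-model extras default to
    ``log(empirical_constant)``. Missing fits fall back to the constant.
    """
    spec = get_model(model)
    fits = single_fluid_fits or {}
    log_c = np.log(empirical_constant)

    def from_fit(fluid, param):
        fit = fits.get(fluid)
        if fit is None:
            return log_c
        value = fit.params.get(param, empirical_constant)
        return np.log(max(value, 1e-4))

    mapping = {
        "syn_plasma": from_fit("plasma", "a"),
        "elim_plasma": from_fit("plasma", "b"),
        "syn_cns": from_fit("csf", "a"),
        "elim_cns": from_fit("csf", "b"),
        "a": from_fit("plasma", "a"),
        "b": from_fit("plasma", "b"),
    }
    means = {name: float(mapping.get(name, log_c))
             for name in spec.rate_names}
    precisions = {name: float(rate_precision) for name in spec.rate_names}
    shift_means = {fl: 0.0 for fl in spec.fluids}
    return PriorSpec(rate_log_means=means, rate_precisions=precisions,
                     shift_means=shift_means)


@dataclass
class PosteriorResult:
    """Posterior samples and summaries for one protein and model."""

    model: str
    param_names: list                # sampled dimensions, in order
    samples: np.ndarray              # (chains, draws, ndim), post burn-in
    rhat: dict
    converged: bool
    summary: dict                    # name -> {mean, median, ci_lo, ci_hi,
                                     #          rel_ci95, rhat}
    fluids: tuple
    priors: PriorSpec | None = None
    log_prob: np.ndarray | None = None

    def flat(self, name: str) -> np.ndarray:
        i = self.param_names.index(name)
        return self.samples[..., i].reshape(-1)

    def rate_names(self) -> list:
        spec = get_model(self.model)
        return list(spec.rate_names)


# ---------------------------------------------------------------------------
# Log posterior
# ---------------------------------------------------------------------------

class _LogPosterior:
    """theta = [log rates..., shifts..., log tau per fluid]."""

    def __init__(self, spec, data, priors, protocol, likelihood_on=True):
        self.spec = spec
        self.data = data
        self.priors = priors
        self.protocol = protocol
        self.likelihood_on = likelihood_on
        self.nr = spec.n_rates
        self.fluids = data.fluids
        self.names = ([f"log_{n}" for n in spec.rate_names]
                      + [f"shift_{f}" for f in self.fluids]
                      + [f"log_tau_{f}" for f in self.fluids])
        self.prior_mu = np.array([priors.rate_log_means[n]
                                  for n in spec.rate_names])
        self.prior_sd = np.array([1.0 / np.sqrt(priors.rate_precisions[n])
                                  for n in spec.rate_names])
        self.shift_mu = np.array([priors.shift_means.get(f, 0.0)
                                  for f in self.fluids])
        self.shift_sd = 1.0 / np.sqrt(priors.shift_precision)

    @property
    def ndim(self) -> int:
        return self.nr + 2 * len(self.fluids)

    def split(self, theta):
        nr, nf = self.nr, len(self.fluids)
        return theta[:nr], theta[nr:nr + nf], theta[nr + nf:]

    def log_prior(self, theta) -> float:
        logr, shifts, logtau = self.split(theta)
        if np.any(np.abs(logr) > 25) or np.any(np.abs(logtau) > 40):
            return -np.inf
        lp = -0.5 * np.sum(((logr - self.prior_mu) / self.prior_sd) ** 2)
        lp += -0.5 * np.sum(((shifts - self.shift_mu) / self.shift_sd) ** 2)
        # Gamma(shape, rate) on tau, sampled as log tau (Jacobian: + log tau)
        tau = np.exp(logtau)
        lp += np.sum(self.priors.gamma_shape * logtau
                     - self.priors.gamma_rate * tau)
        return float(lp)

    def log_likelihood(self, theta) -> float:
        logr, shifts, logtau = self.split(theta)
        rates = np.exp(logr)
        try:
            curves = _curves_at(self.spec, rates, 0.0, self.protocol,
                                self.data.t)
        except (IntegrationError, FloatingPointError):
            return -np.inf
        ll = 0.0
        for i, fl in enumerate(self.fluids):
            tau = np.exp(logtau[i])
            res = self.data.ria[fl] - shifts[i] - curves[fl]
            prec = tau * self.data.w[fl]
            ll += 0.5 * float(np.sum(np.log(prec) - prec * res ** 2))
        return ll

    def __call__(self, theta) -> float:
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        if self.likelihood_on:
            lp += self.log_likelihood(theta)
        return lp if np.isfinite(lp) else -np.inf


def _initial_walkers(logpost, nwalkers, rng, shift_inits=None):
    """Walkers drawn from the priors; shifts start at the quasi-Newton
    estimates (when supplied) with a small jitter."""
    nr, nf = logpost.nr, len(logpost.fluids)
    p0 = np.empty((nwalkers, logpost.ndim))
    p0[:, :nr] = rng.normal(logpost.prior_mu, logpost.prior_sd,
                            size=(nwalkers, nr))
    if shift_inits is not None:
        mu = np.asarray(shift_inits, float)
        p0[:, nr:nr + nf] = rng.normal(mu, 1e-3, size=(nwalkers, nf))
    else:
        p0[:, nr:nr + nf] = rng.normal(logpost.shift_mu, logpost.shift_sd,
                                       size=(nwalkers, nf))
    # error precisions start broad around a plausible RIA noise scale
    p0[:, nr + nf:] = rng.normal(np.log(1e4), 1.0, size=(nwalkers, nf))
    return p0


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ over (chains, draws) of one scalar parameter."""
    import arviz as az
    c, n = chains.shape
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]],
                           axis=0)
    return float(az.rhat(split))


def run_mcmc(model, observations, priors: PriorSpec | None = None,
             n_iter: int = 200_000, n_burn: int = 100_000, chains: int = 2,
             seed: int = 0, nwalkers: int | None = None,
             protocol: InfusionProtocol | None = None,
             shift_inits=None, likelihood_on: bool = True,
             exclude: dict | None = None) -> PosteriorResult:
    """Sample the posterior of a joint model with two independent ensembles.

    ``n_iter`` and ``n_burn`` are total posterior evaluations per chain;
    they are divided by the walker count internally. Initial rate values are
    drawn from their priors; shifts start at the supplied quasi-Newton
    estimates when given. Reproducible under a fixed seed. A result whose
    split-R̂ exceeds 1.1 for any parameter is flagged non-converged (samples
    are still returned).
    """
    spec = get_model(model)
    protocol = protocol or InfusionProtocol()
    fluids = _data_fluids(spec, observations)
    data = _assemble(observations, fluids, exclude)
    if priors is None:
        priors = default_priors(None, spec)
    logpost = _LogPosterior(spec, data, priors, protocol, likelihood_on)
    ndim = logpost.ndim
    if nwalkers is None:
        nwalkers = max(2 * ndim + 2, 24)
    steps = max(int(np.ceil(n_iter / nwalkers)), 10)
    burn = min(max(int(np.ceil(n_burn / nwalkers)), 1), steps - 2)

    all_chains = []
    logps = []
    for c in range(chains):
        rs = np.random.RandomState((seed + 7919 * c) % 2 ** 32)
        rng = np.random.default_rng(seed + 7919 * c)
        p0 = _initial_walkers(logpost, nwalkers, rng, shift_inits)
        sampler = emcee.EnsembleSampler(nwalkers, ndim, logpost)
        state = emcee.State(p0, random_state=rs.get_state())
        sampler.run_mcmc(state, steps, progress=False)
        chain = sampler.get_chain(discard=burn)        # (draws, walkers, ndim)
        all_chains.append(chain.transpose(1, 0, 2).reshape(-1, ndim))
        logps.append(sampler.get_log_prob(discard=burn).T.reshape(-1))
    draws = min(len(c) for c in all_chains)
    samples = np.stack([c[:draws] for c in all_chains])   # (chains, draws, ndim)
    log_prob = np.stack([l[:draws] for l in logps])

    rhat, summary = {}, {}
    converged = True
    for i, name in enumerate(logpost.names):
        chains_i = samples[..., i]
        r = _split_rhat(chains_i) if chains > 1 else np.nan
        rhat[name] = r
        if np.isfinite(r) and r > RHAT_THRESHOLD:
            converged = False
        flat = chains_i.reshape(-1)
        native = np.exp(flat) if name.startswith("log_") else flat
        lo, med, hi = np.percentile(native, [2.5, 50, 97.5])
        mean = float(np.mean(native))
        summary[name.replace("log_", "", 1) if name.startswith("log_")
                else name] = {
            "mean": mean, "median": float(med),
            "ci_lo": float(lo), "ci_hi": float(hi),
            "rel_ci95": float((hi - lo) / abs(med)) if med else np.inf,
            "rhat": r,
        }
    return PosteriorResult(model=spec.name, param_names=logpost.names,
                           samples=samples, rhat=rhat, converged=converged,
                           summary=summary, fluids=tuple(fluids),
                           priors=priors, log_prob=log_prob)


# ---------------------------------------------------------------------------
# Posterior curves and multimodality diagnostics
# ---------------------------------------------------------------------------

def posterior_curves(result: PosteriorResult, protocol=None, grid=None,
                     n_draws: int = 500) -> dict:
    """Pointwise credibility bands and the mean-parameter trajectory.

    Integrates the model for ``n_draws`` evenly spaced posterior draws and
    returns 2.5/50/97.5% pointwise bands per compartment, the trajectory at
    the posterior-mean parameters, and the sup-norm distance between the
    mean-parameter curve and the pointwise median curve. A mean-parameter
    curve that leaves the interquartile band anywhere is the signature of a
    multimodal posterior (the mean falls between modes), and raises the
    ``mean_off_median`` flag.
    """
    from .models import integrate

    spec = get_model(result.model)
    protocol = protocol or InfusionProtocol()
    if grid is None:
        grid = np.arange(0.0, 36.2 + 0.1, 0.1)
    grid = np.asarray(grid, float)
    nr = spec.n_rates
    flat = result.samples.reshape(-1, result.samples.shape[-1])
    idx = np.linspace(0, len(flat) - 1, min(n_draws, len(flat))).astype(int)
    state_names = [s for s in spec.state_names]
    curves = {s: [] for s in state_names}
    skipped = 0
    for row in flat[idx]:
        rates = np.exp(row[:nr])
        try:
            traj = integrate(spec, rates, protocol, grid, method="expm")
        except IntegrationError:
            skipped += 1
            continue
        curves["g"].append(traj.g)
        curves["plasma"].append(traj.r_plasma)
        if "cns" in curves:
            curves["cns"].append(traj.r_cns)
        if "csf" in curves:
            curves["csf"].append(traj.r_csf)

    mean_rates = np.exp(result.samples[..., :nr]).reshape(-1, nr).mean(axis=0)
    mean_traj = integrate(spec, mean_rates, protocol, grid, method="expm")
    mean_curves = {"g": mean_traj.g, "plasma": mean_traj.r_plasma,
                   "cns": mean_traj.r_cns, "csf": mean_traj.r_csf}

    out = {"grid": grid, "bands": {}, "mean_curve": {}, "median_curve": {},
           "sup_distance": {}, "mean_off_median": False, "skipped": skipped}
    for s in state_names:
        arr = np.array(curves[s])
        q2, q25, q50, q75, q97 = np.percentile(arr, [2.5, 25, 50, 75, 97.5],
                                               axis=0)
        out["bands"][s] = {"lo": q2, "q25": q25, "median": q50,
                           "q75": q75, "hi": q97}
        mc = mean_curves[s]
        out["mean_curve"][s] = mc
        out["median_curve"][s] = q50
        out["sup_distance"][s] = float(np.max(np.abs(mc - q50)))
        if np.any((mc < q25 - 1e-12) | (mc > q75 + 1e-12)):
            out["mean_off_median"] = True
    return out


def detect_multimodality(result: PosteriorResult, rate_subset,
                         grid_size: int = 60, rel_threshold: float = 0.1,
                         min_samples: int = 200) -> dict:
    """Scan 2-D kernel densities of rate pairs for multiple modes.

    For every pair among ``rate_subset`` a Gaussian KDE is evaluated on a
    grid; grid points that dominate their 8 neighbors and exceed
    ``rel_threshold`` of the global peak count as modes. The result reports
    whether any pair is multimodal and whether the posterior mean falls off
    the modes (density at the mean below half the peak), which is the
    failure signature of redundantly parameterized models.
    """
    from scipy.stats import gaussian_kde

    if len(rate_subset) < 2:
        raise ValueError("need at least two rate names")
    flat = {}
    for name in rate_subset:
        ln = f"log_{name}"
        if ln not in result.param_names:
            raise KeyError(f"{name!r} is not a sampled rate")
        flat[name] = np.exp(result.flat(ln))
    n = len(next(iter(flat.values())))
    if n < min_samples:
        return {"flag": None, "pairs": {}, "indeterminate": True}

    pairs = {}
    any_flag = False
    mean_off = False
    for i, na in enumerate(rate_subset):
        for nb in rate_subset[i + 1:]:
            x, y = flat[na], flat[nb]
            xy = np.vstack([x, y])
            try:
                kde = gaussian_kde(xy)
            except np.linalg.LinAlgError:
                pairs[(na, nb)] = {"n_modes": 0, "degenerate": True}
                continue
            # pad beyond the sample range so extreme modes sit interior
            px = 0.15 * (x.max() - x.min() + 1e-12)
            py = 0.15 * (y.max() - y.min() + 1e-12)
            gx = np.linspace(x.min() - px, x.max() + px, grid_size)
            gy = np.linspace(y.min() - py, y.max() + py, grid_size)
            gxx, gyy = np.meshgrid(gx, gy)
            dens = kde(np.vstack([gxx.ravel(), gyy.ravel()])).reshape(
                grid_size, grid_size)
            peak = dens.max()
            modes = 0
            for r in range(1, grid_size - 1):
                for c in range(1, grid_size - 1):
                    v = dens[r, c]
                    if v < rel_threshold * peak:
                        continue
                    nb8 = dens[r - 1:r + 2, c - 1:c + 2]
                    if v >= nb8.max() and (nb8 < v).sum() >= 7:
                        modes += 1
            mean_pt = np.array([[x.mean()], [y.mean()]])
            mean_dens = float(kde(mean_pt)[0])
            off = mean_dens < 0.5 * peak
            pairs[(na, nb)] = {"n_modes": int(modes),
                               "mean_density_ratio": mean_dens / peak,
                               "mean_off_mode": bool(off)}
            if modes > 1:
                any_flag = True
                if off:
                    mean_off = True
    return {"flag": any_flag, "mean_off_mode": mean_off, "pairs": pairs,
            "indeterminate": False}
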