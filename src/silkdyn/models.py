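"""Compartment models for relative isotope abundance (RIA) dynamics.

All model variants are linear, first-order compartment systems driven by the
normalized tracer input u(t):

``single`` (one fluid, 2 states)
    g' = k_g (u(t) - g)
    r' = a g - b r

g(t) is the availability of the tracer for protein synthesis (a fixed-rate
filter of the delivered input; k_g is a tracer property carried by the
protocol, not a fitted parameter) and r(t) the RIA of the newly synthesized
protein pool. ``a`` acts as a scale parameter for r, while ``b``, the
clearance rate, shapes the curve and sets the protein half-life.

``two_bc`` (plasma + CSF, 3 states) adds linear transfers between the plasma
and CSF RIA values at rates k_plasma_csf and k_csf_plasma (the pharmacokinetic
2-compartment template: central and peripheral compartments, the peripheral
one without elimination):

    g' = k_g (u - g)
    p' = a g - (b + k_pf) p + k_fp f
    f' = k_pf p - (k_fp + e_f) f          (e_f = 0 in the canonical variant)

``two_bc_delay`` replaces the CSF inflow by its delayed value, with zero
history: f'(t) = k_pf p(t - tau) - (k_fp + e_f) f(t), p(t) = 0 for t < tau.

``three_bc_full`` (plasma + hidden CNS + CSF, 4 states, 13 parameters
including the two per-fluid shifts):

    g' = k_g (u - g)
    p' = a g    - (b_p + k_pc + k_pf) p + k_cp c + k_fp f
    c' = a_c g  + k_pc p - (b_c + k_cp + k_cf) c + k_fc f
    f' = k_pf p + k_cf c - (e_f + k_fp + k_fc) f

``three_bc_simplified`` (10 parameters) sets k_cp = k_pc = e_f = 0: exports
from the CNS to plasma are regarded as already integrated in the plasma RIA
data, the plasma -> CSF route via the CNS as negligible, and there is no CSF
in situ degradation. The three removed rates are mutually redundant with the
remaining CSF outflows, which is what makes the full model ill-posed.

Integration uses an implicit stiff Runge-Kutta scheme (Radau) applied
segment-wise between the input breakpoints, or the exact piecewise
matrix-exponential propagator (``method="expm"``) — the two routes agree to
solver tolerance and are cross-checked in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .protocols import InfusionProtocol

__all__ = [
    "SingleFluidParams", "TwoBCParams", "DelayParams", "ThreeBCParams",
    "Trajectory", "CompartmentModelSpec", "MODELS", "IntegrationError",
    "integrate", "integrate_single_fluid", "integrate_two_bc",
    "integrate_two_bc_delay", "integrate_three_bc",
    "DEFAULT_RATE_BOUNDS", "DEFAULT_SHIFT_BOUNDS",
]

DEFAULT_RATE_BOUNDS = (0.0, 10.0)
DEFAULT_SHIFT_BOUNDS = (-0.05, 0.05)
DEFAULT_TAU_BOUNDS = (0.0, 10.0)


class IntegrationError(RuntimeError):
    """Raised when the ODE/DDE solver fails; carries the parameter values."""

    def __init__(self, message: str, rates=None):
        super().__init__(message)
        self.rates = None if rates is None else np.asarray(rates, float)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleFluidParams:
    """Single-fluid model: synthesis scale ``a``, clearance ``b``, shift ``s``."""

    a: float
    b: float
    s: float = 0.0

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("rates a and b must be >= 0")


@dataclass(frozen=True)
class TwoBCParams:
    """2-biological-compartment (plasma + CSF) model parameters."""

    a: float
    b: float
    k_plasma_csf: float
    k_csf_plasma: float
    csf_elimination: float = 0.0
    s_plasma: float = 0.0
    s_csf: float = 0.0

    def __post_init__(self):
        for name in ("a", "b", "k_plasma_csf", "k_csf_plasma", "csf_elimination"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")


@dataclass(frozen=True)
class DelayParams:
    """2-biological-compartment model with delayed plasma -> CSF transfer."""

    base: TwoBCParams
    tau: float

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("delay tau must be >= 0")


@dataclass(frozen=True)
class ThreeBCParams:
    """3-biological-compartment (plasma + hidden CNS + CSF) parameters.

    ``variant="full"`` exposes all 11 rates (13 parameters with the two
    shifts); ``variant="simplified"`` requires k_plasma_cns, k_cns_plasma and
    elim_csf to be zero (10 parameters).
    """

    syn_plasma: float
    syn_cns: float
    elim_plasma: float
    elim_cns: float
    k_plasma_csf: float
    k_csf_plasma: float
    k_cns_csf: float
    k_csf_cns: float
    k_plasma_cns: float = 0.0
    k_cns_plasma: float = 0.0
    elim_csf: float = 0.0
    s_plasma: float = 0.0
    s_csf: float = 0.0
    variant: str = "simplified"

    def __post_init__(self):
        for name in ("syn_plasma", "syn_cns", "elim_plasma", "elim_cns",
                     "k_plasma_csf", "k_csf_plasma", "k_cns_csf", "k_csf_cns",
                     "k_plasma_cns", "k_cns_plasma", "elim_csf"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if self.variant not in ("full", "simplified"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "simplified":
            for name in ("k_plasma_cns", "k_cns_plasma", "elim_csf"):
                if getattr(self, name) != 0.0:
                    raise ValueError(
                        f"{name} must be 0 in the simplified variant")


@dataclass
class Trajectory:
    """Model trajectories on a time grid.

    ``r_cns`` is None for 1- and 2-compartment variants; ``r_csf`` is None
    for the single-fluid model.
    """

    times: np.ndarray
    g: np.ndarray
    r_plasma: np.ndarray
    r_cns: np.ndarray | None = None
    r_csf: np.ndarray | None = None

    def r(self, fluid: str) -> np.ndarray:
        if fluid == "plasma":
            return self.r_plasma
        if fluid == "csf":
            if self.r_csf is None:
                raise KeyError("this model variant has no CSF compartment")
            return self.r_csf
        if fluid == "cns":
            if self.r_cns is None:
                raise KeyError("this model variant has no CNS compartment")
            return self.r_cns
        raise KeyError(f"unknown fluid {fluid!r}")


# ---------------------------------------------------------------------------
# Model specifications (named rate vectors -> system matrices)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentModelSpec:
    """A model variant: named rate roles, state layout and system builder.

    ``build_system(rates, k_g)`` returns ``(A, B)`` such that the state obeys
    x' = A x + B u(t) with the normalized input u and tracer-availability
    rate ``k_g`` taken from the protocol.
    """

    name: str
    rate_names: tuple
    state_names: tuple          # always starts with "g"
    fluids: tuple               # observable fluids
    has_delay: bool = False
    _builder: Callable = field(default=None, repr=False, compare=False)

    @property
    def n_rates(self) -> int:
        return len(self.rate_names)

    @property
    def n_params(self) -> int:
        """Rates + one shift per observable fluid (the paper's count)."""
        return self.n_rates + len(self.fluids) + (1 if self.has_delay else 0)

    def build_system(self, rates, k_g: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        rates = np.asarray(rates, float)
        if rates.shape != (self.n_rates,):
            raise ValueError(
                f"model {self.name!r} expects {self.n_rates} rates, "
                f"got {rates.shape}")
        return self._builder(rates, k_g)

    def rate_dict(self, rates) -> dict:
        return dict(zip(self.rate_names, np.asarray(rates, float)))

    def default_bounds(self) -> list:
        bounds = [DEFAULT_RATE_BOUNDS] * self.n_rates
        if self.has_delay:
            bounds.append(DEFAULT_TAU_BOUNDS)
        bounds += [DEFAULT_SHIFT_BOUNDS] * len(self.fluids)
        return bounds


def _build_single(r, k_g):
    a, b = r
    A = np.array([[-k_g, 0.0],
                  [a, -b]])
    B = np.array([k_g, 0.0])
    return A, B


def _build_two_bc(r, k_g):
    a, b, k_pf, k_fp = r
    return _two_bc_matrices(a, b, k_pf, k_fp, 0.0, k_g)


def _two_bc_matrices(a, b, k_pf, k_fp, e_f, k_g):
    A = np.array([
        [-k_g, 0.0, 0.0],
        [a, -(b + k_pf), k_fp],
        [0.0, k_pf, -(k_fp + e_f)],
    ])
    B = np.array([k_g, 0.0, 0.0])
    return A, B


def _build_three_bc(r, k_g):
    (a_p, a_c, b_p, b_c, k_pf, k_fp, k_cf, k_fc, k_pc, k_cp, e_f) = r
    A = np.array([
        [-k_g, 0.0, 0.0, 0.0],
        [a_p, -(b_p + k_pc + k_pf), k_cp, k_fp],
        [a_c, k_pc, -(b_c + k_cp + k_cf), k_fc],
        [0.0, k_pf, k_cf, -(e_f + k_fp + k_fc)],
    ])
    B = np.array([k_g, 0.0, 0.0, 0.0])
    return A, B


def _build_three_bc_simplified(r, k_g):
    full = np.concatenate([r, [0.0, 0.0, 0.0]])
    return _build_three_bc(full, k_g)


MODELS: dict[str, CompartmentModelSpec] = {
    "single": CompartmentModelSpec(
        name="single",
        rate_names=("a", "b"),
        state_names=("g", "plasma"),
        fluids=("plasma",),
        _builder=_build_single,
    ),
    "two_bc": CompartmentModelSpec(
        name="two_bc",
        rate_names=("a", "b", "k_plasma_csf", "k_csf_plasma"),
        state_names=("g", "plasma", "csf"),
        fluids=("plasma", "csf"),
        _builder=_build_two_bc,
    ),
    "two_bc_delay": CompartmentModelSpec(
        name="two_bc_delay",
        rate_names=("a", "b", "k_plasma_csf", "k_csf_plasma"),
        state_names=("g", "plasma", "csf"),
        fluids=("plasma", "csf"),
        has_delay=True,
        _builder=_build_two_bc,
    ),
    "three_bc_full": CompartmentModelSpec(
        name="three_bc_full",
        rate_names=("syn_plasma", "syn_cns", "elim_plasma", "elim_cns",
                    "k_plasma_csf", "k_csf_plasma", "k_cns_csf", "k_csf_cns",
                    "k_plasma_cns", "k_cns_plasma", "elim_csf"),
        state_names=("g", "plasma", "cns", "csf"),
        fluids=("plasma", "csf"),
        _builder=_build_three_bc,
    ),
    "three_bc_simplified": CompartmentModelSpec(
        name="three_bc_simplified",
        rate_names=("syn_plasma", "syn_cns", "elim_plasma", "elim_cns",
                    "k_plasma_csf", "k_csf_plasma", "k_cns_csf", "k_csf_cns"),
        state_names=("g", "plasma", "cns", "csf"),
        fluids=("plasma", "csf"),
        _builder=_build_three_bc_simplified,
    ),
}


def get_model(spec) -> CompartmentModelSpec:
    if isinstance(spec, CompartmentModelSpec):
        return spec
    try:
        return MODELS[spec]
    except KeyError:
        raise KeyError(
            f"unknown model {spec!r}; available: {sorted(MODELS)}") from None


# ---------------------------------------------------------------------------
# Integration backends
# ---------------------------------------------------------------------------

def _segments(protocol: InfusionProtocol, t_end: float):
    """Input breakpoints and levels covering [0, t_end]."""
    breaks, levels = protocol.levels()
    knots = [0.0]
    lv = []
    for i in range(len(levels)):
        lo, hi = breaks[i], breaks[i + 1]
        if lo >= t_end:
            break
        knots.append(min(hi, t_end))
        lv.append(levels[i])
    if knots[-1] < t_end:
        knots.append(t_end)
        lv.append(0.0)
    return np.asarray(knots), np.asarray(lv)


def _radau_trajectory(A, B, protocol, times, rtol, atol, rates):
    times = np.asarray(times, float)
    n = A.shape[0]
    t_end = times[-1] if times[-1] > 0 else 1e-9
    knots, levels = _segments(protocol, t_end)
    out = np.zeros((len(times), n))
    x0 = np.zeros(n)
    for i in range(len(levels)):
        lo, hi = knots[i], knots[i + 1]
        u = levels[i]

        def rhs(t, x, _u=u):
            return A @ x + B * _u

        inner = times[(times > lo) & (times <= hi)]
        t_eval = np.unique(np.append(inner, hi))
        sol = solve_ivp(rhs, (lo, hi), x0, method="Radau", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"Radau failed on [{lo}, {hi}]: {sol.message}", rates)
        if len(inner):
            out[np.isin(times, inner)] = sol.y.T[np.isin(t_eval, inner)]
        x0 = sol.y[:, -1]
    out[times == 0.0] = 0.0
    return out


def _expm_step(A, Bu, x0, dt):
    """Exact propagation over dt with constant input, via augmented expm."""
    n = A.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A * dt
    M[:n, n] = Bu * dt
    E = expm(M)
    return E[:n, :n] @ x0 + E[:n, n]


def _expm_trajectory(A, B, protocol, times, rates):
    """Exact solution of x' = Ax + Bu(t) with piecewise-constant u.

    Uses an eigendecomposition of A when it is well conditioned, falling
    back to the augmented matrix exponential otherwise. Exact up to floating
    point for these constant-coefficient linear systems.
    """
    times = np.asarray(times, float)
    t_end = float(times[-1]) if times[-1] > 0 else 0.0
    knots, levels = _segments(protocol, max(t_end, 1e-12))
    # merge observation times into the knot sequence
    all_t = np.unique(np.concatenate([knots, times]))
    all_t = all_t[(all_t >= 0) & (all_t <= knots[-1])]
    u_of = np.zeros(len(all_t) - 1)
    for i in range(len(levels)):
        sel = (all_t[:-1] >= knots[i] - 1e-15) & (all_t[:-1] < knots[i + 1] - 1e-15)
        u_of[sel] = levels[i]

    n = A.shape[0]
    x = np.zeros(n)
    states = {0.0: x.copy()}
    for i in range(len(all_t) - 1):
        dt = all_t[i + 1] - all_t[i]
        x = _expm_step(A, B * u_of[i], x, dt)
        states[float(all_t[i + 1])] = x.copy()
    out = np.array([states[float(t)] for t in times])
    return out


def _to_trajectory(spec, times, states) -> Trajectory:
    cols = dict(zip(spec.state_names, states.T))
    return Trajectory(
        times=np.asarray(times, float),
        g=cols["g"],
        r_plasma=cols["plasma"],
        r_cns=cols.get("cns"),
        r_csf=cols.get("csf"),
    )


def integrate(model, rates, protocol: InfusionProtocol, times,
              method: str = "radau", rtol: float = 1e-8,
              atol: float = 1e-10) -> Trajectory:
    """Integrate a (non-delay) model variant on a sorted time grid.

    ``times`` must start at 0. ``method`` is ``"radau"`` (implicit stiff
    Runge-Kutta) or ``"expm"`` (exact piecewise matrix-exponential
    propagation).
    """
    spec = get_model(model)
    if spec.has_delay:
        raise ValueError("use integrate_two_bc_delay for the delay variant")
    times = np.asarray(times, float)
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be sorted and start at 0")
    A, B = spec.build_system(rates, protocol.availability_rate)
    if method == "radau":
        states = _radau_trajectory(A, B, protocol, times, rtol, atol, rates)
    elif method == "expm":
        states = _expm_trajectory(A, B, protocol, times, rates)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _to_trajectory(spec, times, states)


# -- convenience wrappers over parameter dataclasses ------------------------

def integrate_single_fluid(params: SingleFluidParams, protocol, times,
                           **kw) -> Trajectory:
    return integrate("single", [params.a, params.b], protocol, times, **kw)


def integrate_two_bc(params: TwoBCParams, protocol, times, **kw) -> Trajectory:
    if params.csf_elimination:
        A, B = _two_bc_matrices(params.a, params.b, params.k_plasma_csf,
                                params.k_csf_plasma, params.csf_elimination,
                                protocol.availability_rate)
        times = np.asarray(times, float)
        method = kw.pop("method", "radau")
        if method == "radau":
            states = _radau_trajectory(A, B, protocol, times,
                                       kw.pop("rtol", 1e-8),
                                       kw.pop("atol", 1e-10), None)
        else:
            states = _expm_trajectory(A, B, protocol, times, None)
        return _to_trajectory(MODELS["two_bc"], times, states)
    rates = [params.a, params.b, params.k_plasma_csf, params.k_csf_plasma]
    return integrate("two_bc", rates, protocol, times, **kw)


def integrate_three_bc(params: ThreeBCParams, protocol, times,
                       **kw) -> Trajectory:
    if params.variant == "simplified":
        rates = [params.syn_plasma, params.syn_cns, params.elim_plasma,
                 params.elim_cns, params.k_plasma_csf, params.k_csf_plasma,
                 params.k_cns_csf, params.k_csf_cns]
        return integrate("three_bc_simplified", rates, protocol, times, **kw)
    rates = [params.syn_plasma, params.syn_cns, params.elim_plasma,
             params.elim_cns, params.k_plasma_csf, params.k_csf_plasma,
             params.k_cns_csf, params.k_csf_cns, params.k_plasma_cns,
             params.k_cns_plasma, params.elim_csf]
    return integrate("three_bc_full", rates, protocol, times, **kw)


class LinearPropagator:
    """Cached exact propagator for repeated evaluation at fixed times.

    Precomputes the merged knot sequence (input breakpoints + evaluation
    times) once; each ``states(rates)`` call costs one eigendecomposition of
    the small system matrix plus a handful of vector operations per segment.
    Used in fitting and MCMC hot loops; agrees with ``integrate`` to
    floating-point accuracy for these linear models.
    """

    def __init__(self, spec, protocol: InfusionProtocol, times):
        self.spec = spec
        self.k_g = protocol.availability_rate
        times = np.unique(np.asarray(times, float))
        t_end = float(times[-1]) if times[-1] > 0 else 1e-12
        knots, levels = _segments(protocol, t_end)
        all_t = np.unique(np.concatenate([knots, times]))
        all_t = all_t[(all_t >= 0) & (all_t <= knots[-1])]
        u = np.zeros(len(all_t) - 1)
        for i in range(len(levels)):
            sel = (all_t[:-1] >= knots[i] - 1e-15) \
                & (all_t[:-1] < knots[i + 1] - 1e-15)
            u[sel] = levels[i]
        self.all_t = all_t
        self.dts = np.diff(all_t)
        self.us = u
        self.time_index = np.searchsorted(all_t, times)
        self.times = times

    def states(self, rates) -> np.ndarray:
        """State matrix at the requested times (rows align with ``times``)."""
        A, B = self.spec.build_system(rates, self.k_g)
        n = A.shape[0]
        try:
            lam, V = np.linalg.eig(A)
            Vi = np.linalg.inv(V)
            cond = np.linalg.cond(V)
            use_eig = cond <= 1e7
            if use_eig and cond > 1e3:
                # near-defective systems silently lose accuracy in the
                # eigenbasis; validate against one true matrix exponential
                dt0 = float(np.max(self.dts))
                E_eig = (V * np.exp(lam * dt0)) @ Vi
                E_ref = expm(A * dt0)
                scale = 1.0 + np.max(np.abs(E_ref))
                use_eig = np.max(np.abs(E_eig.real - E_ref)) <= 1e-10 * scale
        except np.linalg.LinAlgError:
            use_eig = False
        out = np.zeros((len(self.all_t), n))
        if use_eig:
            # all segment factors at once; only the recurrence is sequential
            z = lam[None, :] * self.dts[:, None]
            E = np.exp(z)
            small = np.abs(z) < 1e-8
            phi = np.where(small, 1.0 + z / 2.0,
                           np.expm1(z) / np.where(small, 1.0, z))
            forc = phi * (self.dts * self.us)[:, None] * (Vi @ B)[None, :]
            y = np.zeros(n, dtype=complex)
            ys = np.empty((len(self.dts), n), dtype=complex)
            for i in range(len(self.dts)):
                y = E[i] * y + forc[i]
                ys[i] = y
            out[1:] = (ys @ V.T).real
        else:
            xr = np.zeros(n)
            for i, (dt, u) in enumerate(zip(self.dts, self.us)):
                xr = _expm_step(A, B * u, xr, dt)
                out[i + 1] = xr
        return out[self.time_index]


def single_fluid_curve(a: float, b: float, protocol: InfusionProtocol,
                       times) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (g, r) of the single-fluid model on an arbitrary grid.

    Exact segment-wise solution for the piecewise-constant input; much
    faster than the generic propagators and used in fitting hot loops.
    """
    times = np.asarray(times, float)
    t_end = float(np.max(times)) if len(times) else 0.0
    knots, levels = _segments(protocol, max(t_end, 1e-12))
    kg = protocol.availability_rate
    g0, r0 = 0.0, 0.0
    g_out = np.zeros_like(times)
    r_out = np.zeros_like(times)

    def step(g0, r0, u, dt):
        ek = np.exp(-kg * dt)
        eb = np.exp(-b * dt)
        g1 = u + (g0 - u) * ek
        # particular + homogeneous terms of r' = a g - b r
        if b > 1e-12:
            term_u = (a * u / b) * (1.0 - eb)
        else:
            term_u = a * u * dt
        if abs(b - kg) > 1e-9:
            d = (ek - eb) / (b - kg)
        else:
            d = dt * ek
        r1 = r0 * eb + term_u + a * (g0 - u) * d
        return g1, r1

    for i in range(len(knots) - 1):
        lo, hi = knots[i], knots[i + 1]
        u = levels[i]
        sel = (times > lo) & (times <= hi)
        if np.any(sel):
            for j in np.nonzero(sel)[0]:
                g_out[j], r_out[j] = step(g0, r0, u, times[j] - lo)
        g0, r0 = step(g0, r0, u, hi - lo)
    # anything beyond the last knot decays with zero input
    sel = times > knots[-1]
    for j in np.nonzero(sel)[0]:
        g_out[j], r_out[j] = step(g0, r0, 0.0, times[j] - knots[-1])
    return g_out, r_out


# ---------------------------------------------------------------------------
# Delay variant (method of steps)
# ---------------------------------------------------------------------------

def integrate_two_bc_delay(params: DelayParams, protocol: InfusionProtocol,
                           times, rtol: float = 1e-8, atol: float = 1e-10,
                           tau_floor: float = 1e-3) -> Trajectory:
    """Integrate the delayed 2-biological-compartment model.

    The CSF inflow term uses the plasma RIA delayed by ``tau`` with zero
    history (p(t) = 0 for t < tau). Solved by the method of steps: on each
    window [k tau, (k+1) tau] the delayed plasma value is known from the
    dense solution of previous windows, reducing the DDE to an ODE chain.
    Delays below ``tau_floor`` are treated as zero.
    """
    base, tau = params.base, params.tau
    times = np.asarray(times, float)
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be sorted and start at 0")
    if tau <= tau_floor:
        return integrate_two_bc(base, protocol, times, rtol=rtol, atol=atol)

    a, b, k_pf, k_fp = base.a, base.b, base.k_plasma_csf, base.k_csf_plasma
    e_f = base.csf_elimination
    kg = protocol.availability_rate
    t_end = float(times[-1])

    # input evaluation
    breaks, levels = protocol.levels()

    def u_at(t):
        if t >= breaks[-1]:
            return 0.0
        i = int(np.searchsorted(breaks, t, side="right") - 1)
        return float(levels[max(i, 0)])

    dense_segments = []  # (lo, hi, OdeSolution)

    def plasma_history(t):
        if t < 0:
            return 0.0
        for lo, hi, sol in dense_segments:
            if lo - 1e-12 <= t <= hi + 1e-12:
                return float(sol(np.clip(t, lo, hi))[1])
        raise IntegrationError(f"history lookup failed at t={t}")

    def rhs(t, x):
        g, p, f = x
        u = u_at(t)
        pd = plasma_history(t - tau)
        return [kg * (u - g),
                a * g - (b + k_pf) * p + k_fp * f,
                k_pf * pd - (k_fp + e_f) * f]

    # window boundaries: multiples of tau, plus the input breakpoints to keep
    # the RHS smooth inside each solver call
    bounds = set(np.arange(0.0, t_end, tau))
    bounds.update(b for b in breaks if 0 < b < t_end)
    bounds.update({0.0, t_end})
    bounds = np.array(sorted(bounds))
    if len(bounds) > 20000:
        raise IntegrationError("delay too small relative to the horizon")

    x0 = np.zeros(3)
    out = np.zeros((len(times), 3))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sol = solve_ivp(rhs, (lo, hi), x0, method="Radau", dense_output=True,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"DDE integration failed on [{lo}, {hi}]: {sol.message}")
        dense_segments.append((lo, hi, sol.sol))
        sel = (times > lo) & (times <= hi)
        if np.any(sel):
            out[sel] = sol.sol(times[sel]).T
        x0 = sol.y[:, -1]
    out[times == 0.0] = 0.0
    return _to_trajectory(MODELS["two_bc_delay"], times, out)
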