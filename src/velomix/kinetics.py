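"""Closed-form splicing kinetics.

The transcription/splicing/degradation system per gene is

    du/dt = alpha(t) - beta * u
    ds/dt = beta * u - gamma * s

with transcription either constant within a phase (``alpha`` during induction,
0 during repression) or time-dependent,
``alpha(t) = alpha1 - (alpha1 - alpha0) * exp(-lambda_alpha * t)`` during
induction and 0 during repression.  Four transcriptional states are modeled:
induction (1), induction steady state (2), repression (3) and repression
steady state (4).  Repression starts at the per-gene switch time ``t_switch``
from the induction steady state ``(alpha/beta, alpha/gamma)`` (constant-rate
model) or from the finite-time induction solution at the switch
(time-dependent model, where the steady state depends on the rate history).

All solvers accept numpy arrays or autodiff ``Tensor`` objects so the same
closed forms drive both the simulator and the variational model's likelihood.
Degenerate denominators (gamma ~ beta, lambda_alpha hitting beta or gamma) are
replaced by their analytic limits inside a 1e-8 window rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._ad import Tensor

__all__ = [
    "KineticParams",
    "StateSolution",
    "INDUCTION",
    "INDUCTION_SS",
    "REPRESSION",
    "REPRESSION_SS",
    "solve_induction",
    "solve_repression",
    "solve_state",
    "solve_time_dependent",
    "alpha_of_t",
    "velocity",
]

INDUCTION, INDUCTION_SS, REPRESSION, REPRESSION_SS = 1, 2, 3, 4

_DEGENERATE_TOL = 1e-8


# ---------------------------------------------------------------------------
# numpy/Tensor dispatch helpers
# ---------------------------------------------------------------------------

def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def _value(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _where(cond, a, b):
    if _is_tensor(a, b):
        a = a if isinstance(a, Tensor) else Tensor(a)
        b = b if isinstance(b, Tensor) else Tensor(b)
        return a.where(cond, b)
    return np.where(cond, a, b)


def _ediff(a, b, tau):
    """(exp(-b*tau) - exp(-a*tau)) / (a - b), symmetric in (a, b).

    Limit a -> b is tau * exp(-a*tau) (L'Hopital), substituted when
    |a - b| < 1e-8 so the expression stays finite and smooth near the
    gamma = beta (or rate = decay-constant) degeneracy.
    """
    den = a - b
    mask = np.abs(_value(den)) >= _DEGENERATE_TOL
    den_safe = _where(mask, den, np.ones_like(_value(den)))
    regular = (_exp(-1.0 * b * tau) - _exp(-1.0 * a * tau)) / den_safe
    # midpoint form keeps the partial derivatives wrt a and b symmetric (each
    # half the diagonal derivative), matching the true gradient at a == b
    limit = tau * _exp(-0.5 * (a + b) * tau)
    return _where(mask, regular, limit)


def _ediff_dlam(gamma, lam, tau):
    """d/dlam of _ediff(gamma, lam, tau), used for the lambda -> beta limit."""
    den = gamma - lam
    mask = np.abs(_value(den)) >= _DEGENERATE_TOL
    den_safe = _where(mask, den, np.ones_like(_value(den)))
    e_l = _exp(-1.0 * lam * tau)
    e_g = _exp(-1.0 * gamma * tau)
    regular = (-1.0 * tau * e_l * den_safe + (e_l - e_g)) / (den_safe * den_safe)
    # second-order limit gamma -> lam, midpoint exponent as in _ediff
    limit = -0.5 * tau * tau * _exp(-0.5 * (gamma + lam) * tau)
    return _where(mask, regular, limit)


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass
class KineticParams:
    """Per-gene kinetic rates and switch times.

    ``alpha`` is the induction-phase transcription rate (for the
    time-dependent variant it is the asymptotic rate ``alpha1``; ``alpha0``
    and ``lambda_alpha`` shape the approach).  ``sigma_u``/``sigma_s`` are the
    likelihood scales of the observation model.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    t_switch: np.ndarray
    sigma_u: np.ndarray | None = None
    sigma_s: np.ndarray | None = None
    variant: Literal["constant", "time_dependent"] = "constant"
    alpha0: np.ndarray | None = None
    alpha1: np.ndarray | None = None
    lambda_alpha: np.ndarray | None = None
    t_max: float = 20.0

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "t_switch"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, arr)
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(self.t_switch >= self.t_max):
            raise ValueError("t_switch must be < t_max")
        if self.variant == "time_dependent":
            for name in ("alpha0", "alpha1", "lambda_alpha"):
                if getattr(self, name) is None:
                    raise ValueError(f"time_dependent variant requires {name}")
                arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
                if np.any(arr <= 0):
                    raise ValueError(f"{name} must be strictly positive")
                setattr(self, name, arr)

    @property
    def n_genes(self) -> int:
        return self.alpha.shape[0]

    def steady_state_u(self) -> np.ndarray:
        """Induction steady-state unspliced abundance alpha/beta."""
        a = self.alpha1 if self.variant == "time_dependent" else self.alpha
        return a / self.beta

    def steady_state_s(self) -> np.ndarray:
        a = self.alpha1 if self.variant == "time_dependent" else self.alpha
        return a / self.gamma

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "t_switch": self.t_switch,
        }
        for name in ("sigma_u", "sigma_s", "alpha0", "alpha1", "lambda_alpha"):
            if getattr(self, name) is not None:
                cols[name] = getattr(self, name)
        df = pd.DataFrame(cols)
        df.attrs["variant"] = self.variant
        return df

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "variant", self.variant)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "KineticParams":
        df = pd.read_csv(path, sep="\t")
        variant = str(df["variant"].iloc[0]) if "variant" in df else "constant"
        kw = {c: df[c].to_numpy() for c in df.columns if c != "variant"}
        return cls(variant=variant, **kw)


@dataclass
class StateSolution:
    """Mean unspliced/spliced abundance at a given time and state."""

    u_mean: np.ndarray
    s_mean: np.ndarray
    state: int | np.ndarray = INDUCTION

    def __iter__(self):
        yield self.u_mean
        yield self.s_mean


# ---------------------------------------------------------------------------
# constant transcription rate: raw solvers on plain values
# ---------------------------------------------------------------------------

def induction_uv(alpha, beta, gamma, t):
    """Induction-phase (u, s) from initial condition (0, 0) at t=0."""
    ebt = _exp(-1.0 * beta * t)
    u = alpha / beta * (1.0 - ebt)
    # alpha/(gamma-beta) * (e^{-gt} - e^{-bt}) = -alpha * _ediff(gamma, beta, t)
    s = alpha / gamma * (1.0 - _exp(-1.0 * gamma * t)) - alpha * _ediff(gamma, beta, t)
    return u, s


def repression_uv(beta, gamma, u0, s0, tau):
    """Repression-phase (u, s) a lag ``tau`` after the switch, from (u0, s0)."""
    u = u0 * _exp(-1.0 * beta * tau)
    # -beta*u0/(gamma-beta) * (e^{-g tau} - e^{-b tau}) = beta*u0*_ediff(gamma, beta, tau)
    s = s0 * _exp(-1.0 * gamma * tau) + beta * u0 * _ediff(gamma, beta, tau)
    return u, s


def solve_induction(p: KineticParams, t) -> StateSolution:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("induction time must be >= 0")
    u, s = induction_uv(p.alpha, p.beta, p.gamma, t)
    # cancellation in the closed form can undershoot zero by ~1 ulp
    return StateSolution(np.maximum(u, 0.0), np.maximum(s, 0.0), INDUCTION)


def solve_repression(p: KineticParams, t, init: str = "steady_state") -> StateSolution:
    """Repression-phase solution from the switch time onward.

    ``init`` picks the convention for the state at the switch: the printed
    equations define it as the induction steady state (alpha/beta,
    alpha/gamma); ``init="finite"`` instead continues from the finite-time
    induction value at t_switch.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < p.t_switch):
        raise ValueError("repression time must be >= t_switch")
    tau = t - p.t_switch
    if init == "finite":
        u0, s0 = induction_uv(p.alpha, p.beta, p.gamma, p.t_switch)
    else:
        u0 = p.alpha / p.beta
        s0 = p.alpha / p.gamma
    u, s = repression_uv(p.beta, p.gamma, u0, s0, tau)
    return StateSolution(np.maximum(u, 0.0), np.maximum(s, 0.0), REPRESSION)


def solve_state(p: KineticParams, t, state: int) -> StateSolution:
    """Dispatch over the four transcriptional states."""
    if p.variant == "time_dependent":
        return solve_time_dependent(p, t, state)
    if state == INDUCTION:
        return solve_induction(p, t)
    if state == REPRESSION:
        return solve_repression(p, t)
    t = np.asarray(t, dtype=float)
    shape = np.broadcast_shapes(t.shape, p.alpha.shape)
    if state == INDUCTION_SS:
        u = np.broadcast_to(p.alpha / p.beta, shape).copy()
        s = np.broadcast_to(p.alpha / p.gamma, shape).copy()
        return StateSolution(u, s, INDUCTION_SS)
    if state == REPRESSION_SS:
        zero = np.zeros(shape)
        return StateSolution(zero, zero.copy(), REPRESSION_SS)
    raise ValueError(f"unknown transcriptional state: {state}")


def velocity(p: KineticParams, u_mean, s_mean):
    """RNA velocity ds/dt = beta * u - gamma * s at given mean abundances."""
    return p.beta * np.asarray(u_mean) - p.gamma * np.asarray(s_mean)


# ---------------------------------------------------------------------------
# time-dependent transcription rate
# ---------------------------------------------------------------------------

def alpha_of_t(p: KineticParams, t, state: int):
    """Transcription rate alpha(t): saturating exponential during induction
    (and its steady state), zero during repression phases."""
    if p.variant != "time_dependent":
        raise ValueError("alpha_of_t requires the time_dependent variant")
    t = np.asarray(t, dtype=float)
    if state in (INDUCTION, INDUCTION_SS):
        return p.alpha1 - (p.alpha1 - p.alpha0) * np.exp(-p.lambda_alpha * t)
    if state in (REPRESSION, REPRESSION_SS):
        return np.zeros(np.broadcast_shapes(t.shape, p.alpha1.shape))
    raise ValueError(f"unknown transcriptional state: {state}")


def induction_uv_td(alpha0, alpha1, lam, beta, gamma, t):
    """Time-dependent-rate induction (u, s) from (0, 0) at t=0.

    u(t) = (a1/b)(1-e^{-bt}) - (a1-a0) * (e^{-lt}-e^{-bt})/(b-l)
    s(t) adds the gamma-propagated counterparts; all of (b-l), (g-l), (g-b)
    are limit-handled, including the coincident lambda = beta = gamma case.
    """
    da = alpha1 - alpha0
    ebt = _exp(-1.0 * beta * t)
    egt = _exp(-1.0 * gamma * t)
    u = alpha1 / beta * (1.0 - ebt) - da * _ediff(beta, lam, t)
    s = alpha1 / gamma * (1.0 - egt) - alpha1 * _ediff(gamma, beta, t)
    # last two terms of the spliced solution share the 1/(beta-lam) pole;
    # combined they tend to d/dlam[-_ediff(gamma, lam, t)] as lam -> beta
    den = beta - lam
    mask = np.abs(_value(den)) >= _DEGENERATE_TOL
    den_safe = _where(mask, den, np.ones_like(_value(den)))
    combined = (_ediff(gamma, beta, t) - _ediff(gamma, lam, t)) / den_safe
    limit = _ediff_dlam(gamma, 0.5 * (beta + lam), t)
    s = s + beta * da * _where(mask, combined, limit)
    return u, s


def solve_time_dependent(
    p: KineticParams, t, state: int, init: str = "steady_state"
) -> StateSolution:
    """Closed forms under the time-dependent transcription rate.

    Repression initial conditions follow the same steady-state convention as
    the constant-rate model ((alpha1/beta, alpha1/gamma)), which makes the
    alpha0 = alpha1 case reduce exactly to the constant-rate solution;
    ``init="finite"`` starts from the time-dependent induction value at the
    switch instead.
    """
    if p.variant != "time_dependent":
        raise ValueError("solve_time_dependent requires the time_dependent variant")
    t = np.asarray(t, dtype=float)
    shape = np.broadcast_shapes(t.shape, p.alpha1.shape)
    if state == INDUCTION:
        if np.any(t < 0):
            raise ValueError("induction time must be >= 0")
        u, s = induction_uv_td(p.alpha0, p.alpha1, p.lambda_alpha, p.beta, p.gamma, t)
        return StateSolution(np.maximum(u, 0.0), np.maximum(s, 0.0), INDUCTION)
    if state == INDUCTION_SS:
        u = np.broadcast_to(p.alpha1 / p.beta, shape).copy()
        s = np.broadcast_to(p.alpha1 / p.gamma, shape).copy()
        return StateSolution(u, s, INDUCTION_SS)
    if state == REPRESSION:
        if np.any(t < p.t_switch):
            raise ValueError("repression time must be >= t_switch")
        # transcription shuts off at the switch; dynamics decay from the
        # induction steady state (or the finite-time induction value)
        if init == "finite":
            u0, s0 = induction_uv_td(
                p.alpha0, p.alpha1, p.lambda_alpha, p.beta, p.gamma, p.t_switch
            )
        else:
            u0 = p.alpha1 / p.beta
            s0 = p.alpha1 / p.gamma
        u, s = repression_uv(p.beta, p.gamma, u0, s0, t - p.t_switch)
        return StateSolution(np.maximum(u, 0.0), np.maximum(s, 0.0), REPRESSION)
    if state == REPRESSION_SS:
        zero = np.zeros(shape)
        return StateSolution(zero, zero.copy(), REPRESSION_SS)
    raise ValueError(f"unknown transcriptional state: {state}")
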