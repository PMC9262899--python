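"""Hill-type musculotendon model with a compliant tendon.

A musculotendon unit (MTU) is a contractile fiber in series with an elastic
tendon. At each timestep the fiber length is found by solving the static
equilibrium between tendon force and the along-tendon component of fiber
force,

    -F_o^m f^T(l^t) + F_o^m (a f^l(l^m) + f^PE(l^m)) cos(alpha(l^m)) = 0,

after which MTU force is affine in activation,

    F^MTU = F_o^m (a f^l + f^PE) cos(alpha) = c0 + c1 a.

The force-velocity property is deliberately omitted: with a compliant
tendon the plantarflexor fibers shorten slowly during stance, and the
static equilibrium alone reproduces their force profiles well.

Characteristic curves are smooth analytic surrogates of the standard
dimensionless muscle curves: an exponential tendon curve above slack
length, a Gaussian-sum active force-length curve with its maximum at the
optimal fiber length, and an exponential passive curve engaging above the
optimal length. All are C1 everywhere, which keeps Newton iterations
well-behaved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

#: Pennation is capped to avoid the fixed-height singularity as fibers shorten.
MAX_PENNATION_RAD = np.deg2rad(84.0)

#: Relative equilibrium tolerance: |residual| < RESIDUAL_RTOL * F_o^m.
RESIDUAL_RTOL = 1e-8

_NEWTON_MAX_ITER = 50
_BRACKET = (0.3, 1.8)  # bisection fallback bracket, units of l_o_m


class EquilibriumError(RuntimeError):
    """Raised when no fiber length satisfies tendon-fiber equilibrium."""


@dataclass(frozen=True)
class MusculotendonParams:
    """Constant parameters of one musculotendon actuator.

    Parameters
    ----------
    name : str
        Muscle name.
    f_o_m : float
        Maximum isometric fiber force, N.
    l_o_m : float
        Optimal fiber length, m.
    l_s_t : float
        Tendon slack length, m.
    alpha_o : float
        Pennation angle at the optimal fiber length, rad.
    """

    name: str
    f_o_m: float
    l_o_m: float
    l_s_t: float
    alpha_o: float = 0.0

    def __post_init__(self) -> None:
        if self.f_o_m <= 0:
            raise ValueError(f"{self.name}: f_o_m must be positive")
        if self.l_o_m <= 0:
            raise ValueError(f"{self.name}: l_o_m must be positive")
        if self.l_s_t < 0:
            raise ValueError(f"{self.name}: l_s_t must be nonnegative")
        if not 0 <= self.alpha_o < np.pi / 2:
            raise ValueError(f"{self.name}: alpha_o must be in [0, pi/2)")


@dataclass(frozen=True)
class CurveSet:
    """Dimensionless characteristic curves of the Hill model.

    Tendon: ``f_t(x) = kt1 (exp(kt2 (x-1)) - 1 - kt2 (x-1))`` for x > 1,
    zero below; ``kt1`` is set so the tendon carries one maximal isometric
    force at strain ``tendon_strain_at_fom``.

    Active fiber: a two-term Gaussian sum centred at the optimal length,
    ``f_l(x) = w exp(-(x-1)^2/g1) + (1-w) exp(-(x-1)^2/g2)``.

    Passive fiber: ``f_pe(x) = kp1 (exp(kp2 (x-1)) - 1 - kp2 (x-1))`` for
    x > 1, zero below, reaching 1 at strain ``passive_strain_at_fom``.
    """

    tendon_strain_at_fom: float = 0.049
    kt2: float = 30.0
    active_w: float = 0.8
    active_g1: float = 0.15
    active_g2: float = 0.8
    passive_strain_at_fom: float = 0.6
    kp2: float = 5.0
    kt1: float = field(init=False)
    kp1: float = field(init=False)

    def __post_init__(self) -> None:
        e = self.tendon_strain_at_fom
        object.__setattr__(
            self, "kt1", 1.0 / (np.exp(self.kt2 * e) - 1.0 - self.kt2 * e)
        )
        e = self.passive_strain_at_fom
        object.__setattr__(
            self, "kp1", 1.0 / (np.exp(self.kp2 * e) - 1.0 - self.kp2 * e)
        )

    # -- curve evaluations (scalar or ndarray) ------------------------------

    def tendon_fl(self, l_t_norm):
        """Tendon force multiplier f^T at normalized tendon length l_t/l_s_t."""
        x = np.asarray(l_t_norm, dtype=float)
        eps = np.maximum(x - 1.0, 0.0)
        return self.kt1 * (np.exp(self.kt2 * eps) - 1.0 - self.kt2 * eps)

    def tendon_fl_deriv(self, l_t_norm):
        x = np.asarray(l_t_norm, dtype=float)
        eps = np.maximum(x - 1.0, 0.0)
        return self.kt1 * self.kt2 * (np.exp(self.kt2 * eps) - 1.0)

    def active_fl(self, l_m_norm):
        """Active force-length multiplier f^l at normalized fiber length."""
        x = np.asarray(l_m_norm, dtype=float)
        d2 = (x - 1.0) ** 2
        return self.active_w * np.exp(-d2 / self.active_g1) + (
            1.0 - self.active_w
        ) * np.exp(-d2 / self.active_g2)

    def active_fl_deriv(self, l_m_norm):
        x = np.asarray(l_m_norm, dtype=float)
        d = x - 1.0
        return self.active_w * np.exp(-d**2 / self.active_g1) * (
            -2.0 * d / self.active_g1
        ) + (1.0 - self.active_w) * np.exp(-d**2 / self.active_g2) * (
            -2.0 * d / self.active_g2
        )

    def passive_fl(self, l_m_norm):
        """Passive force-length multiplier f^PE at normalized fiber length."""
        x = np.asarray(l_m_norm, dtype=float)
        eps = np.maximum(x - 1.0, 0.0)
        return self.kp1 * (np.exp(self.kp2 * eps) - 1.0 - self.kp2 * eps)

    def passive_fl_deriv(self, l_m_norm):
        x = np.asarray(l_m_norm, dtype=float)
        eps = np.maximum(x - 1.0, 0.0)
        return self.kp1 * self.kp2 * (np.exp(self.kp2 * eps) - 1.0)


DEFAULT_CURVES = CurveSet()


@dataclass(frozen=True)
class FiberState:
    """Solved fiber configuration at one timestep."""

    l_m: float  # fiber length, m
    l_t: float  # tendon length, m
    alpha: float  # pennation, rad
    equilibrium_residual: float  # N


def pennation(params: MusculotendonParams, l_m: float) -> float:
    """Pennation from the fixed-height assumption l_m sin(alpha) = const."""
    h = params.l_o_m * np.sin(params.alpha_o)
    if h == 0.0:
        return 0.0
    s = min(h / l_m, np.sin(MAX_PENNATION_RAD))
    return float(np.arcsin(s))


def eval_curves(curves: CurveSet, l_m_norm, l_t_norm):
    """Evaluate (f_l, f_pe, f_t) at normalized fiber and tendon lengths."""
    if np.any(np.asarray(l_m_norm) <= 0) or np.any(np.asarray(l_t_norm) <= 0):
        raise ValueError("normalized lengths must be positive")
    return (
        curves.active_fl(l_m_norm),
        curves.passive_fl(l_m_norm),
        curves.tendon_fl(l_t_norm),
    )


def _residual(params, curves, a, l_mtu, l_m):
    """Equilibrium residual in units of F_o^m (dimensionless)."""
    alpha = pennation(params, l_m)
    l_t = l_mtu - l_m * np.cos(alpha)
    f_t = curves.tendon_fl(l_t / params.l_s_t) if params.l_s_t > 0 else 0.0
    x = l_m / params.l_o_m
    return float(
        -f_t + (a * curves.active_fl(x) + curves.passive_fl(x)) * np.cos(alpha)
    )


def rigid_tendon_fiber(params: MusculotendonParams, l_mtu: float) -> FiberState:
    """Fiber state assuming an inextensible tendon at its slack length."""
    if l_mtu <= params.l_s_t:
        raise ValueError(
            f"{params.name}: MTU length {l_mtu:.4f} m does not exceed tendon "
            f"slack length {params.l_s_t:.4f} m"
        )
    proj = l_mtu - params.l_s_t  # l_m cos(alpha)
    h = params.l_o_m * np.sin(params.alpha_o)
    l_m = float(np.hypot(proj, h))
    return FiberState(
        l_m=l_m, l_t=params.l_s_t, alpha=pennation(params, l_m),
        equilibrium_residual=0.0,
    )


def solve_fiber_equilibrium(
    params: MusculotendonParams,
    curves: CurveSet,
    a_prev: float,
    l_mtu: float,
    l_m_init: float | None = None,
) -> FiberState:
    """Solve the tendon-fiber static equilibrium for the fiber length.

    Uses the activation of the previous timestep and the MTU length of the
    current one. Newton's method from ``l_m_init`` (or a rigid-tendon
    estimate), with a bracketed bisection fallback.

    Raises
    ------
    EquilibriumError
        If no equilibrium exists in the physiological fiber-length bracket.
    """
    if not 0.0 <= a_prev <= 1.0:
        raise ValueError("a_prev must be in [0, 1]")
    if l_mtu <= params.l_s_t * (1.0 - 1e-9):
        raise ValueError(
            f"{params.name}: MTU length below tendon slack length"
        )
    if params.l_s_t == 0.0:
        fs = rigid_tendon_fiber(params, l_mtu + 1e-12)
        return fs

    rigid = rigid_tendon_fiber(params, max(l_mtu, params.l_s_t * (1 + 1e-12)))
    # Degenerate slack configuration: with zero activation, a fiber at or
    # below optimal length with a tendon at or below slack length carries no
    # force anywhere; take the rigid-tendon geometry as the canonical state.
    if a_prev == 0.0 and rigid.l_m <= params.l_o_m * (1.0 + 1e-12):
        r = _residual(params, curves, a_prev, l_mtu, rigid.l_m)
        if abs(r) < RESIDUAL_RTOL:
            return FiberState(
                l_m=rigid.l_m,
                l_t=l_mtu - rigid.l_m * np.cos(rigid.alpha),
                alpha=rigid.alpha,
                equilibrium_residual=r * params.f_o_m,
            )

    l_m = l_m_init if l_m_init and l_m_init > 0 else rigid.l_m
    lo = _BRACKET[0] * params.l_o_m
    hi = _BRACKET[1] * params.l_o_m
    l_m = min(max(l_m, lo), hi)

    for _ in range(_NEWTON_MAX_ITER):
        r = _residual(params, curves, a_prev, l_mtu, l_m)
        if abs(r) < RESIDUAL_RTOL:
            alpha = pennation(params, l_m)
            return FiberState(
                l_m=float(l_m),
                l_t=float(l_mtu - l_m * np.cos(alpha)),
                alpha=alpha,
                equilibrium_residual=r * params.f_o_m,
            )
        h = 1e-7 * params.l_o_m
        dr = (
            _residual(params, curves, a_prev, l_mtu, l_m + h)
            - _residual(params, curves, a_prev, l_mtu, l_m - h)
        ) / (2 * h)
        if dr == 0.0 or not np.isfinite(dr):
            break
        step = r / dr
        l_m = min(max(l_m - step, lo), hi)

    # Bisection fallback on the physiological bracket.
    f_lo = _residual(params, curves, a_prev, l_mtu, lo)
    f_hi = _residual(params, curves, a_prev, l_mtu, hi)
    if f_lo * f_hi > 0:
        raise EquilibriumError(
            f"{params.name}: no equilibrium bracket for l_mtu={l_mtu:.4f} m, "
            f"a_prev={a_prev:.3f}"
        )
    l_m = brentq(
        lambda x: _residual(params, curves, a_prev, l_mtu, x),
        lo,
        hi,
        xtol=1e-12,
    )
    alpha = pennation(params, l_m)
    r = _residual(params, curves, a_prev, l_mtu, l_m)
    return FiberState(
        l_m=float(l_m),
        l_t=float(l_mtu - l_m * np.cos(alpha)),
        alpha=alpha,
        equilibrium_residual=r * params.f_o_m,
    )


def mtu_force(
    params: MusculotendonParams,
    curves: CurveSet,
    a: float,
    fiber: FiberState,
) -> tuple[float, float, float]:
    """MTU force at a solved fiber state: ``force = c0 + c1 * a``.

    Returns ``(force, c0, c1)`` with ``c0 = F_o^m f^PE cos(alpha)`` (passive)
    and ``c1 = F_o^m f^l cos(alpha)`` (active gain), both in newtons.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation must be in [0, 1]")
    x = fiber.l_m / params.l_o_m
    c = np.cos(fiber.alpha)
    c0 = params.f_o_m * float(curves.passive_fl(x)) * c
    c1 = params.f_o_m * float(curves.active_fl(x)) * c
    return c0 + c1 * a, c0, c1
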