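"""Static optimization of muscle activations over a gait trial.

At each timestep the muscle-redundancy problem is solved: find activations
``a`` in [0, 1] minimizing a weighted sum of squared activations, subject
to muscle-generated joint moments matching inverse-dynamics moments at
every DOF. With fiber lengths fixed by the tendon-equilibrium solve (using
the previous timestep's activations), each MTU force is affine in its
activation, so the moment constraints are linear and the problem is a
strictly convex quadratic program.

Two objectives are provided: the natural objective min sum(a_i^2), a
standard surrogate for metabolic cost, and a gastrocnemius-avoidance
objective that multiplies the squared activation of both gastrocnemius
heads by a large weight (default 100), shifting plantarflexion duty to the
soleus.

An optional EMG-derived ratio constraint forces the simulated
gastrocnemius-to-soleus activation ratio to track the measured ratio
within a tolerance (default 0.02), enforced separately for each
gastrocnemius head. The nonlinear ratio bound |g/(g+s) - r| <= tol is
rewritten exactly as two linear inequalities,

    g (1 - (r+tol)) <= (r+tol) s      and      g (1 - (r-tol)) >= (r-tol) s,

valid whenever g + s > 0, which is guaranteed by a small lower activation
bound on enforced frames.

Ideal reserve torques (one per DOF, heavily penalized) guarantee
feasibility; on well-posed trials they stay at numerical zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .hill import FiberState, mtu_force, rigid_tendon_fiber, solve_fiber_equilibrium
from .model import PlanarModel

RESERVE_SCALE_NM = 100.0  # reserve torques are normalized by this before penalty
DEFAULT_RESERVE_WEIGHT = 1000.0
RATIO_ACTIVATION_FLOOR = 1e-6
RATIO_DENOM_FLOOR = 0.01  # enforce Eq-ratio only where delayed envelopes sum >= this


class InfeasibleFrameError(RuntimeError):
    """The moment constraints could not be met even with reserve torques."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """Coordination objective: 'natural' or 'gastroc_avoidance'."""

    kind: str = "natural"
    gastroc_weight: float = 100.0
    reserve_weight: float = DEFAULT_RESERVE_WEIGHT

    def __post_init__(self) -> None:
        if self.kind not in ("natural", "gastroc_avoidance"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.kind == "gastroc_avoidance" and self.gastroc_weight <= 1:
            raise ValueError("gastroc_weight must exceed 1 for avoidance")

    def muscle_weights(self, model: PlanarModel) -> np.ndarray:
        w = self.gastroc_weight if self.kind == "gastroc_avoidance" else 1.0
        return model.weight_vector(w)


@dataclass
class RatioConstraintSpec:
    """EMG activation-ratio tracking constraint.

    ``emg_ratio`` maps each gastrocnemius head name to its per-frame target
    ratio series g/(g+s); enforced where ``active_mask`` is True.
    """

    emg_ratio: dict[str, np.ndarray]
    active_mask: np.ndarray
    tolerance: float = 0.02
    delay: float = 0.040
    soleus: str = "soleus"

    def __post_init__(self) -> None:
        if not 0 < self.tolerance < 0.5:
            raise ValueError("tolerance must be in (0, 0.5)")


@dataclass
class ActivationSolution:
    """Per-frame activations, fiber states, forces and diagnostics."""

    muscle_names: list[str]
    activations: np.ndarray  # (T, nM)
    mtu_forces: np.ndarray  # (T, nM), N
    fiber_lengths: np.ndarray  # (T, nM), m
    reserve_torques: np.ndarray  # (T, nDOF), N*m
    objective_values: np.ndarray  # (T,)
    moment_residuals: np.ndarray  # (T, nDOF), N*m
    ratio_residuals: np.ndarray | None = None  # (T, nHeads) where enforced
    fiber_states: list[list[FiberState]] = field(default_factory=list)
    #: activation history actually fed into each frame's tendon-equilibrium
    #: solve (frame 0 is re-solved once, warm-started with its own first-pass
    #: activations, so this differs from a simple one-frame shift there)
    a_prev_used: np.ndarray | None = None


def _solve_qp(H, g, A_eq, b_eq, lb, ub, C=None, d=None):
    """Minimize 0.5 x'Hx + g'x s.t. A_eq x = b_eq, Cx <= d, lb <= x <= ub.

    SLSQP solve followed by an exact KKT re-solve on the active set it
    identifies, which drives equality residuals to machine precision. H is
    diagonal positive definite.
    """
    n = len(g)
    x0 = np.clip(np.zeros(n), lb, ub)
    cons = [{"type": "eq",
             "fun": lambda x: A_eq @ x - b_eq,
             "jac": lambda x: A_eq}]
    if C is not None and len(C):
        cons.append({"type": "ineq",
                     "fun": lambda x: d - C @ x,
                     "jac": lambda x: -C})
    res = minimize(
        lambda x: 0.5 * x @ (H * x) + g @ x,
        x0,
        jac=lambda x: H * x + g,
        bounds=list(zip(lb, ub)),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 300, "ftol": 1e-14},
    )
    x = res.x
    if not res.success:
        # retry from an interior point
        res = minimize(
            lambda x: 0.5 * x @ (H * x) + g @ x,
            np.clip(0.1 * np.ones(n), lb, ub),
            jac=lambda x: H * x + g,
            bounds=list(zip(lb, ub)),
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if not res.success:
            raise InfeasibleFrameError(res.message)
        x = res.x

    x = _kkt_polish(x, H, g, A_eq, b_eq, lb, ub, C, d)
    if np.max(np.abs(A_eq @ x - b_eq)) > 1e-6:
        raise InfeasibleFrameError("moment constraints violated at optimum")
    return x


def _kkt_polish(x, H, g, A_eq, b_eq, lb, ub, C, d, tol=1e-7):
    """Re-solve the equality-constrained QP on the active set of ``x``."""
    n = len(x)
    rows = [A_eq]
    rhs = [b_eq]
    lower_active = x <= lb + tol
    upper_active = x >= ub - tol
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        if lower_active[i]:
            rows.append(e[None, :])
            rhs.append(np.array([lb[i]]))
        elif upper_active[i]:
            rows.append(e[None, :])
            rhs.append(np.array([ub[i]]))
    if C is not None and len(C):
        slack = d - C @ x
        act = slack <= tol
        if np.any(act):
            rows.append(C[act])
            rhs.append(d[act])
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    m = A.shape[0]
    K = np.zeros((n + m, n + m))
    K[:n, :n] = np.diag(H)
    K[:n, n:] = A.T
    K[n:, :n] = A
    r = np.concatenate([-g, b])
    try:
        sol, *_ = np.linalg.lstsq(K, r, rcond=None)
    except np.linalg.LinAlgError:
        return x
    x_new = sol[:n]
    # accept only if the polished point is feasible and no worse
    if np.any(x_new < lb - 1e-9) or np.any(x_new > ub + 1e-9):
        return x
    if C is not None and len(C) and np.any(C @ x_new > d + 1e-9):
        return x
    f_old = 0.5 * x @ (H * x) + g @ x
    f_new = 0.5 * x_new @ (H * x_new) + g @ x_new
    if f_new > f_old + 1e-9 * (1 + abs(f_old)):
        return x
    return np.clip(x_new, lb, ub)


def _fiber_pass(model: PlanarModel, q: dict, a_prev: np.ndarray,
                l_m_init: np.ndarray | None, rigid_tendon: bool):
    fibers = []
    for i, (p, _) in enumerate(model.muscles):
        l_mtu = model.mtu_length(p.name, q)
        if rigid_tendon or p.l_s_t == 0.0:
            fibers.append(rigid_tendon_fiber(p, l_mtu))
        else:
            init = l_m_init[i] if l_m_init is not None else None
            fibers.append(
                solve_fiber_equilibrium(p, model.curves, float(a_prev[i]),
                                        l_mtu, init)
            )
    return fibers


def solve_timestep(
    model: PlanarModel,
    q: dict[str, float],
    m_id: np.ndarray,
    a_prev: np.ndarray,
    objective: ObjectiveSpec,
    ratio_targets: dict[str, float] | None = None,
    ratio_tol: float = 0.02,
    l_m_init: np.ndarray | None = None,
    rigid_tendon: bool = False,
):
    """Solve one frame of the redundancy problem.

    Returns ``(a, reserves, fibers, forces, obj_value, moment_residual)``.
    ``ratio_targets`` maps gastrocnemius head name -> target ratio for this
    frame (None disables the EMG constraint).
    """
    nM = len(model.muscles)
    nD = len(model.dofs)
    fibers = _fiber_pass(model, q, a_prev, l_m_init, rigid_tendon)

    c0 = np.empty(nM)
    c1 = np.empty(nM)
    for i, (p, _) in enumerate(model.muscles):
        _, c0[i], c1[i] = mtu_force(p, model.curves, 0.0, fibers[i])

    R = model.moment_arm_matrix(q)  # (nD, nM)

    # decision vector: [a (nM), reserves (nD)]
    w = objective.muscle_weights(model)
    H = np.concatenate([
        2.0 * w,
        2.0 * objective.reserve_weight / RESERVE_SCALE_NM**2 * np.ones(nD),
    ])
    g = np.zeros(nM + nD)

    A_eq = np.zeros((nD, nM + nD))
    A_eq[:, :nM] = R * c1[None, :]
    A_eq[:, nM:] = np.eye(nD)
    b_eq = np.asarray(m_id, dtype=float) - R @ c0

    # Reserves are a feasibility fallback only: first solve with them pinned
    # at zero so well-posed trials carry no reserve torque at all.
    lb = np.concatenate([np.zeros(nM), np.zeros(nD)])
    ub = np.concatenate([np.ones(nM), np.zeros(nD)])

    C = d = None
    if ratio_targets:
        names = model.muscle_names
        i_sol = names.index("soleus")
        rows, rh = [], []
        tol_eff = ratio_tol - 1e-7  # numerical margin keeps the exact bound
        for head, r in ratio_targets.items():
            i_g = names.index(head)
            lb[i_g] = max(lb[i_g], RATIO_ACTIVATION_FLOOR)
            lb[i_sol] = max(lb[i_sol], RATIO_ACTIVATION_FLOOR)
            hi = min(r + tol_eff, 1.0)
            lo = max(r - tol_eff, 0.0)
            # g(1-hi) - hi*s <= 0
            row = np.zeros(nM + nD)
            row[i_g] = 1.0 - hi
            row[i_sol] = -hi
            rows.append(row)
            rh.append(0.0)
            # -(g(1-lo) - lo*s) <= 0
            row = np.zeros(nM + nD)
            row[i_g] = -(1.0 - lo)
            row[i_sol] = lo
            rows.append(row)
            rh.append(0.0)
        C = np.vstack(rows)
        d = np.array(rh)

    try:
        x = _solve_qp(H, g, A_eq, b_eq, lb, ub, C, d)
    except InfeasibleFrameError:
        lb[nM:] = -np.inf
        ub[nM:] = np.inf
        x = _solve_qp(H, g, A_eq, b_eq, lb, ub, C, d)
    a = x[:nM]
    reserves = x[nM:]
    forces = c0 + c1 * a
    resid = R @ forces + reserves - m_id
    obj = float(np.sum(w * a**2)
                + objective.reserve_weight
                * np.sum((reserves / RESERVE_SCALE_NM) ** 2))
    return a, reserves, fibers, forces, obj, resid


def solve_trial(
    model: PlanarModel,
    trial,
    objective: ObjectiveSpec,
    ratio: RatioConstraintSpec | None = None,
    rigid_tendon: bool = False,
) -> ActivationSolution:
    """Sequential per-timestep solve over a gait trial.

    Activation history threads into the tendon-equilibrium solve: frame k
    uses frame k-1's optimized activations. The first frame is solved from
    rest and then re-solved once, warm-started with its own activations.
    """
    t = np.asarray(trial.t)
    if np.any(np.diff(t) <= 0):
        raise ValueError("trial time grid must be strictly increasing")
    T = len(t)
    nM = len(model.muscles)
    nD = len(model.dofs)

    act = np.zeros((T, nM))
    forces = np.zeros((T, nM))
    fl = np.zeros((T, nM))
    reserves = np.zeros((T, nD))
    objvals = np.zeros(T)
    resid = np.zeros((T, nD))
    ratio_resid = None
    heads: list[str] = []
    if ratio is not None:
        heads = sorted(ratio.emg_ratio)
        ratio_resid = np.full((T, len(heads)), np.nan)

    a_prev = np.zeros(nM)
    l_m_prev: np.ndarray | None = None
    all_fibers: list[list[FiberState]] = []
    a_prev_used = np.zeros((T, nM))

    for k in range(T):
        q = {dof: float(trial.q[dof][k]) for dof in model.dofs}
        m_id = np.array([trial.m_id[dof][k] for dof in model.dofs])
        targets = None
        if ratio is not None and bool(ratio.active_mask[k]):
            targets = {h: float(ratio.emg_ratio[h][k]) for h in heads}
        try:
            out = solve_timestep(
                model, q, m_id, a_prev, objective,
                ratio_targets=targets, ratio_tol=(ratio.tolerance if ratio else 0.02),
                l_m_init=l_m_prev, rigid_tendon=rigid_tendon,
            )
        except Exception as e:  # annotate with the failing frame
            raise RuntimeError(f"frame {k} (t={t[k]:.3f} s): {e}") from e
        a, res, fibers, f, obj, r = out
        a_prev_used[k] = a_prev

        if k == 0:
            # warm-start pass: re-solve frame 0 with its own activations
            a_prev_used[0] = a
            out = solve_timestep(
                model, q, m_id, a, objective,
                ratio_targets=targets, ratio_tol=(ratio.tolerance if ratio else 0.02),
                l_m_init=np.array([fb.l_m for fb in fibers]),
                rigid_tendon=rigid_tendon,
            )
            a, res, fibers, f, obj, r = out

        act[k] = a
        reserves[k] = res
        forces[k] = f
        fl[k] = [fb.l_m for fb in fibers]
        objvals[k] = obj
        resid[k] = r
        all_fibers.append(fibers)
        if targets is not None:
            names = model.muscle_names
            i_sol = names.index("soleus")
            for hi_idx, h in enumerate(heads):
                i_g = names.index(h)
                denom = a[i_g] + a[i_sol]
                sim_r = a[i_g] / denom if denom > 0 else np.nan
                ratio_resid[k, hi_idx] = sim_r - ratio.emg_ratio[h][k]
        a_prev = a
        l_m_prev = fl[k]

    return ActivationSolution(
        muscle_names=model.muscle_names,
        activations=act,
        mtu_forces=forces,
        fiber_lengths=fl,
        reserve_torques=reserves,
        objective_values=objvals,
        moment_residuals=resid,
        ratio_residuals=ratio_resid,
        fiber_states=all_fibers,
        a_prev_used=a_prev_used,
    )


def brute_force_oracle(
    model: PlanarModel,
    q: dict[str, float],
    m_id: np.ndarray,
    a_prev: np.ndarray,
    objective: ObjectiveSpec,
    grid_step: float = 1e-3,
    moment_tol: float | None = None,
):
    """Exhaustive grid search over the activation box (tiny problems only).

    Feasibility is moment matching within ``moment_tol`` (default: the
    moment slack achievable by one grid step). Returns the best feasible
    grid point, or None when the grid holds no feasible point.
    """
    nM = len(model.muscles)
    if nM > 4 or len(model.dofs) > 2:
        raise ValueError("oracle limited to <= 4 muscles and <= 2 DOFs")
    fibers = _fiber_pass(model, q, a_prev, None, False)
    c0 = np.empty(nM)
    c1 = np.empty(nM)
    for i, (p, _) in enumerate(model.muscles):
        _, c0[i], c1[i] = mtu_force(p, model.curves, 1.0, fibers[i])
    R = model.moment_arm_matrix(q)
    if moment_tol is None:
        # finest moment increment the grid can realize per DOF: about half a
        # grid step through the highest-gain muscle
        moment_tol = 0.51 * grid_step * np.abs(R * c1[None, :]).max(axis=1)
    w = objective.muscle_weights(model)

    axes = [np.arange(0.0, 1.0 + grid_step / 2, grid_step)] * nM
    grids = np.meshgrid(*axes, indexing="ij")
    A = np.stack([gr.ravel() for gr in grids], axis=1)  # (G, nM)
    F = c0[None, :] + c1[None, :] * A
    M = F @ R.T  # (G, nD)
    feas = np.all(np.abs(M - np.asarray(m_id)[None, :]) <= moment_tol, axis=1)
    if not feas.any():
        return None
    cost = (A**2 * w[None, :]).sum(axis=1)
    cost[~feas] = np.inf
    return A[int(np.argmin(cost))]
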