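"""End-to-end orchestration: simulate, process EMG, solve, compute KCF.

Two study stages are mirrored here. The design stage solves identical
joint kinetics under the natural and the gastrocnemius-avoidance
objectives and reports the compensatory force changes and the knee-load
delta that motivate plantarflexor biofeedback. The evaluation stage runs
EMG-informed solves of baseline and retention trials, with the simulated
gastrocnemius-to-soleus activation ratio constrained to track the measured
(delayed, MVC-normalized) EMG ratio within 2%.

Cohort summaries are descriptive (mean +/- SD) only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emg import (
    EMGRecording,
    activation_ratio,
    apply_delay,
    compute_envelope,
    framewise_ratio,
    normalize_mvc,
)
from .loading import KCFResult, compute_kcf
from .model import PlanarModel
from .solver import (
    ActivationSolution,
    ObjectiveSpec,
    RatioConstraintSpec,
    RATIO_DENOM_FLOOR,
    solve_trial,
)
from .synth import GaitTrial, SyntheticTruth, generate_emg

GASTROC_HEADS = ("gasmed", "gaslat")


def process_emg(
    raw: dict[str, np.ndarray],
    mvc_raw: dict[str, np.ndarray],
    fs: float,
    delay: float = 0.040,
):
    """Raw EMG -> delayed, MVC-normalized linear envelopes."""
    env = compute_envelope(EMGRecording(dict(raw), fs))
    mvc_env = compute_envelope(EMGRecording(dict(mvc_raw), fs))
    norm = normalize_mvc(env, mvc_env.channels)
    return apply_delay(norm, delay)


def envelopes_on_grid(
    env_channels: dict[str, np.ndarray],
    fs: float,
    trial: GaitTrial,
    cycle_duration: float,
    cycle_index: int = 1,
) -> dict[str, np.ndarray]:
    """Extract one cycle of each envelope and resample to the trial grid.

    ``cycle_index`` selects which repetition of the tiled EMG to use; the
    middle cycle avoids filter edge effects.
    """
    n_cyc = int(round(cycle_duration * fs))
    out = {}
    for ch, x in env_channels.items():
        seg = x[cycle_index * n_cyc:(cycle_index + 1) * n_cyc]
        p_hi = np.arange(len(seg)) / n_cyc
        out[ch] = np.interp(trial.t / cycle_duration, p_hi, seg)
    return out


def ratio_constraint_from_envelopes(
    grid_env: dict[str, np.ndarray],
    trial: GaitTrial,
    tolerance: float = 0.02,
    delay: float = 0.040,
) -> RatioConstraintSpec:
    """Build the EMG ratio constraint for both gastrocnemius heads.

    Enforced only during stance and where the delayed gastrocnemius plus
    soleus envelopes exceed the denominator floor.
    """
    soleus = grid_env["soleus"]
    ratios = {}
    mask = np.asarray(trial.stance_mask, dtype=bool).copy()
    for head in GASTROC_HEADS:
        r, ok = framewise_ratio(grid_env[head], soleus, RATIO_DENOM_FLOOR)
        ratios[head] = np.nan_to_num(r, nan=0.5)
        mask &= ok
    return RatioConstraintSpec(
        emg_ratio=ratios, active_mask=mask, tolerance=tolerance, delay=delay
    )


def _group_stance_forces(
    model: PlanarModel, sol: ActivationSolution, trial: GaitTrial
) -> dict[str, float]:
    st = trial.stance_mask
    names = sol.muscle_names
    out = {}
    for gname, members in model.groups.items():
        idx = [names.index(m) for m in members]
        out[gname] = float(sol.mtu_forces[st][:, idx].sum(axis=1).mean())
    out["iliopsoas"] = float(
        sol.mtu_forces[st][:, names.index("iliopsoas")].mean()
    )
    return out


def _sim_ratio(sol: ActivationSolution, trial: GaitTrial) -> float:
    names = sol.muscle_names
    return activation_ratio(
        sol.activations[:, names.index("gasmed")],
        sol.activations[:, names.index("soleus")],
        trial.stance_mask,
    )


@dataclass
class ConditionResult:
    """One solved condition: activations, knee loading, summary scalars."""

    solution: ActivationSolution
    kcf: KCFResult
    activation_ratio: float
    stance_group_forces: dict[str, float]


def _run_condition(model, trial, objective, ratio=None, rigid_tendon=False):
    sol = solve_trial(model, trial, objective, ratio=ratio,
                      rigid_tendon=rigid_tendon)
    kcf = compute_kcf(model, sol, trial)
    return ConditionResult(
        solution=sol,
        kcf=kcf,
        activation_ratio=_sim_ratio(sol, trial),
        stance_group_forces=_group_stance_forces(model, sol, trial),
    )


def run_design_simulation(
    model: PlanarModel, trial: GaitTrial, gastroc_weight: float = 100.0
) -> dict:
    """Solve identical kinetics under natural and avoidance objectives."""
    nat = _run_condition(model, trial, ObjectiveSpec("natural"))
    avoid = _run_condition(
        model, trial,
        ObjectiveSpec("gastroc_avoidance", gastroc_weight=gastroc_weight),
    )
    rows = {}
    for grp in ("gastrocnemius", "soleus", "hamstrings", "iliopsoas",
                "quadriceps"):
        rows[f"force_{grp}_natural_N"] = nat.stance_group_forces[grp]
        rows[f"force_{grp}_avoidance_N"] = avoid.stance_group_forces[grp]
    report = {
        "natural": nat,
        "avoidance": avoid,
        "summary": {
            **rows,
            "kcf_p1_natural_BW": nat.kcf.p1_bw,
            "kcf_p2_natural_BW": nat.kcf.p2_bw,
            "kcf_p1_avoidance_BW": avoid.kcf.p1_bw,
            "kcf_p2_avoidance_BW": avoid.kcf.p2_bw,
            "kcf_p2_delta_BW": avoid.kcf.p2_bw - nat.kcf.p2_bw,
            "ratio_natural": nat.activation_ratio,
            "ratio_avoidance": avoid.activation_ratio,
        },
    }
    return report


def run_emg_informed(
    model: PlanarModel,
    trial: GaitTrial,
    truth: SyntheticTruth,
    fs: float = 2000.0,
    cycle_duration: float = 1.1,
    tolerance: float = 0.02,
    delay: float = 0.040,
    emg_seed: int | None = None,
) -> dict:
    """EMG-informed solve of one trial: generate EMG, process, constrain."""
    raw, mvc_raw = generate_emg(
        truth, fs=fs, cycle_duration=cycle_duration, seed=emg_seed
    )
    delayed = process_emg(raw, mvc_raw, fs, delay=delay)
    grid_env = envelopes_on_grid(delayed.channels, fs, trial, cycle_duration)
    ratio = ratio_constraint_from_envelopes(
        grid_env, trial, tolerance=tolerance, delay=delay
    )
    cond = _run_condition(model, trial, ObjectiveSpec("natural"), ratio=ratio)
    rr = cond.solution.ratio_residuals
    enforced = ratio.active_mask
    max_resid = float(np.nanmax(np.abs(rr[enforced]))) if enforced.any() else np.nan
    emg_ratio = activation_ratio(
        grid_env["gasmed"], grid_env["soleus"], trial.stance_mask
    )
    return {
        "condition": cond,
        "ratio_spec": ratio,
        "summary": {
            "emg_ratio": emg_ratio,
            "sim_ratio": cond.activation_ratio,
            "max_ratio_residual": max_resid,
            "n_enforced_frames": int(enforced.sum()),
            "kcf_p1_BW": cond.kcf.p1_bw,
            "kcf_p2_BW": cond.kcf.p2_bw,
            "gastroc_p2_contrib_BW": float(
                cond.kcf.group_contribs_n["gastrocnemius"][
                    _p2_index(cond.kcf)
                ] / model.bodyweight_newtons
            ),
        },
    }


def _p2_index(kcf: KCFResult) -> int:
    idx = np.flatnonzero(kcf.stance_mask)
    late = idx[idx.size // 2:]
    return int(late[np.argmax(kcf.total_n[late])])


def compare_baseline_retention(
    model: PlanarModel, pair, fs: float = 2000.0, cycle_duration: float = 1.1
) -> dict:
    """EMG-informed baseline vs retention contrast for one subject."""
    base_trial, base_truth = pair.baseline
    ret_trial, ret_truth = pair.retention
    base = run_emg_informed(model, base_trial, base_truth, fs=fs,
                            cycle_duration=cycle_duration)
    ret = run_emg_informed(model, ret_trial, ret_truth, fs=fs,
                           cycle_duration=cycle_duration)
    b, r = base["summary"], ret["summary"]
    return {
        "baseline": base,
        "retention": ret,
        "summary": {
            "ratio_baseline": b["sim_ratio"],
            "ratio_retention": r["sim_ratio"],
            "ratio_change_pct": 100.0 * (r["sim_ratio"] - b["sim_ratio"])
            / b["sim_ratio"],
            "kcf_p2_baseline_BW": b["kcf_p2_BW"],
            "kcf_p2_retention_BW": r["kcf_p2_BW"],
            "kcf_p2_delta_BW": r["kcf_p2_BW"] - b["kcf_p2_BW"],
            "gastroc_p2_contrib_delta_BW": r["gastroc_p2_contrib_BW"]
            - b["gastroc_p2_contrib_BW"],
            "max_ratio_residual": max(
                b["max_ratio_residual"], r["max_ratio_residual"]
            ),
        },
    }


def summarize_cohort(summaries: list[dict]) -> pd.DataFrame:
    """Column-wise mean and SD over per-subject summary dicts."""
    if not summaries:
        raise ValueError("need at least one report")
    df = pd.DataFrame(summaries)
    out = pd.DataFrame({"mean": df.mean(axis=0), "sd": df.std(axis=0, ddof=1)})
    if len(df) == 1:
        out["sd"] = 0.0
    return out
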