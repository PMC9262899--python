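"""Knee contact force (KCF) along the tibia's longitudinal axis.

Total KCF is the sum of the intersegmental axial reaction (from inverse
dynamics with torque actuators only) and the axial components of tensile
forces in every knee-crossing muscle. With constant per-muscle axial
projection coefficients the decomposition into functional muscle groups is
an exact superposition.

Peaks: P1 is the maximum over the first half of stance, P2 the maximum
over the final half. (For joint angles/moments plotted flexor-negative the
late-stance peak is conventionally a minimum; KCF is compressive-positive
throughout stance, so both peaks are maxima.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PlanarModel
from .solver import ActivationSolution


@dataclass
class KCFResult:
    """KCF time series and its decomposition, plus half-stance peaks."""

    t: np.ndarray
    total_n: np.ndarray
    intersegmental_n: np.ndarray
    group_contribs_n: dict[str, np.ndarray]
    bodyweight_n: float
    stance_mask: np.ndarray
    p1_bw: float
    p2_bw: float

    @property
    def total_bw(self) -> np.ndarray:
        return self.total_n / self.bodyweight_n

    @property
    def intersegmental_bw(self) -> np.ndarray:
        return self.intersegmental_n / self.bodyweight_n


def extract_peaks(series: np.ndarray, stance_mask: np.ndarray) -> tuple[float, float]:
    """(P1, P2): maxima over the first and final halves of stance."""
    mask = np.asarray(stance_mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("stance mask selects no samples")
    vals = np.asarray(series, dtype=float)[idx]
    if np.all(np.isnan(vals)):
        raise ValueError("series is all-NaN over stance")
    half = idx.size // 2
    first = vals[:half] if half > 0 else vals[:1]
    last = vals[half:]
    return float(np.nanmax(first)), float(np.nanmax(last))


def decompose_kcf(
    model: PlanarModel, solution: ActivationSolution, trial
) -> dict[str, np.ndarray]:
    """Per-group axial muscle force contributions at the knee, N."""
    coeffs = model.knee_axial_coeffs()
    names = solution.muscle_names
    grouped: set[str] = set()
    out: dict[str, np.ndarray] = {}
    for gname, members in model.groups.items():
        idx = [names.index(m) for m in members]
        grouped.update(members)
        out[gname] = solution.mtu_forces[:, idx] @ coeffs[idx]
    for i, n in enumerate(names):
        if coeffs[i] != 0.0 and n not in grouped:
            raise ValueError(
                f"muscle {n!r} crosses the knee but belongs to no group"
            )
    return out


def compute_kcf(
    model: PlanarModel, solution: ActivationSolution, trial
) -> KCFResult:
    """Total KCF, its intersegmental/muscle-group decomposition and peaks."""
    if trial.interseg_axial is None:
        raise ValueError("trial has no intersegmental axial force series")
    interseg = np.asarray(trial.interseg_axial, dtype=float)
    if len(interseg) != solution.activations.shape[0]:
        raise ValueError("solution and trial time grids differ")
    groups = decompose_kcf(model, solution, trial)
    total = interseg + sum(groups.values())
    bw = model.bodyweight_newtons
    p1, p2 = extract_peaks(total / bw, trial.stance_mask)
    return KCFResult(
        t=np.asarray(trial.t),
        total_n=total,
        intersegmental_n=interseg,
        group_contribs_n=groups,
        bodyweight_n=bw,
        stance_mask=np.asarray(trial.stance_mask, dtype=bool),
        p1_bw=p1,
        p2_bw=p2,
    )
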