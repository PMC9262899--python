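"""Seeded synthetic gait generator with known ground truth.

One gait cycle (heel strike to heel strike) is built from smooth periodic
sagittal joint-angle profiles and a set of smooth per-muscle ground-truth
activation bumps whose phasing follows the normative pattern: hamstrings
dominant in the first 10% of stance, quadriceps from 10-40% of stance, and
the plantarflexors (gastrocnemius and soleus) from 40-90% of stance.

The inverse-dynamics joint moments are computed FROM the ground-truth
activations through the same musculotendon model the solver uses (forward
consistency), so the generated moments are exactly achievable and a
redundancy solve needs no reserve torques. Because the redundancy problem
has many solutions, recovery tests target moments, activation ratios and
knee loading rather than raw activations.

Raw EMG is emulated per channel as the ground-truth activation modulator
(advanced by the 40 ms electromechanical delay, so that envelope + delay
re-aligns with the truth) multiplying zero-mean band-limited (30-450 Hz)
carrier noise, plus a small additive sensor-noise floor. Maximum voluntary
contraction (MVC) recordings use a constant unit modulator.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .hill import mtu_force, solve_fiber_equilibrium
from .model import PlanarModel

#: EMG electrode channel -> model muscle providing its modulator.
EMG_CHANNELS = {
    "soleus": "soleus",
    "gasmed": "gasmed",
    "gaslat": "gaslat",
    "tibant": "tibant",
    "bflh": "bflh",
    "semiten": "semiten",
    "recfem": "recfem",
    "vasmed": "vasmed",
    "vaslat": "vaslat",
}


@dataclass
class GaitTrial:
    """One gait cycle of kinematics, kinetics and stance events."""

    t: np.ndarray
    q: dict[str, np.ndarray]  # rad per DOF
    m_id: dict[str, np.ndarray]  # N*m per DOF
    stance_mask: np.ndarray
    interseg_axial: np.ndarray | None  # N, compressive positive
    bodyweight: float  # N
    grf_vertical: np.ndarray | None = None  # N


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated trial."""

    muscle_names: list[str]
    activations_true: np.ndarray  # (T, nM)
    emg_modulators: dict[str, np.ndarray]  # per channel, truth-aligned
    seed: int


@dataclass
class TrialConfig:
    """Generator settings; defaults are normative treadmill walking.

    Activation bump amplitudes are fractions of maximum activation; bump
    centers/widths are fractions of the gait cycle.
    """

    cycle_duration: float = 1.1  # s
    stance_fraction: float = 0.6
    dt: float = 0.01  # s
    bodyweight: float = 700.0  # N
    emg_delay: float = 0.040  # s
    gastroc_scale: float = 1.0  # retention presets scale the gastrocnemius down
    ratio_reduction: float | None = None  # exact truth-ratio reduction target
    amplitude_jitter: dict[str, float] = field(default_factory=dict)


# (center, width, amplitude) of periodic activation bumps, in cycle fraction.
# Multiple bumps per muscle are summed. Stance occupies [0, 0.6).
_ACTIVATION_BUMPS: dict[str, list[tuple[float, float, float]]] = {
    "glutei":    [(0.04, 0.06, 0.28)],
    "bflh":      [(0.02, 0.05, 0.24), (0.93, 0.06, 0.18)],
    "bfsh":      [(0.02, 0.05, 0.18), (0.93, 0.06, 0.14)],
    "semiten":   [(0.02, 0.05, 0.22), (0.93, 0.06, 0.16)],
    "semimem":   [(0.02, 0.05, 0.24), (0.93, 0.06, 0.16)],
    "vasmed":    [(0.12, 0.07, 0.32)],
    "vaslat":    [(0.12, 0.07, 0.32)],
    "recfem":    [(0.13, 0.07, 0.16), (0.62, 0.05, 0.12)],
    "soleus":    [(0.42, 0.09, 0.50)],
    "gasmed":    [(0.41, 0.08, 0.42)],
    "gaslat":    [(0.41, 0.08, 0.34)],
    "tibant":    [(0.02, 0.05, 0.22), (0.75, 0.12, 0.28)],
    "iliopsoas": [(0.58, 0.08, 0.30)],
    "tfl":       [(0.55, 0.10, 0.12)],
}

_BASELINE_ACTIVATION = 0.01  # small tonic level keeps equilibria well-posed


def _periodic_bump(p: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth periodic bump of unit height at ``center`` (cycle fraction).

    A von Mises-shaped bump matching a Gaussian of standard deviation
    ``width`` near its peak.
    """
    return np.exp(
        (np.cos(2.0 * np.pi * (p - center)) - 1.0)
        / (2.0 * np.pi * width) ** 2
    )


def _kinematics(p: np.ndarray) -> dict[str, np.ndarray]:
    """Normative sagittal joint angles (rad) over cycle fraction ``p``."""
    hip = 0.14 + 0.31 * np.cos(2 * np.pi * p)
    knee = (
        0.06
        + 0.22 * _periodic_bump(p, 0.15, 0.08)
        + 1.00 * _periodic_bump(p, 0.73, 0.10)
    )
    ankle = (
        0.06 * _periodic_bump(p, 0.05, 0.05)
        - 0.20 * _periodic_bump(p, 0.45, 0.12)
        + 0.28 * _periodic_bump(p, 0.65, 0.06)
    )
    return {
        "hip_flexion": hip,
        "knee_flexion": knee,
        "ankle_plantarflexion": ankle,
    }


def _truth_activations(
    model: PlanarModel, p: np.ndarray, cfg: TrialConfig
) -> np.ndarray:
    T = len(p)
    names = model.muscle_names
    act = np.full((T, len(names)), _BASELINE_ACTIVATION)
    for i, name in enumerate(names):
        for center, width, amp in _ACTIVATION_BUMPS.get(name, []):
            amp = amp * cfg.amplitude_jitter.get(name, 1.0)
            act[:, i] += amp * _periodic_bump(p, center, width)
    gastroc = set(model.groups.get("gastrocnemius", ()))
    if cfg.gastroc_scale != 1.0:
        for i, name in enumerate(names):
            if name in gastroc:
                act[:, i] *= cfg.gastroc_scale
    if np.any(act > 1.0) or np.any(act < 0.0):
        raise ValueError("configured activation bumps leave [0, 1]")
    return act


def _soleus_scale_for_ratio(
    model: PlanarModel, act: np.ndarray, stance: np.ndarray,
    gastroc_scale: float, ratio_reduction: float,
) -> float:
    """Soleus scale making the truth ratio drop by exactly ratio_reduction.

    Truth ratio uses the medial gastrocnemius per the biofeedback metric.
    Stance means scale linearly with amplitude, so the reduction is exact.
    """
    names = model.muscle_names
    g = act[stance, names.index("gasmed")].mean() / gastroc_scale
    s = act[stance, names.index("soleus")].mean()
    r0 = g / (g + s)
    r1 = (1.0 - ratio_reduction) * r0
    return gastroc_scale * g * (1.0 - r1) / (r1 * s)


def _forward_moments(model: PlanarModel, trial_q, t, act):
    """Joint moments generated by the truth activations (sequential fibers)."""
    T = len(t)
    nD = len(model.dofs)
    m = np.zeros((T, nD))
    l_m_prev = None
    for k in range(T):
        q = {dof: float(trial_q[dof][k]) for dof in model.dofs}
        a_prev = act[k - 1] if k > 0 else act[0]
        forces = np.empty(len(model.muscles))
        l_ms = np.empty(len(model.muscles))
        for i, (p_i, _) in enumerate(model.muscles):
            l_mtu = model.mtu_length(p_i.name, q)
            init = l_m_prev[i] if l_m_prev is not None else None
            fb = solve_fiber_equilibrium(
                p_i, model.curves, float(a_prev[i]), l_mtu, init
            )
            forces[i], _, _ = mtu_force(p_i, model.curves, float(act[k, i]), fb)
            l_ms[i] = fb.l_m
        R = model.moment_arm_matrix(q)
        m[k] = R @ forces
        l_m_prev = l_ms
    return m


def _interseg_profile(p: np.ndarray, stance_fraction: float, bw: float) -> np.ndarray:
    """Double-bump axial intersegmental knee force over stance, N."""
    ps = p / stance_fraction  # fraction of stance
    in_stance = p < stance_fraction
    base = (
        0.40 * np.exp(-0.5 * ((ps - 0.45) / 0.30) ** 2)
        + 0.62 * np.exp(-0.5 * ((ps - 0.18) / 0.10) ** 2)
        + 0.62 * np.exp(-0.5 * ((ps - 0.78) / 0.10) ** 2)
    )
    # smooth edge taper
    edge = np.clip(np.minimum(ps / 0.05, (1.0 - ps) / 0.05), 0.0, 1.0)
    out = np.where(in_stance, base * edge, 0.0)
    return bw * out


def generate_trial(
    model: PlanarModel,
    config: TrialConfig | None = None,
    seed: int = 0,
) -> tuple[GaitTrial, SyntheticTruth]:
    """Generate one gait cycle with forward-consistent moments."""
    cfg = config or TrialConfig()
    T = int(round(cfg.cycle_duration / cfg.dt))
    t = np.arange(T) * cfg.dt
    p = t / cfg.cycle_duration
    stance = p < cfg.stance_fraction

    q = _kinematics(p)
    act = _truth_activations(model, p, cfg)
    if cfg.ratio_reduction is not None:
        s = _soleus_scale_for_ratio(
            model, act, stance, cfg.gastroc_scale, cfg.ratio_reduction
        )
        act[:, model.muscle_names.index("soleus")] *= s
        if np.any(act > 1.0):
            raise ValueError("ratio-reduction preset pushed soleus above 1")

    m = _forward_moments(model, q, t, act)
    m_id = {dof: m[:, j] for j, dof in enumerate(model.dofs)}

    bw = cfg.bodyweight
    interseg = _interseg_profile(p, cfg.stance_fraction, bw)
    grf = _interseg_profile(p, cfg.stance_fraction, bw) * 1.12  # GRF-like

    # EMG modulators: truth activations, advanced by the electromechanical
    # delay so that envelope processing plus delay re-aligns with truth.
    shift = int(round(cfg.emg_delay / cfg.dt))
    modulators = {}
    for ch, muscle in EMG_CHANNELS.items():
        a = act[:, model.muscle_names.index(muscle)]
        modulators[ch] = np.roll(a, -shift)  # periodic cycle: roll is exact

    trial = GaitTrial(
        t=t, q=q, m_id=m_id, stance_mask=stance,
        interseg_axial=interseg, bodyweight=bw, grf_vertical=grf,
    )
    truth = SyntheticTruth(
        muscle_names=list(model.muscle_names),
        activations_true=act,
        emg_modulators=modulators,
        seed=seed,
    )
    return trial, truth


def _bandlimited_carrier(rng, n, fs, band=(30.0, 450.0)):
    """Unit-mean-rectified band-limited Gaussian carrier noise."""
    x = rng.standard_normal(n)
    high = min(band[1], 0.99 * fs / 2)
    sos = butter(4, [band[0], high], btype="band", fs=fs, output="sos")
    y = sosfiltfilt(sos, x)
    y /= y.std()
    return y * np.sqrt(np.pi / 2.0)  # E|carrier| = 1


def generate_emg(
    truth: SyntheticTruth,
    fs: float = 2000.0,
    cycle_duration: float = 1.1,
    n_cycles: int = 3,
    sensor_noise: float = 0.008,
    seed: int | None = None,
):
    """Raw EMG whose linear envelope recovers the truth modulators.

    Tiles the single-cycle modulators over ``n_cycles`` so the zero-phase
    filters have room to settle. Returns ``(recording, mvc_recording)``
    as raw-channel dicts with sampling rate ``fs`` (build
    :class:`coordsim.emg.EMGRecording` from them).
    """
    if fs < 1000.0:
        raise ValueError("EMG sampling rate must be at least 1000 Hz")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_cycle = int(round(cycle_duration * fs))
    n = n_cycle * n_cycles
    t_mod = np.linspace(0.0, 1.0, num=len(next(iter(truth.emg_modulators.values()))),
                        endpoint=False)
    p_hi = (np.arange(n) / n_cycle) % 1.0

    channels = {}
    mvc_channels = {}
    n_mvc = int(round(4.0 * fs))
    for ch, mod in truth.emg_modulators.items():
        mod_hi = np.interp(p_hi, t_mod, mod, period=1.0)
        carrier = _bandlimited_carrier(rng, n, fs)
        noise = sensor_noise * rng.standard_normal(n)
        channels[ch] = mod_hi * carrier + noise
        mvc_carrier = _bandlimited_carrier(rng, n_mvc, fs)
        mvc_channels[ch] = mvc_carrier + sensor_noise * rng.standard_normal(n_mvc)
    return channels, mvc_channels


@dataclass
class SubjectPair:
    """Baseline and retention trials for one synthetic subject."""

    subject: int
    baseline: tuple[GaitTrial, SyntheticTruth]
    retention: tuple[GaitTrial, SyntheticTruth]
    config_baseline: TrialConfig
    config_retention: TrialConfig


def retention_config(
    base: TrialConfig | None = None,
    gastroc_scale: float = 0.6,
    ratio_reduction: float = 0.25,
) -> TrialConfig:
    """Retention-preset config: gastrocnemius down, soleus up, exact
    truth-ratio reduction."""
    cfg = base or TrialConfig()
    return replace(cfg, gastroc_scale=gastroc_scale, ratio_reduction=ratio_reduction)


def make_cohort(
    model: PlanarModel,
    n_subjects: int,
    seed: int = 0,
    base_config: TrialConfig | None = None,
) -> list[SubjectPair]:
    """Baseline/retention pairs with per-subject seeded parameter jitter."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    base = base_config or TrialConfig()
    pairs = []
    for s in range(n_subjects):
        bw = base.bodyweight * float(rng.uniform(0.9, 1.1))
        jitter = {
            name: float(rng.uniform(0.92, 1.08))
            for name in _ACTIVATION_BUMPS
        }
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg_b = replace(base, bodyweight=bw, amplitude_jitter=jitter)
        cfg_r = retention_config(cfg_b)
        model_s = replace_bodyweight(model, bw)
        pairs.append(
            SubjectPair(
                subject=s,
                baseline=generate_trial(model_s, cfg_b, seed=sub_seed),
                retention=generate_trial(model_s, cfg_r, seed=sub_seed + 1),
                config_baseline=cfg_b,
                config_retention=cfg_r,
            )
        )
    return pairs


def replace_bodyweight(model: PlanarModel, bodyweight: float) -> PlanarModel:
    """Shallow copy of the model with a different bodyweight."""
    return PlanarModel(
        muscles=model.muscles,
        groups=model.groups,
        bodyweight_newtons=bodyweight,
        curves=model.curves,
        dofs=model.dofs,
    )
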