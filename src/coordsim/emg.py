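"""Surface-EMG envelope processing and the plantarflexor biofeedback metric.

Linear envelopes follow the standard pipeline: 30-500 Hz 4th-order
zero-phase Butterworth bandpass, full-wave rectification, 6 Hz 4th-order
zero-phase Butterworth lowpass, then normalization by the per-muscle
maximum recorded across maximum voluntary contraction (MVC) trials. A
40 ms electromechanical delay is applied before envelopes are compared
with, or used to constrain, simulated activations.

The biofeedback metric is the activation ratio: the stance-averaged
gastrocnemius envelope divided by the sum of stance-averaged gastrocnemius
and soleus envelopes. The adaptive feedback target is either a 15%
reduction from baseline or the reduction achieved in the previous trial,
whichever is greater.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

BANDPASS_HZ = (30.0, 500.0)
LOWPASS_HZ = 6.0
FILTER_ORDER = 4
DEFAULT_DELAY_S = 0.040
MIN_TARGET_REDUCTION = 0.15


@dataclass
class EMGRecording:
    """Raw multi-channel surface EMG, mV, at sampling rate ``fs`` Hz."""

    channels: dict[str, np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        for name, x in self.channels.items():
            x = np.asarray(x, dtype=float)
            if not np.all(np.isfinite(x)):
                raise ValueError(f"channel {name!r} has non-finite samples")
            self.channels[name] = x


@dataclass
class EnvelopeSeries:
    """Nonnegative EMG linear envelopes (raw units or fraction of MVC)."""

    channels: dict[str, np.ndarray]
    fs: float
    delay_applied: float = 0.0
    normalized: bool = False


@dataclass(frozen=True)
class FeedbackState:
    """Biofeedback bookkeeping across trials."""

    baseline_ratio: float
    baseline_gastroc: float
    current_target_reduction: float = MIN_TARGET_REDUCTION

    def __post_init__(self) -> None:
        if self.current_target_reduction < MIN_TARGET_REDUCTION:
            raise ValueError("target reduction may not fall below 15%")


def _bandpass_sos(fs: float):
    low, high = BANDPASS_HZ
    nyq = fs / 2.0
    if high >= nyq:
        high = 0.99 * nyq
        warnings.warn(
            f"bandpass upper edge clamped to {high:.0f} Hz (fs={fs:.0f} Hz)",
            stacklevel=3,
        )
    return butter(FILTER_ORDER, [low, high], btype="band", fs=fs, output="sos")


def _lowpass_sos(fs: float):
    return butter(FILTER_ORDER, LOWPASS_HZ, btype="low", fs=fs, output="sos")


def compute_envelope(rec: EMGRecording, channel: str | None = None) -> EnvelopeSeries:
    """Linear envelope: bandpass, rectify, lowpass (all zero-phase).

    Processes all channels unless ``channel`` names one. The result is
    clipped at zero (the zero-phase lowpass can undershoot slightly).
    """
    names = [channel] if channel is not None else list(rec.channels)
    sos_bp = _bandpass_sos(rec.fs)
    sos_lp = _lowpass_sos(rec.fs)
    # forward-backward filtering needs padding; 3x the (doubled) order each way
    padlen = 3 * (2 * FILTER_ORDER + 1)
    out = {}
    for name in names:
        x = rec.channels[name]
        if len(x) <= 2 * padlen:
            raise ValueError(
                f"channel {name!r}: {len(x)} samples too short for zero-phase "
                f"filtering (need > {2 * padlen})"
            )
        band = sosfiltfilt(sos_bp, x)
        env = sosfiltfilt(sos_lp, np.abs(band))
        out[name] = np.maximum(env, 0.0)
    return EnvelopeSeries(channels=out, fs=rec.fs)


def normalize_mvc(env: EnvelopeSeries, mvc_envelopes: dict[str, float | np.ndarray]) -> EnvelopeSeries:
    """Divide each channel by its scalar MVC maximum.

    ``mvc_envelopes`` maps channel -> MVC envelope series (its max is used)
    or directly to a scalar maximum. Values above 1 are kept (MVC
    under-estimation is common) but trigger a warning above 1.5.
    """
    out = {}
    for name, x in env.channels.items():
        mvc = mvc_envelopes[name]
        mvc_max = float(np.max(mvc)) if np.ndim(mvc) else float(mvc)
        if mvc_max <= 0:
            raise ValueError(f"channel {name!r}: MVC maximum must be positive")
        y = x / mvc_max
        if np.max(y, initial=0.0) > 1.5:
            warnings.warn(
                f"channel {name!r}: normalized envelope exceeds 1.5 of MVC",
                stacklevel=2,
            )
        out[name] = y
    return EnvelopeSeries(out, env.fs, env.delay_applied, normalized=True)


def apply_delay(env: EnvelopeSeries, delay: float = DEFAULT_DELAY_S) -> EnvelopeSeries:
    """Shift envelopes later by an electromechanical delay (seconds).

    The leading edge is held at the first sample value.
    """
    if delay < 0:
        raise ValueError("delay must be nonnegative")
    shift = int(round(delay * env.fs))
    out = {}
    for name, x in env.channels.items():
        if shift >= len(x):
            raise ValueError(f"delay of {shift} samples exceeds signal length")
        if shift == 0:
            out[name] = x.copy()
        else:
            out[name] = np.concatenate([np.full(shift, x[0]), x[:-shift]])
    return EnvelopeSeries(
        out, env.fs, env.delay_applied + shift / env.fs, env.normalized
    )


def activation_ratio(
    gastroc_env: np.ndarray, soleus_env: np.ndarray,
    stance_mask: np.ndarray | None = None,
) -> float:
    """Gastrocnemius-to-soleus activation ratio, g / (g + s).

    ``g`` and ``s`` are the stance-phase means of the (normalized)
    envelopes.
    """
    g = np.asarray(gastroc_env, dtype=float)
    s = np.asarray(soleus_env, dtype=float)
    if stance_mask is not None:
        mask = np.asarray(stance_mask, dtype=bool)
        if not mask.any():
            raise ValueError("stance mask selects no samples")
        g = g[mask]
        s = s[mask]
    gm = float(np.mean(g))
    sm = float(np.mean(s))
    if gm + sm <= 0:
        raise ZeroDivisionError("activation ratio undefined: zero envelopes")
    return gm / (gm + sm)


def framewise_ratio(gastroc_env: np.ndarray, soleus_env: np.ndarray,
                    denom_floor: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample ratio g/(g+s) and a mask where the denominator is usable."""
    g = np.asarray(gastroc_env, dtype=float)
    s = np.asarray(soleus_env, dtype=float)
    denom = g + s
    mask = denom >= denom_floor
    ratio = np.full_like(g, np.nan)
    ratio[mask] = g[mask] / denom[mask]
    return ratio, mask


def update_feedback_target(state: FeedbackState, achieved_reduction: float) -> FeedbackState:
    """Adaptive target: max(15%, the reduction achieved last trial)."""
    if not np.isfinite(achieved_reduction):
        raise ValueError("achieved_reduction must be finite")
    new = max(MIN_TARGET_REDUCTION, float(achieved_reduction))
    return replace(state, current_target_reduction=new)


def stance_mask_from_grf(grf_vertical: np.ndarray, threshold_n: float = 20.0) -> np.ndarray:
    """Foot-contact mask from vertical ground reaction force."""
    return np.asarray(grf_vertical, dtype=float) >= threshold_n
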