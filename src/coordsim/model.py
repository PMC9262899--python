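"""Simplified sagittal-plane lower-limb musculoskeletal model.

Three degrees of freedom (hip flexion, knee flexion, ankle plantarflexion;
moments positive in those directions) are actuated by ~14 lumped
musculotendon units. Each muscle's moment arm about each DOF is a low-order
polynomial in that joint's angle, and its MTU length follows from the
virtual-work relation r_j(q) = -dl_mtu/dq_j, integrated analytically from a
reference posture (all joints at zero).

Knee contact force bookkeeping uses a constant per-muscle axial projection
coefficient: the fraction of the muscle's tensile force transmitted as
compression along the tibia's longitudinal axis at the knee. Constant
coefficients keep the muscle-group decomposition an exact superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hill import CurveSet, DEFAULT_CURVES, MusculotendonParams

DOFS = ("hip_flexion", "knee_flexion", "ankle_plantarflexion")

#: Documented 75%-of-stance sagittal posture (rad): slight hip extension,
#: moderate knee flexion, ankle dorsiflexion — late-stance push-off.
POSTURE_75_STANCE = {
    "hip_flexion": -0.10,
    "knee_flexion": 0.30,
    "ankle_plantarflexion": -0.15,
}

#: Muscles whose knee-flexion moment arms enter the hamstrings:gastrocnemius
#: weighted moment-arm comparison.
HAMSTRINGS_MA_GROUP = ("bflh", "bfsh", "semiten", "semimem")
GASTROC_MA_GROUP = ("gasmed", "gaslat")

#: Weighted hamstrings-to-gastrocnemius knee flexion moment-arm ratio the
#: default fixture is calibrated to at the 75%-stance posture.
HAMSTRING_GASTROC_MA_RATIO = 1.7


class InfeasiblePostureError(ValueError):
    """MTU length at the requested posture fell below tendon slack length."""


@dataclass(frozen=True)
class MusclePath:
    """Geometry of one muscle: moment-arm polynomials and reference length.

    ``dof_moment_arms`` maps DOF name -> polynomial coefficients
    ``(r0, r1, r2)`` so that ``r(q) = r0 + r1 q + r2 q**2`` in meters
    (flexor/plantarflexor positive). ``knee_axial_coeff`` is the constant
    projection of muscle force onto the tibia long axis.
    """

    muscle: str
    dof_moment_arms: dict[str, tuple[float, float, float]]
    l_mtu_ref: float
    knee_axial_coeff: float = 0.0

    def moment_arm(self, dof: str, q: float) -> float:
        coeffs = self.dof_moment_arms.get(dof)
        if coeffs is None:
            return 0.0
        r0, r1, r2 = coeffs
        return r0 + r1 * q + r2 * q * q

    def length_change(self, dof: str, q: float) -> float:
        """-integral of r(q') dq' from 0 to q (shortening positive arm)."""
        coeffs = self.dof_moment_arms.get(dof)
        if coeffs is None:
            return 0.0
        r0, r1, r2 = coeffs
        return -(r0 * q + r1 * q * q / 2.0 + r2 * q**3 / 3.0)


@dataclass
class PlanarModel:
    """Sagittal lower-limb model: muscles, geometry, groups, bodyweight."""

    muscles: list[tuple[MusculotendonParams, MusclePath]]
    groups: dict[str, tuple[str, ...]]
    bodyweight_newtons: float = 700.0
    curves: CurveSet = field(default_factory=lambda: DEFAULT_CURVES)
    dofs: tuple[str, ...] = DOFS

    @property
    def muscle_names(self) -> list[str]:
        return [p.name for p, _ in self.muscles]

    def params(self, name: str) -> MusculotendonParams:
        for p, _ in self.muscles:
            if p.name == name:
                return p
        raise KeyError(name)

    def path(self, name: str) -> MusclePath:
        for _, path in self.muscles:
            if path.muscle == name:
                return path
        raise KeyError(name)

    def mtu_length(self, muscle: str, q: dict[str, float]) -> float:
        """MTU length at posture ``q`` (rad per DOF), meters."""
        p = self.params(muscle)
        path = self.path(muscle)
        l = path.l_mtu_ref
        for dof in self.dofs:
            l += path.length_change(dof, q.get(dof, 0.0))
        if l <= p.l_s_t:
            raise InfeasiblePostureError(
                f"{muscle}: MTU length {l:.4f} m <= slack length at posture {q}"
            )
        return l

    def moment_arm_matrix(self, q: dict[str, float]) -> np.ndarray:
        """(nDOF x nMuscles) moment arms at posture ``q``, meters."""
        out = np.zeros((len(self.dofs), len(self.muscles)))
        for j, dof in enumerate(self.dofs):
            for i, (_, path) in enumerate(self.muscles):
                out[j, i] = path.moment_arm(dof, q.get(dof, 0.0))
        return out

    def knee_axial_coeffs(self) -> np.ndarray:
        return np.array([path.knee_axial_coeff for _, path in self.muscles])

    def weight_vector(self, gastroc_weight: float = 1.0) -> np.ndarray:
        """Per-muscle objective weights; gastrocnemius heads get the penalty."""
        gastroc = set(self.groups.get("gastrocnemius", ()))
        return np.array(
            [gastroc_weight if n in gastroc else 1.0 for n in self.muscle_names]
        )


def _ref_length(params: MusculotendonParams) -> float:
    """Reference-posture MTU length putting the fiber at optimal length."""
    return params.l_s_t + params.l_o_m * np.cos(params.alpha_o)


# Fixture parameter table. Optimal forces, fiber lengths and slack lengths
# are literature-plausible lumped values for an adult male lower limb; they
# are fixture constants of this package, not measured quantities.
# columns: f_o_m [N], l_o_m [m], l_s_t [m], alpha_o [rad]
_FIXTURE_PARAMS = {
    "iliopsoas":  (2000.0, 0.11, 0.10, 0.20),
    "glutei":     (2700.0, 0.16, 0.07, 0.25),
    "recfem":     (1200.0, 0.08, 0.35, 0.20),
    "vasmed":     (2600.0, 0.10, 0.20, 0.40),
    "vaslat":     (2800.0, 0.10, 0.22, 0.32),
    "bflh":       (1300.0, 0.10, 0.33, 0.20),
    "bfsh":       (560.0,  0.11, 0.11, 0.25),
    "semiten":    (410.0,  0.19, 0.25, 0.22),
    "semimem":    (1700.0, 0.07, 0.35, 0.26),
    "gasmed":     (1600.0, 0.06, 0.40, 0.30),
    "gaslat":     (700.0,  0.06, 0.38, 0.21),
    "soleus":     (3600.0, 0.045, 0.28, 0.49),
    "tibant":     (900.0,  0.07, 0.24, 0.17),
    "tfl":        (400.0,  0.10, 0.45, 0.05),
}

# Moment-arm polynomials (m), flexor/plantarflexor-positive, as (r0, r1, r2)
# in the joint angle (rad). Hamstring knee arms are rescaled at fixture
# construction to satisfy the weighted moment-arm ratio constraint.
_FIXTURE_ARMS = {
    "iliopsoas": {"hip_flexion": (0.035, 0.0, 0.0)},
    "glutei":    {"hip_flexion": (-0.055, 0.0, 0.0)},
    "recfem":    {"hip_flexion": (0.040, 0.0, 0.0),
                  "knee_flexion": (-0.042, 0.012, 0.0)},
    "vasmed":    {"knee_flexion": (-0.043, 0.012, 0.0)},
    "vaslat":    {"knee_flexion": (-0.043, 0.012, 0.0)},
    "bflh":      {"hip_flexion": (-0.055, 0.0, 0.0),
                  "knee_flexion": (0.028, 0.010, 0.0)},
    "bfsh":      {"knee_flexion": (0.027, 0.010, 0.0)},
    "semiten":   {"hip_flexion": (-0.050, 0.0, 0.0),
                  "knee_flexion": (0.040, 0.012, 0.0)},
    "semimem":   {"hip_flexion": (-0.050, 0.0, 0.0),
                  "knee_flexion": (0.034, 0.010, 0.0)},
    "gasmed":    {"knee_flexion": (0.017, 0.004, 0.0),
                  "ankle_plantarflexion": (0.048, 0.0, 0.0)},
    "gaslat":    {"knee_flexion": (0.015, 0.004, 0.0),
                  "ankle_plantarflexion": (0.046, 0.0, 0.0)},
    "soleus":    {"ankle_plantarflexion": (0.050, 0.0, 0.0)},
    "tibant":    {"ankle_plantarflexion": (-0.040, 0.0, 0.0)},
    "tfl":       {"hip_flexion": (0.025, 0.0, 0.0),
                  "knee_flexion": (-0.008, 0.0, 0.0)},
}

# Constant projection of muscle force onto the tibia long axis at the knee.
# Zero for muscles that do not cross the knee.
_FIXTURE_AXIAL = {
    "recfem": 0.75, "vasmed": 0.75, "vaslat": 0.75,
    "bflh": 0.90, "bfsh": 0.90, "semiten": 0.90, "semimem": 0.90,
    "gasmed": 0.92, "gaslat": 0.92,
    "tfl": 0.30,
}

#: Functional muscle groups used for the knee-load decomposition and the
#: coordination objectives.
_FIXTURE_GROUPS = {
    "quadriceps": ("vasmed", "vaslat", "recfem"),
    "hamstrings": ("bflh", "bfsh", "semiten", "semimem"),
    "gastrocnemius": ("gasmed", "gaslat"),
    "tensor_fascia_latae": ("tfl",),
    "soleus": ("soleus",),
    "other": ("iliopsoas", "glutei", "tibant"),
}


def _weighted_knee_arm(model_arms, params, names, q_knee):
    num = 0.0
    den = 0.0
    for n in names:
        r0, r1, r2 = model_arms[n]["knee_flexion"]
        r = r0 + r1 * q_knee + r2 * q_knee**2
        f = params[n][0]
        num += f * r
        den += f
    return num / den


def default_fixture(bodyweight_newtons: float = 700.0) -> PlanarModel:
    """Packaged 14-muscle sagittal model.

    Hamstring knee-flexion moment arms are scaled at construction so the
    optimal-force-weighted hamstrings:gastrocnemius knee flexion moment-arm
    ratio at the 75%-stance posture equals ``HAMSTRING_GASTROC_MA_RATIO``.
    """
    arms = {m: dict(d) for m, d in _FIXTURE_ARMS.items()}
    qk = POSTURE_75_STANCE["knee_flexion"]
    ham = _weighted_knee_arm(arms, _FIXTURE_PARAMS, HAMSTRINGS_MA_GROUP, qk)
    gas = _weighted_knee_arm(arms, _FIXTURE_PARAMS, GASTROC_MA_GROUP, qk)
    scale = HAMSTRING_GASTROC_MA_RATIO * gas / ham
    for n in HAMSTRINGS_MA_GROUP:
        r0, r1, r2 = arms[n]["knee_flexion"]
        arms[n]["knee_flexion"] = (r0 * scale, r1 * scale, r2 * scale)

    muscles = []
    for name, (f_o, l_o, l_s, a_o) in _FIXTURE_PARAMS.items():
        p = MusculotendonParams(name, f_o, l_o, l_s, a_o)
        path = MusclePath(
            muscle=name,
            dof_moment_arms=arms[name],
            l_mtu_ref=_ref_length(p),
            knee_axial_coeff=_FIXTURE_AXIAL.get(name, 0.0),
        )
        muscles.append((p, path))

    return PlanarModel(
        muscles=muscles,
        groups=dict(_FIXTURE_GROUPS),
        bodyweight_newtons=bodyweight_newtons,
    )


def weighted_knee_moment_arm_ratio(model: PlanarModel, q=None) -> float:
    """Optimal-force-weighted hamstrings:gastrocnemius knee moment-arm ratio."""
    if q is None:
        q = POSTURE_75_STANCE
    qk = q["knee_flexion"]

    def group_arm(names):
        num = den = 0.0
        for n in names:
            p = model.params(n)
            num += p.f_o_m * model.path(n).moment_arm("knee_flexion", qk)
            den += p.f_o_m
        return num / den

    return group_arm(HAMSTRINGS_MA_GROUP) / group_arm(GASTROC_MA_GROUP)
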