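# Methods

## Musculotendon model

Each musculotendon unit (MTU) is a contractile fiber in series with an
elastic tendon, parametrized by maximum isometric force `F_o^m` (N),
optimal fiber length `l_o^m` (m), tendon slack length `l_s^t` (m) and
pennation at optimal length `α_o` (rad). Fiber length at each timestep
solves the static tendon–fiber equilibrium using the MTU length of the
current frame and the activation of the previous frame; MTU force is then
affine in the current activation, which is what makes the per-frame
redundancy problem a convex QP.

The dimensionless characteristic curves are smooth analytic surrogates of
the standard muscle curves, chosen so that solver behavior depends only on
their qualitative properties (all C1; the exact control-point shapes of
published digitized curves are not reproduced):

- tendon: `f^T(x) = k_1 (e^{k_2(x−1)} − 1 − k_2(x−1))` for `x = l^t/l_s^t > 1`,
  zero below; `k_2 = 30` and `k_1` normalized so the tendon carries `F_o^m`
  at 4.9% strain (a standard nominal tendon strain);
- active fiber: a two-term Gaussian sum centred at the optimal length,
  `0.8·e^{−(x−1)²/0.15} + 0.2·e^{−(x−1)²/0.8}`, maximum 1 at `x = 1`;
- passive fiber: same exponential form as the tendon with `k_2 = 5`,
  reaching 1 at 60% strain, zero below optimal length.

Pennation follows the fixed-height model `α(l^m) = asin(l_o^m sin α_o / l^m)`,
capped at 84° to avoid the singularity as fibers shorten. Newton's method
runs to an absolute residual below `1e−8·F_o^m` (max 50 iterations,
initialized from the previous frame's fiber length, or a rigid-tendon
estimate on the first frame), with a bracketed bisection fallback on
`[0.3, 1.8]·l_o^m`. With zero activation and a slack tendon the
equilibrium is degenerate (a continuum of zero-force states); the
rigid-tendon geometry is taken as the canonical state. Newton tolerance
and iteration cap are implementation choices. The force–velocity property
is intentionally absent: with a compliant tendon, plantarflexor fibers
operate near-isometrically during stance, and including tendon compliance
while omitting force–velocity reproduces plantarflexor EMG timing better
than the converse.

## Sagittal-plane model fixture

The packaged model has three DOFs (hip flexion, knee flexion, ankle
plantarflexion; those moments positive) and 14 lumped muscles: iliopsoas,
glutei (lumped), rectus femoris, two vasti lumps, biceps femoris long and
short heads, semitendinosus, semimembranosus, medial and lateral
gastrocnemius, soleus, tibialis anterior, and tensor fascia latae. Moment
arms are ≤ 2nd-order polynomials in the spanned joint's angle; MTU length
integrates `−r_j(q)` analytically from the reference posture (all joints
at zero, every fiber at optimal length), so the virtual-work identity
`r = −∂l/∂q` holds exactly. Optimal forces, fiber lengths, slack lengths,
pennations and moment-arm coefficients are literature-plausible lumped
values for an adult male limb; they are fixture constants of this package,
not subject measurements.

Two constraints are imposed on the fixture by construction: (i) the
functional muscle groups used for knee-load decomposition (quadriceps,
hamstrings, gastrocnemius, tensor fascia latae, plus soleus and a
non-knee "other" group), and (ii) the optimal-force-weighted
hamstrings-to-gastrocnemius knee flexion moment-arm ratio at a documented
75%-of-stance posture (hip −0.10, knee 0.30, ankle −0.15 rad), set to 1.7
by scaling the hamstring knee-arm polynomials once at fixture build. This
ratio is the mechanical reason a hamstrings-for-gastrocnemius substitution
lowers knee load.

Knee contact force along the tibia axis uses a constant per-muscle axial
projection coefficient (quadriceps 0.75 via the extensor mechanism,
hamstrings 0.90, gastrocnemius 0.92, TFL 0.30, soleus 0). A constant
coefficient keeps the group decomposition an exact superposition; posture
dependence of the projection is a known simplification. The
intersegmental axial force is an input series, not recomputed from 3D
dynamics.

## Redundancy solver

Per frame: minimize `Σ w_i a_i²` (+ heavily penalized reserve torques)
subject to linear moment-matching constraints, bounds `0 ≤ a ≤ 1`, and
optionally the EMG ratio constraint. The avoidance objective uses weight
100 on both gastrocnemius heads. The QP is solved with SLSQP followed by
an exact KKT re-solve on the identified active set, which drives moment
residuals to machine precision and makes repeated solves bit-identical.
Reserve torques (one ideal torque per DOF, penalty 1000 on
`(reserve/100 N·m)²`) are pinned to zero first and only released if the
muscle-only problem is infeasible, so well-posed trials carry exactly zero
reserve. Moment equality is enforced to 1e−6 N·m (the solver typically
achieves ~1e−12); whether the original implementation used equality or a
toleranced constraint is unknown, so equality is our choice.

The ratio constraint `|g/(g+s) − r| ≤ 0.02` is rewritten exactly as two
linear inequalities valid when `g + s > 0`, guaranteed by a 1e−6 lower
activation bound on enforced frames; a 1e−7 margin is subtracted from the
tolerance so floating-point polish cannot overshoot the stated bound. The
constraint is enforced separately for each gastrocnemius head against the
soleus, only during stance and only where the delayed gastrocnemius plus
soleus envelopes exceed 0.01 of MVC (the ratio is ill-conditioned when
both are silent). Activation history threads sequentially; the first frame
is solved from rest and re-solved once warm-started with its own
activations.

A brute-force grid oracle (exhaustive search over the activation box,
≤ 4 muscles, ≤ 2 DOFs) provides an independent check of the QP on toy
problems; its feasibility tolerance is half a grid step through the
highest-gain muscle, the finest moment increment the grid can realize.

## EMG processing

Band-pass 30–500 Hz and low-pass 6 Hz, both 4th-order zero-phase
Butterworth (applied forward–backward via second-order sections, so the
magnitude response is effectively 8th-order; reflective padding of 3× the
doubled filter order — padding is unspecified in standard descriptions
and is our choice). Rectification between the two filters. MVC
normalization divides by the scalar maximum of the same pipeline applied
to MVC recordings; values above 1 are kept and logged (warning above
1.5). The 40 ms electromechanical delay shifts envelopes later by
`round(0.040·fs)` samples with the leading edge held. Sampling rates at
or below 1 kHz clamp the band-pass edge to 0.99× Nyquist with a warning.
Stance events come from a 20 N vertical-GRF threshold when GRF is
present, else are supplied explicitly. The adaptive biofeedback target is
`max(0.15, achieved reduction)`.

## Synthetic data generator

The generator defines the study conditions for all tests: one 1.1 s gait
cycle at 100 Hz, 60% stance, 700 N bodyweight, sagittal kinematics built
from smooth periodic (von Mises-shaped) profiles, and per-muscle
ground-truth activations as periodic bumps whose phasing follows the
normative dominance pattern (hamstrings first 10% of stance, quadriceps
10–40%, plantarflexors 40–90%). Bump amplitudes were chosen once to give
physiological activation levels (peak soleus ≈ 0.5, gastrocnemius ≈ 0.4,
vasti ≈ 0.3) and, through them, a normative peak KCF in the 2–4 BW range
with a 50–75% muscle share. Joint moments are computed *from* the truth
through the same musculotendon model (forward consistency), so generated
moments are exactly achievable and solved trials need no reserves. The
intersegmental axial force is a smooth double-bump profile peaking near
0.9 BW; its exact shape is a design choice, not a measured trace.

Raw EMG per channel is the truth activation (advanced by the 40 ms delay,
so that envelope processing plus delay re-aligns with the truth)
multiplying band-limited (30–450 Hz) Gaussian carrier noise scaled to
unit rectified mean, plus a 0.008 additive sensor-noise floor; MVC
recordings use a constant unit modulator over 4 s. The retention preset
scales the gastrocnemius truth by 0.6 and solves for the soleus scale
that reduces the ground-truth activation ratio by exactly 25%. Cohorts
jitter bodyweight (±10%) and bump amplitudes (±8%) from a single seeded
generator.

Because the redundancy problem is degenerate, raw activation recovery is
not expected and not asserted; recovery tests target moments, activation
ratios, envelopes and knee loading. What the synthetic data do not
emulate: measurement noise in kinematics/kinetics, soft-tissue artifact,
electrode crosstalk, inter-muscle electromechanical-delay differences,
kinematic changes between baseline and retention, and 3D load paths —
so passing tests demonstrate internal consistency and correct mechanics
of the pipeline, not validity on any human dataset.

## Problem sizes and numerical choices

Default analyses use one gait cycle of 110 frames, 14 muscles and a
6-subject synthetic cohort; each trial solve takes well under a second,
so the full analysis chain runs in seconds. Tie-breaks: identical
agonists split equally by strict convexity; the half-stance boundary for
P1/P2 assigns the middle stance sample to the late window. Degenerate
inputs (zero moments at the reference posture, silent EMG channels,
empty stance masks, postures that slacken an MTU below its tendon length)
either produce exact zeros or raise typed errors naming the muscle and
frame.

## Known limitations

Planar three-DOF geometry with polynomial moment arms; constant knee
axial projections; no force–velocity or activation dynamics; no
medial/lateral compartment split; intersegmental force taken as input;
cohort statistics are descriptive only (the cohort is synthetic, so
inferential tests would imply claims the data cannot support).
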