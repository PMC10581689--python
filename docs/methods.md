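# Methods

`hybridarm` models intuitive, movement-based control of a transhumeral
prosthesis evaluated in a virtual pick-and-place task. A user who retains only
the two proximal shoulder degrees of freedom (DoF) moves naturally toward a
goal; an artificial controller predicts the five missing distal joint angles
from the proximal angles plus the goal location, and the *hybrid arm* —
operator proximal + predicted distal — must bring the (virtual) hand into the
target zone. The package contains the full desk-scale pipeline: forward
kinematics, target-set generation, a synthetic movement generator, the
distal-joint predictor, the closed-loop task simulation and its evaluation
metrics.

## 1. Kinematic model

The arm is a 7-DoF chain rooted at the shoulder: shoulder flexion-extension
`s_fe`, shoulder ab-adduction `s_aa`, humeral rotation `h_r`, elbow
flexion-extension `e_fe`, forearm pronation-supination `f_ps`, wrist
flexion-extension `w_fe`, and radial-ulnar deviation `w_ru`. Segment lengths
are an `ArmMorphology` (defaults: upper arm 0.30 m, forearm 0.25 m,
wrist-to-hand-centre 0.08 m — adult 50th-percentile figures).

Conventions: the world frame has x anterior, y to the subject's left, z up;
the zero posture hangs along −z. Rotations are composed as
`R_u = Ry(−s_fe) · Rx(−s_aa) · Rz(−h_r)`,
`R_f = R_u · Ry(−e_fe) · Rz(−f_ps)`,
`R_h = R_f · Ry(−w_fe) · Rx(−w_ru)`, so positive `s_fe` swings the arm
forward and positive `e_fe` flexes the elbow forward at the zero posture.

A *hand location* is the 5-vector (x, y, z, incl, azim): hand-centre position
plus the spherical orientation of the hand axis (wrist → hand centre unit
vector). Inclination is measured from vertical (+z); azimuth about +z, defined
as exactly 0 on the vertical axis to keep the representation continuous there.
Hand orientation uses 2 angles rather than 3 because the pick-and-place task
only constrains the pointing axis of the hand, not roll about it.

Left-side data are handled by an exact mirror symmetry: angle sign flips
(+1, −1, −1, +1, −1, +1, −1), location y → −y and azim → −azim (wrapped to
(−π, π]). Mirroring commutes with forward kinematics by construction, which
the test-suite verifies to 1e-9 on random postures.

## 2. Target generation

**ROM estimation** (`estimate_rom`): per-DoF min/max over a recorded sweep
session; the sweep generator articulates each DoF mid → max → min → mid in
turn. Elbow extension is additionally capped (the task is seated with the
trunk free, so full extension is never used): the estimated lower bound is
raised by a fixed safety margin.

**Plausible targets** (`sample_plausible_targets`): candidate postures are
drawn uniformly inside the ROM box and their hand locations kept only if all
three workspace filters pass: (a) hand axis within 80° of vertical (objects
are grasped roughly from above), (b) hand anterior of one third of the arm
length (in front of the trunk), (c) hand no lower than two thirds of the arm
length below the shoulder (above table height). Accepted targets are shuffled
and alternately assigned pick/place roles. The defaults produce exactly 300
targets.

**Possible targets** (`gng_fit` + `possible_targets`): a growing neural gas
(GNG) network is fitted to the user's own recorded postures (downsampled
10×), yielding a fixed budget of 200 nodes that tile the reachable posture
manifold; their forward-kinematics images become targets known to be
attainable by that user. The GNG implementation follows the classical
incremental algorithm (winner/second-winner adaptation, edge aging, error
accumulation, periodic insertion at the highest-error node) with one
modification: training always completes full passes over the data and
guarantees at least one adaptation pass even when the node budget is met at
initialization, so tiny budgets still converge to cluster centroids. Target
sequencing draws a random order, rejecting any consecutive pair whose centres
are closer than 0.20 m so every trial requires an actual reach.

## 3. Synthetic movement generator

The generator replaces motion capture of human subjects. It emulates:

- **Postural synergy**: for each goal the 7-DoF goal posture comes from an
  analytic inverse-kinematics model with a fixed swivel-angle parameterization
  (swivel 0.3 rad) of the elbow circle, plus a smooth periodic
  pronation-supination term `f_ps = 0.4 · sin(azim) · sin(incl)` so the
  distal DoFs vary smoothly and deterministically with the goal. This is the
  "natural coordination" a predictor is supposed to learn.
- **Movement kinematics**: joint trajectories between postures follow a
  minimum-jerk profile (10τ³ − 15τ⁴ + 6τ⁵), duration 1.3 s per reach,
  sampled at 90 Hz (typical VR headset rate).
- **Sensor noise**: i.i.d. Gaussian angle noise, SD 0.5°.
- **Session structure**: alternating pick-and-place reaches over a target
  list, with target-shown / validated / timeout events, starting from a rest
  posture.
- **Artifacts** (opt-in injection for testing the cleaning filters): tracking
  *freezing* (samples repeated for a duration ≥ 0.5 s) and *jumping*
  (inter-sample hand displacement > 0.01 m).

It does **not** emulate: trunk/scapular compensation, online visual-feedback
corrections (movements replay the nominal synergy open-loop), muscular
fatigue, inter-subject variability beyond morphology scaling, or grasping
itself (the task validates hand position/orientation only). These choices are
deliberate: the generator is the fixed experimental condition the rest of the
pipeline is measured against.

## 4. Distal-joint predictor

A multilayer perceptron maps 7 inputs (`s_fe`, `s_aa`, x, y, z, incl, azim) to
the 5 distal angles: layers 256 → 256 → dropout(0.5) → 64 → 5, ReLU hidden
activations, linear output. Inputs and outputs are z-scored with statistics
frozen from the training set; predictions are clipped to the training output
range. Training is mini-batch SGD with momentum on mean-squared error,
batch 64, with an optional geometric learning-rate schedule
(`lr × lr_decay^epoch`).

**Hand-location-as-target trick**: at training time the goal context fed to
the network is each sample's *own* hand location, as if every posture had
brought the hand onto a hypothetical target — target locations in a task are
sparse and clustered, whereas the hand location varies continuously along
whole trajectories, so the network becomes a smooth goal-conditioned
inverse-kinematics regressor. At run time the same input slots carry the
actual target location.

**Regimes**: the *Own* model trains on the user's own recordings. The
*Generic* model trains on donor recordings: donor angles are mirrored to the
user's side and donor hand locations are *remapped* — recomputed under the
user's morphology — because identical angles put the hand in different places
for different segment lengths; outputs remain the donors' original angles.

**Presets** (`PRESETS`): `own` (30 epochs, lr 1e-4, no momentum) and
`generic` (10 epochs, lr 1.59e-7, momentum 0.95) record the published
hyperparameters of the two regimes verbatim; their learning rates belong to
an unknown original feature scaling and are far too small for z-scored data,
so they are kept for provenance, not performance. The package `default`
(30 epochs, lr 0.01, momentum 0.95, lr_decay 0.93) was selected from a
convergence sweep under z-scoring and is what `fit()` uses when no
configuration is given.

The API follows the model/results convention: `DistalJointModel(x, y,
morph).fit(config)` returns a frozen `DistalJointResults` with weights,
normalisation statistics, diagnostics, `summary()`, `save()`/`load()`.

## 5. Closed-loop task phase

`run_closed_loop_phase` simulates one test phase: the simulated operator moves
naturally (synergy posture + minimum-jerk) toward each target and holds
there; at every 90 Hz sample only the operator's two proximal angles reach the
hybrid arm, whose five distal angles come from the model queried with the
*target* location. The trial succeeds at the first sample whose hybrid hand
location is inside the target zone (emulating the validation button), else it
times out (default limit 10 s). Tolerances: *hard* 2 cm / 5° and *relaxed*
4 cm / 10° (position error on the hand centre; angular error between hand
axes).

Note the operator replays the nominal synergy open-loop: it does not adjust
its proximal angles to compensate prediction error the way a human with
visual feedback does, so closed-loop success is bounded by model accuracy
alone. This is the main respect in which simulated success rates
underestimate what a human operator achieves with the same predictor.

## 6. Cleaning and metrics

`clean_trials` removes whole trials containing tracking artifacts: freezing
(identical consecutive samples spanning ≥ 0.5 s) or jumping (hand displacement
> 0.01 m between consecutive samples, i.e. > 0.9 m/s at 90 Hz), and reports
which trials were removed and why. Noise-free synthetic sessions are left
untouched.

Metrics (`phase_metrics`): success rate (% validated before timeout), median
movement time over successful trials (target shown → validation), and
*spread volume* — the volume, in dm³, of the minimum-volume enclosing
ellipsoid (MVEE) of the densest 90% of shoulder positions, a measure of
compensatory body motion. The 90% trim uses Mahalanobis distance to the cloud
mean; the MVEE is computed by the Khachiyan algorithm on the convex-hull
vertices of the kept points (duality-gap stopping rule, tolerance 1e-6).
Degenerate (rank-deficient) clouds yield volume 0 with a warning. The test
suite checks the implementation against an independent brute-force MVEE to
5%, plus rigid-motion invariance and cubic scaling.

## 7. Numerical choices

- All angles are radians internally; CSV/CLI boundaries use degrees where
  stated in the file headers.
- Azimuths are wrapped to (−π, π]; angular differences are compared on the
  circle.
- The IK rejects goals outside a [0.2, 0.98] × arm-length shell to stay away
  from the straight-arm singularity.
- RNGs are NumPy `default_rng` seeded explicitly everywhere; every generator,
  fit and simulation is reproducible from its seed. Derived seeds are offsets
  from the user seed.
- MLP weights use He initialization; dropout is inverted (scaled at train
  time) so inference is deterministic.

## 8. Parameters and defaults

| Parameter | Default | Rationale |
|---|---|---|
| morphology (upper arm, forearm, hand) | 0.30 / 0.25 / 0.08 m | adult 50th-percentile |
| sampling rate | 90 Hz | VR headset tracking rate |
| move duration | 1.3 s | natural reach duration |
| angle noise SD | 0.5° | optical tracking noise scale |
| swivel angle | 0.3 rad | comfortable elbow-drop posture |
| plausible targets | 300 | session of ~150 pick-place pairs |
| GNG nodes / possible targets | 200 | workspace tiling at ~5 cm scale |
| min consecutive separation | 0.20 m | forces an actual reach each trial |
| axis-verticality filter | ≤ 80° | overhead grasp plausibility |
| anterior filter | x > arm length / 3 | in front of trunk |
| height filter | −z ≤ 2/3 arm length | above table height |
| tolerance hard / relaxed | 2 cm, 5° / 4 cm, 10° | task difficulty levels |
| trial time limit | 10 s | generous timeout |
| freezing threshold | ≥ 0.5 s | distinguishes artifact from hold |
| jumping threshold | > 0.01 m/sample | > 0.9 m/s, physically implausible |
| spread-volume coverage | 90% | robust to outlier samples |
| training batch / dropout | 64 / 0.5 | fixed architecture choices |
| default training | 30 epochs, lr 0.01, momentum 0.95, decay 0.93 | convergence sweep under z-scoring |

## 9. Limitations

- The synthetic operator is open-loop; no error compensation, so simulated
  closed-loop success understates human-in-the-loop performance (see §5).
- With the fixed architecture — in particular the 0.5-dropout layer feeding a
  64-unit layer — SGD training plateaus with held-out per-DoF RMSE of several
  degrees even though the synthetic synergy map itself is deterministic;
  `scripts/acceptance.py` reports the exact figures for a given seed.
- The synergy IK is one fixed coordination strategy; real users show
  subject-specific and goal-dependent synergies.
- Morphology handles segment lengths only; no joint-centre offsets or
  soft-tissue effects.
- GNG hyperparameters (learning rates, edge aging, insertion cadence) follow
  common literature values and are not tuned per dataset.
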