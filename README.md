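# hybridarm

Movement-based transhumeral prosthesis control, evaluated in a simulated
pick-and-place task: goal-aware distal-joint prediction, workspace target
generation, synthetic movement synthesis and closed-loop task evaluation.

## The problem

A person with an amputation above the elbow retains only the two proximal
shoulder degrees of freedom (flexion-extension and ab-adduction) but needs
seven to place a hand on an object: humeral rotation, elbow flexion, forearm
pronation-supination and two wrist angles are missing. Able-bodied reaching is
highly coordinated — given where the hand must go and what the shoulder is
doing, the remaining joints are largely determined. *Movement-based* control
exploits this: an artificial controller observes the user's residual shoulder
motion plus the goal location and predicts the five distal joint angles,
so the *hybrid arm* (human proximal + predicted distal) reaches the target
while the user simply moves naturally.

## The model

- **Kinematics** (`hybridarm.kinematics`): a 7-DoF shoulder-rooted chain;
  hand state is a 5-vector (x, y, z position of the hand centre plus
  inclination/azimuth of the hand axis); exact left/right mirror symmetry.
- **Targets** (`hybridarm.targets`): range-of-motion estimation from a sweep
  recording; *plausible* targets sampled uniformly in the ROM and filtered by
  three workspace criteria; *possible* targets obtained by fitting a growing
  neural gas to the user's own postures and sequenced with a minimum 20 cm
  separation between consecutive targets.
- **Controller** (`hybridarm.controller`): an MLP (256-256-dropout-64) maps
  (shoulder angles, goal location) to the five distal angles, trained with the
  hand-location-as-target trick on continuous recordings; *Own* and *Generic*
  (donor-data, morphology-remapped) regimes.
- **Movement synthesis** (`hybridarm.synthmove`): synergy-based inverse
  kinematics plus minimum-jerk profiles generate realistic 90 Hz sessions, the
  package's substitute for human motion capture.
- **Task evaluation** (`hybridarm.taskeval`): closed-loop pick-and-place
  simulation with hard (2 cm, 5°) and relaxed (4 cm, 10°) tolerances,
  artifact cleaning (freezing/jumping), success rate, movement time and
  shoulder spread volume (minimum-volume enclosing ellipsoid).

See [docs/methods.md](docs/methods.md) for conventions, parameters and
limitations.

## Tests

```sh
python -m pytest -q tests/
```

The suite contains unit and property-based tests per module plus
`tests/test_acceptance.py`, one test per end-to-end acceptance criterion.
Criterion 6 (held-out per-DoF RMSE < 5° and ≥ 95% closed-loop success with
the default training configuration) currently **fails** and is left failing
deliberately: with the fixed network architecture the training plateaus a few
degrees above the bar, and the simulated operator replays its natural
movement open-loop without compensating prediction errors the way a human
with visual feedback does. `docs/methods.md` §9 discusses this.

## Worked example

```python
import numpy as np

from hybridarm import ArmMorphology, Tolerance
from hybridarm.cli import default_rom_bounds
from hybridarm.controller import DistalJointModel, build_training_pairs
from hybridarm.synthmove import SynergyParams, generate_rom_sweep_session, generate_session
from hybridarm.targets import estimate_rom, sample_plausible_targets
from hybridarm.taskeval import run_closed_loop_phase, success_rate

morph = ArmMorphology(upper_arm_len=0.30, forearm_len=0.25, hand_len=0.08)

# 1. calibrate the range of motion from a synthetic sweep recording
sweep = generate_rom_sweep_session(default_rom_bounds(), morph, seed=0)
rom = estimate_rom(sweep)
print("elbow range (deg):", np.degrees(rom.bounds[3]).round(1))

# 2. sample workspace-plausible targets and record a pick-and-place session
targets = sample_plausible_targets(rom, morph, n=100, seed=1)
session = generate_session(targets, morph, SynergyParams(), seed=2)
print("session:", session.angles.shape[0], "samples at", session.rate, "Hz")

# 3. train the distal-joint predictor on (proximal angles, hand location) pairs
x, y = build_training_pairs(session)
idx = np.random.default_rng(9).permutation(x.shape[0])
train, test = idx[:10_000], idx[10_000:]
fitted = DistalJointModel(x[train], y[train], morph).fit()
print("held-out per-DoF RMSE (deg):", np.degrees(fitted.rmse(x[test], y[test])).round(2))

# 4. simulate a closed-loop test phase at relaxed tolerance
eval_targets = sample_plausible_targets(rom, morph, n=50, seed=7)
trials = run_closed_loop_phase(fitted, eval_targets, morph, Tolerance.relaxed(), seed=11)
print(f"closed-loop success: {success_rate(trials):.0f}%")
```

Output:

```
elbow range (deg): [ 25.2 145.8]
session: 11601 samples at 90.0 Hz
held-out per-DoF RMSE (deg): [2.12 3.96 1.66 5.09 3.15]
closed-loop success: 52%
```

The five RMSE columns are humeral rotation, elbow flexion-extension, forearm
pronation-supination, wrist flexion-extension and radial-ulnar deviation.

## Command line

Every pipeline stage is also a `hybridarm` subcommand operating on CSV/JSON
files with YAML provenance sidecars:

```sh
hybridarm synth rom-sweep --seed 0 --out sweep.csv
hybridarm estimate-rom --session sweep.csv --out rom.yaml
hybridarm gen-plausible --rom rom.yaml -n 300 --seed 1 --out plausible.csv
hybridarm synth session --targets plausible.csv --seed 2 --out session.csv
hybridarm fit-gng --session session.csv --n-nodes 200 --seed 3 --out nodes.csv
hybridarm gen-possible --nodes nodes.csv --seed 4 --out possible.csv
hybridarm train --session session.csv --preset default --out model.json
hybridarm simulate --model model.json --targets possible.csv --tolerance relaxed \
    --out trials.json --session-out hybrid_session.csv
hybridarm evaluate --results trials.json --session hybrid_session.csv --out metrics.json
```

Morphology defaults to the built-in adult figures; pass `--morphology
morph.json` to override. Each output carries a YAML provenance sidecar
recording the command, inputs and seed.

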