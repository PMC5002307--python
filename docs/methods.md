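# Methods

## Model

`vpcsim` simulates the online recruitment of visual place cells (VPCs)
from landmark percepts. The pipeline per location-update step is:

1. **Move.** The agent advances `speed · dt` along its heading. Speed is
   redrawn uniformly on `(0, v_max]` each period (constant within a
   period). At a wall the path reflects specularly — the normal velocity
   component is negated, the tangential one preserved; corner hits are
   handled by folding the x and y coordinates independently into the
   arena (a triangle-wave fold), which composes both reflections
   deterministically.
2. **Perceive.** Every landmark whose Euclidean distance lies in the
   closed annulus `[d_min, d_max]` is perceived with its id, saliency,
   allocentric bearing (degrees clockwise from north) and distance. The
   resulting set is the place code. The annulus endpoints are included;
   an empty place code is valid.
3. **Fire.** Each recruited cell evaluates the Gaussian similarity
   between its memorized place code and the current one (formula in the
   README). Landmarks are matched by id equality. Bearing differences are
   wrapped to [−180°, 180°] before squaring, so a small physical rotation
   across north stays small. With no matched landmark the rate is 0; at
   the exact recruitment percept it is exactly 1. Rates always lie in
   [0, 1].
4. **Recruit.** If the maximal rate (winner; ties to the lowest cell id)
   is strictly below FRT, or no cell exists, the current place code is
   memorized by a new cell. Empty percepts never recruit — they carry no
   location information and the saliency normalization is undefined for
   them.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `width`, `height` | m | 40, 40 | arena dimensions |
| `n_landmarks` | – | 100 | uniformly random landmark positions |
| `saliency_mode` | – | `equal` | all saliencies 1; `uniform_random` draws (0, 1] |
| `d_min`, `d_max` | m | 10, 15 | recognition annulus (closed) |
| `v_max` | m/s | 5 | maximal running speed |
| `dt` | s | 1 | location-update period |
| `n_steps` | – | 4000 | updates per exploration |
| `sigma_d2` | m² | 25 | distance AFFF (σ_d = 5 m) |
| `sigma_theta2` | deg² | 100 | bearing AFFF (σ_θ = 10°) |
| `w_d`, `w_theta` | {0,1} | 1, 1 | enable distance / bearing terms |
| `frt` | – | 0.2 | firing-rate threshold for recruitment |
| `resolution` | m | 0.5 | rate-map bin size (80×80 bins at default arena) |
| `heading_policy` | – | `wander` | free-space turning rule |

Defaults are the baseline study conditions of the experiment the
simulator reproduces.

σ_θ² is interpreted in squared **degrees**: σ_θ² = 100 means a 10°
angular tuning width, a plausible bearing sensitivity at 10–15 m range
(a radians² reading would make the orientation term vacuous).

## Design choices

- **Heading policy.** The boundary rule (specular reflection) is part of
  the model; the free-space turning rule is not specified by it. The
  default `wander` perturbs the heading each period by a turn uniform on
  [−30°, +30°], which produces dense space-filling coverage; `uniform`
  (fresh heading each period) and `fixed` (heading changes only at
  walls) are selectable. The recruited-cell count is insensitive to the
  policy (±3 cells at baseline) because the count is governed by
  firing-field packing, not by how the space is traversed.
- **Saliency-weight normalization.** The weights `w_i` are normalized
  over the **current** percept (all N(t) landmarks), so currently
  visible landmarks unknown to a cell dilute the matched weights and
  depress the rate — scene change is penalized even where the matched
  geometry is perfect. `weight_normalization="matched"` (normalize over
  the matched subset only) is available for sensitivity analysis; at
  baseline it yields ~90 instead of ~120 cells.
- **Strict threshold.** "Winner below FRT" is strict (`<`): a winner at
  exactly FRT does not recruit.
- **Seeds.** A run's base seed deterministically derives one landmark
  seed and one trajectory seed (both < 2³¹), each overridable, so sweeps
  can hold the landmark layout fixed across parameter values within a
  replicate while varying the trajectory across replicates.
- **Rate maps.** Per-cell maps store the *mean* rate of the trajectory
  points in each bin; the population map takes the per-bin *maximum*
  across cells (the strongest responder). Unvisited bins are explicitly
  missing (NA), never zero: conflating "not visited" with "not firing"
  would corrupt field-area metrics. Points exactly on the north/east
  boundary fall into the last bin.

## What the synthetic world does and does not emulate

The generator produces uniformly random point landmarks with exact,
noise-free bearing/distance perception and perfect recognition. Real
visual front-ends add measurement noise, occlusion, misrecognition, and
highly non-uniform landmark density (some locations may perceive many
landmarks, others none). Passing tests therefore validate the
recruitment/firing dynamics under idealized perception, not robustness
of any image-processing pipeline — the perception stage is an interface,
and any provider of per-step place codes can replace the annulus rule.

## Numerical notes

- Firing rates are exact sums of `exp` terms; the self-recall rate is 1
  to ≤ 1e-12 because the weights sum to 1 by construction.
- Angle wrapping uses `((Δ + 180) mod 360) − 180`.
- A percept's landmark count at baseline averages ≈ 24 (annulus area
  ~393 m² × density 100/1600 m⁻²), dropping near walls.
- Simulation cost is O(n_steps × n_cells × percept size); the baseline
  run takes ~1.5 s on one core.

## Known limitations and sensitivities

- **The recruited-cell count is dominated by σ_θ².** At baseline
  (σ_θ = 10°) a bearing mismatch of ~9° — a ~2 m lateral displacement at
  12.5 m range — already halves a landmark's contribution, so firing
  fields are ~2.8 m in radius (~25 m²) and ~120 cells are needed to
  cover the 1600 m² arena (the recruitment rule guarantees coverage of
  everything visited). The count scales roughly inversely with field
  area: σ_θ² = 400 gives ~67 cells, σ_θ² = 900 gives ~49. Reported cell
  counts for this class of model are therefore only comparable when the
  angular units of σ_θ² are stated unambiguously.
- No forgetting or pruning: cells are never removed, and revisits never
  update memorized codes.
- No occlusion or perception noise (hooks would go in the perception
  provider); no kinematic vehicle model.
- The parameter-study assertions are qualitative orderings of replicate
  means (5 trajectories per condition), not estimates with confidence
  intervals.

## Problem sizes used by the test suite

Unit tests run on scaled-down configurations (≤ 500 steps). The
end-to-end suite runs the full baseline (4000 steps) over 10 seeds, a
4000-step coverage check, and four sweeps at 5 replicates each (FRT ×4
values, annulus ×3, AFFF ×2, exploration length ×5 up to 8000 steps),
about two minutes in total on one core. `scripts/acceptance.py` runs the
10-seed baseline (~20 s).
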