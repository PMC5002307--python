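# vpcsim

A simulator of **visual place cell (VPC) generation** for bio-inspired
navigation research. Hippocampal place cells fire only when an animal
occupies a restricted region of space; `vpcsim` models how such cells can
be *recruited online* from purely visual (allothetic) information while an
agent explores an arena, with no self-motion integration at all.

It is aimed at people studying landmark-based place coding, RatSLAM-style
bio-inspired SLAM, or novelty-triggered neuron recruitment, who want a
small, fully reproducible test bed for the firing-field / recruitment
dynamics.

## The model

At each location-update step the vehicle perceives the landmarks whose
distance lies in a recognition annulus `[d_min, d_max]`. Each perceived
landmark *i* contributes its recognition id `r_i`, saliency `s_i`,
allocentric bearing `θ_i` (degrees clockwise from north) and distance
`d_i`; the set of these tuples is the current **place code** `C(t)`.

Every recruited cell *k* has memorized the place code seen at its
recruitment step. Its firing rate at the current percept is a Gaussian
similarity measure over the **matched** landmarks (ids present in both
codes):

    f_k(t) = Σ_{i matched} w_i · exp( − [ w_d (d_i − d_i^k)² / σ_d²
                                        + w_θ Δθ_i² / σ_θ² ] )

    w_i = s_i / Σ_{j ∈ C(t)} s_j          (saliency weights)
    Δθ_i = bearing difference wrapped to [−180°, 180°]

`σ_d²` (m²) and `σ_θ²` (deg²) are the *adjustment factors of the firing
field* (AFFF): larger values widen the firing fields. `w_d, w_θ ∈ {0,1}`
switch the distance / bearing terms on or off.

**Recruitment** is winner-take-all with a threshold: if the best firing
rate over all existing cells falls strictly below the firing-rate
threshold (FRT) — or no cell exists yet — the current place code is
memorized by a new cell. A new cell fires at exactly 1 on its own percept,
so every visited, nonempty percept ends its step with a winner at or
above FRT: the union of firing fields covers the explored space by
construction.

The agent performs a random walk (speed redrawn uniformly on `(0, v_max]`
each period, heading perturbed per a configurable policy) with specular
reflection at the arena walls.

## Worked example

```python
from vpcsim import RunConfig, run_single, field_metrics

result = run_single(RunConfig(seed=1))      # baseline conditions
print(result.n_vpcs)
rm = result.cell_rate_map(0)                # first recruited cell
fm = field_metrics(rm, rate_threshold=0.2)
print(round(fm.field_area_m2, 2), round(fm.coverage_fraction, 4))
```

prints

```
122
17.25 0.0238
```

122 place cells were recruited over the 4000-step exploration of the
40 m × 40 m arena, and the first cell's firing field (bins where its mean
rate is ≥ FRT = 0.2) covers 17.25 m² — about 2.4 % of the visited bins —
i.e. a localized field, as place cells should have. The population rate
map (`result.population_rate_map()`, the per-bin maximum over all cells)
covers every visited bin at ≥ FRT.

The same run from a shell, plus a parameter study:

```bash
vpcsim run --config examples/baseline.yaml --seed 1 --out out/run1
vpcsim sweep --config examples/baseline.yaml --param frt \
    --values 0.1,0.2,0.3,0.4 --replicates 5 --out out/frt_sweep --light
```

Each run writes a self-contained bundle (resolved config + seeds,
landmark CSV, trajectory CSV, cell registry JSON, firing log, rate map)
that reproduces the run byte-for-byte.

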