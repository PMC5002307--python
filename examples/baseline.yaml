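# Baseline study conditions: 40 m x 40 m arena, 100 equal-saliency
# landmarks, 10-15 m recognition annulus, 4000-step random walk.
width: 40.0
height: 40.0
n_landmarks: 100
d_min: 10.0
d_max: 15.0
v_max: 5.0
dt: 1.0
n_steps: 4000
sigma_d2: 25.0
sigma_theta2: 100.0
w_d: 1
w_theta: 1
frt: 0.2
# optional keys (documented defaults shown)
saliency_mode: equal
heading_policy: wander
resolution: 0.5
weight_normalization: current
seed: 0
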