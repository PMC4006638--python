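# 2-D Brusselator at mu = 0.3994 above the Turing threshold
# (B = B_c (1 + mu), B_c = (1 + A sqrt(D_X/D_Y))^2 = 7.66053): the amplitude
# equations predict that only the stripe mode is stable here.

[model]
name = "brusselator"
[model.params]
A = 5.0
B = 10.72015
D_X = 5.0
D_Y = 40.0

[grid]
ndim = 2
npoints = [60, 60]
spacing = 1.0

[integrator]
kind = "fixed"
scheme = "rk4"
dt = 0.004
t_span = [0.0, 120.0]
save_every = 500

[noise]
seed = 1

[initial]
kind = "steady_state"
perturbation = 0.01

[analysis]
requests = ["spatial_spectrum", "angular_modes", "variance"]
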