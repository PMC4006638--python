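# 2-D Brusselator at mu = 1.4802 (B = B_c (1 + mu) = 19.00026): only the
# reentrant hexagon branch H_0 is stable; the field organises into a
# six-fold pattern.

[model]
name = "brusselator"
[model.params]
A = 5.0
B = 19.00026
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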