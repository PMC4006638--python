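# 1-D Brusselator in the Turing regime: stationary finite-q mode excited,
# q = 0 Hopf damped; the simulation freezes into a stationary spatial
# structure (temporal variance collapses while spatial variance plateaus).

[model]
name = "brusselator"
[model.params]
A = 2.0
B = 4.8
D_X = 2.0
D_Y = 10.0

[grid]
ndim = 1
npoints = [60]
spacing = 1.0

[integrator]
kind = "fixed"
scheme = "rk4"
dt = 0.005
t_span = [0.0, 30.0]
save_every = 40

[noise]
seed = 1

[initial]
kind = "steady_state"
perturbation = 0.01

[analysis]
requests = ["spatial_spectrum", "variance"]
probe = [0]
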