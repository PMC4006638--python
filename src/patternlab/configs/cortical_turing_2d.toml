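# Cortical Turing labyrinth: gap-junction diffusion D2 = 1 cm^2 above its
# Turing threshold, default gamma_i = 50 s^-1 (Hopf stable on the low-firing
# branch).  100 x 100 grid over a 20-cm square cortex.

[model]
name = "cortical"
[model.params]
D2 = 1.0
gamma_i = 50.0
s_drive = 1.0
rest_offset_psi = false
noise_mode = "kick"
noise_amp = 1.0

[grid]
ndim = 2
npoints = [100, 100]
spacing = 0.2

[integrator]
kind = "fixed"
scheme = "rk4"
dt = 0.0004
t_span = [0.0, 3.0]
save_every = 250

[noise]
mode = "kick"
amplitude = 1.0
seed = 1

[initial]
kind = "steady_state"
branch = "low"
perturbation = 0.0

[analysis]
requests = ["spatial_spectrum", "variance"]
component = "V_e"
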