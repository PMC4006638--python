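# Turing-Hopf beating regime, scaled to a 60 x 60 grid over a 20-cm square
# cortex and 150 s of simulated time: gamma_i = 29.45 s^-1 (Hopf excited),
# D2 = 1 cm^2 (Turing excited).  s_drive = 1.13 is the recorded value from
# the reference-configuration sweep (see patternlab.reference); a one-off
# seeded noise kick starts the pattern.

[model]
name = "cortical"
[model.params]
D2 = 1.0
gamma_i = 29.45
s_drive = 1.13
rest_offset_psi = false
noise_mode = "kick"
noise_amp = 1.0

[grid]
ndim = 2
npoints = [60, 60]
spacing = 0.33333333333333333

[integrator]
kind = "fixed"
scheme = "rk4"
dt = 0.0008
t_span = [0.0, 150.0]
save_every = 125

[noise]
mode = "kick"
amplitude = 1.0
seed = 1

[initial]
kind = "steady_state"
branch = "high"
perturbation = 0.0

[analysis]
requests = ["spatial_spectrum", "temporal_spectrum", "beat", "variance"]
component = "V_e"
probe = [1, 30]
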