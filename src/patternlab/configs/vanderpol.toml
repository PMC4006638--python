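# Van der Pol oscillator, mu = 1, x(0) = 2: the integrator cross-check model.

[model]
name = "vanderpol"
[model.params]
mu = 1.0

[integrator]
kind = "fixed"
scheme = "rk4"
dt = 0.001
t_span = [0.0, 20.0]
save_every = 10

[initial]
state = [2.0, 0.0]

[analysis]
requests = []
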