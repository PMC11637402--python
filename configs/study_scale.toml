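# Full study-scale parameter grid: 10 demes x 500 diploids, selection
# strengths N_local*t in {0 .. 15}/500*... and three migration regimes.
# Simulating this grid at full scale takes days; use `predict` on it
# directly, or `simulate --scale 5` for a desk-scale run.

[island]
d = 10
N_local = 500
m = [0.00045, 0.009, 0.09]

[selection]
# N_local * t = {0.25, 0.5, 1, 2.5, 5, 7.5, 15}
t = [0.0005, 0.001, 0.002, 0.005, 0.01, 0.015, 0.03]
U = 7e-3
L_selected = 700
M = [0.0, 0.01]

[neutral]
mu_neutral = 1e-5
L_neutral = 10000

[run]
replicates = 750
# generations defaults to 50 * N_global when omitted
seed = 1
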