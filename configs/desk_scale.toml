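# Desk-scale preset: 10 demes x 100 diploids, migration rates chosen to
# preserve the scaled products 4*N*m*d/(d-1) of the study-scale grid.
# A `simulate` run of one combination takes a few minutes.

[island]
d = 10
N_local = 100
m = [0.00225, 0.045, 0.45]

[selection]
t = [0.0, 0.015]
U = 7e-3
L_selected = 700
M = [0.0]

[neutral]
mu_neutral = 2e-5
L_neutral = 100

[run]
replicates = 50
generations = 20000   # 20 * N_global
seed = 1
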