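# Default model parameters (flat key = value; lengths in um).
# alpha, beta, k set the strength of membrane tension, bending rigidity and
# linker stiffness; delta_p is the pressure difference across the membrane.
# Magnitudes are model units chosen so that realistic cell contours yield
# finite sub-critical pressures; all analyses in this package depend only on
# ratios, orderings and symmetry, never on these absolute values.
alpha = 1.0
beta = 0.002
k = 1.0
delta_p = 0.0
x0_mode = initial
L0 = 0.03
L_crit = 0.015
eta = 0.001
spacing = 0.3
descent_step = 0.05
grad_tol = 3e-05
max_iters = 40000
rng_seed = 0
p_start = 0.01
dt = 0.0002
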