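# Glucose/OGTT case study: two-hour postprandial blood glucose, log-transformed
# and normalized to the non-diseased SD. Two tests differing only in standard
# measurement uncertainty (1% and 10% CV on the original scale).
mu_d: 2.99
sigma_d: 0.75
mu_nd: 0.0
sigma_nd: 1.0
v: 0.067
d: 2.26
u_a: 0.023
u_b: 0.23
l0: 1.0
l_tn: 0.0
l_fn: 100.0
l_tp: 0.0
l_fp: 76.0
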