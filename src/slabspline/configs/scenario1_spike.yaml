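# Dose scenario 1 (doses dense near zero), spike effect present.
name: scenario1_spike
p_zero: 0.25
alpha_X: 1.0
beta_X: 5.0
gamma_X: 2.0
beta1_true: 0.5
intercept_true: 10.0
slope_true: -2.4
quad_true: 4.8
sigma_Y: 1.5
N: 1000
M: 500
seed: 20240621
models: [1, 2, 3, 4, 5, 6, 7, 8, 9]
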