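# Final population-PK model of sirolimus in pediatric lymphangioma.
# CL/F = 11.3 * (weight/70)^0.75 L/h ; V/F = 388 * (weight/70) L ;
# Ka fixed; lognormal IIV on CL/F (omega_cl is the SD of eta);
# additive residual error in ng/ml.
version: 1
cl_f_std: 11.3          # L/h at 70 kg
cl_exponent: 0.75
v_f_std: 388.0          # L at 70 kg
v_exponent: 1.0
standard_weight: 70.0   # kg
ka: 0.485               # 1/h, fixed
omega_cl: 0.303         # SD of eta on CL/F
sigma_add: 3.578        # ng/ml
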