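# Elevated-baseline parameter set, chemotherapy-calibration column:
# beta0 = 4 and n = 2 raise the untreated plateau of proliferating cells
# to 100, reflecting the elevated counts typical of patients entering
# chemotherapy. Used by the CTA-only and combined-treatment scenarios.
P0: 100.0
N0: 70.0
delta: 0.09
gamma: 0.15
tau: 2.22
theta: 60.0
theta1: 100.0
theta2: 100.0
beta0: 4.0
beta0_C: 0.206
beta0_HIA: 0.08
n: 2.0
w: 1.0
m: 0.1
s1: 0.2
s2: 0.2
tau1: 5.0
tau2: 5.0
tau3: 18.0
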