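# Baseline parameter set, untreated-calibration column: the quiescent
# re-entry Hill (beta0 = 1.4, n = 2.7) places the untreated plateau near
# 45 proliferating / 115 non-proliferating cells per 10,000 leukocytes.
# Used by the control and HIA-only scenarios.
P0: 50.0
N0: 70.0
delta: 0.09
gamma: 0.15
tau: 2.22
theta: 60.0
theta1: 100.0
theta2: 100.0
beta0: 1.4
beta0_C: 0.206
beta0_HIA: 0.08
n: 2.7
w: 1.0
m: 0.1
s1: 0.2
s2: 0.2
# Decay-clock onsets (days after administration). Calibrated defaults:
# chosen so the chemotherapy nadir falls about 5 days after
# administration and the post-chemotherapy plateau sits near 80 cells.
tau1: 5.0
tau2: 5.0
tau3: 18.0
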