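"""Predict a full theta cycle of spikes and the per-cycle spike count.

After the first spike, each interspike interval is the time for the
recruited inhibition to decay back to the instantaneous drive level plus
a slow-passage delay:
    dT(Theta) = (1/eps) ln(gIE/F(Theta)) - Omega0/(eps^(1/3) F(Theta)^(1/3)).
Averaging dT over the spiking phases yields an integer estimate M of the
spikes per theta cycle.
"""

from thetagamma import (
    ModelParams,
    isi_extrema,
    predict_spike_sequence,
    simulate,
    spike_count,
    spikes_per_theta_cycle,
)

p = ModelParams(IE=0.5, lam=0.8, gIE=6.0, epsI=0.1, epsTheta=0.01, omega=4.0)
pred = predict_spike_sequence(p)
_, train = simulate(p, t_end=p.theta_period)

print("Strong oscillator set IE=0.5, lam=0.8, gIE=6, eps=0.1, omega=4")
print(f"predicted times: {[round(t, 1) for t in pred.times]}")
print(f"simulated times: {[round(float(t), 1) for t in train.times]}")
print(f"spike count: predicted M = {spike_count(p)}, simulated = {spikes_per_theta_cycle(p)}")

dT_max, dT_min = isi_extrema(p)
print(f"\nISI band: [{dT_min:.2f}, {dT_max:.2f}]  (theta peak .. theta trough)")
print(f"simulated ISIs: {[round(float(d), 1) for d in (train.times[1:] - train.times[:-1])]}")
print(f"intrinsic (unmodulated) period: {pred.isi_intrinsic:.2f}")
# 1/dT_min and 1/dT_max bound the instantaneous gamma frequency attained
# during the theta cycle; the simulated ISIs fall inside the band, fastest
# at the theta peak where the drive is maximal.
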