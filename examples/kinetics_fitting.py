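"""Recover indicator kinetics from a noiseless step response.

Simulates the ASAP2s fluorescence response to a 100 mV depolarising step
and fits a weighted sum of two exponentials, recovering the generating
(tau_fast, tau_slow, fraction-fast) triplet.
"""

import gevitrace as gt

kinetics = gt.get_indicator("ASAP2s")
truth = kinetics.transitions["depolarization"]

waveform = gt.make_step_waveform(v_start=-70.0, v_step=30.0, t_step=0.0,
                                 duration=400.0, dt=0.05)
response = gt.simulate_dff(kinetics, waveform)
fit = gt.fit_biexponential((response.times, response.values))

print("                     fitted    generating")
print(f"tau_fast (ms)      : {fit.tau_fast:8.2f}  {truth.tau_fast:8.2f}")
print(f"tau_slow (ms)      : {fit.tau_slow:8.2f}  {truth.tau_slow:8.2f}")
print(f"fraction fast      : {fit.fraction_fast:8.3f}  {truth.fraction_fast:8.3f}")
print(f"fit r^2            : {fit.r2:8.6f}")
print(f"steady state dF/F  : {response.values[-1]:+.3f}")
print()
print("A noiseless forward-model step is itself a two-exponential relaxation,")
print("so the least-squares fit recovers the tabulated constants essentially")
print("exactly; the steady state matches the F-V curve anchor at +30 mV.")
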