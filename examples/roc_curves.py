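"""Detection rates versus d': Monte-Carlo stream against the closed form.

For each d', simulates the 10^6-sample Gaussian detection stream (one spike
sample in ten), thresholds the spike log-likelihood at the value maximising
true positives minus false positives, and compares the empirical rates with
the analytic optimum u = d'/2 + ln(9)/d'.
"""

import gevitrace as gt

print(" d'    tp (sim)   tp (analytic)   fp (sim)    fp (analytic)")
for dp in (1.0, 2.0, 4.1, 6.0, 10.0):
    rep = gt.roc_simulate(dp, gt.RocConfig(n_samples=10**6, spike_period=10, seed=1))
    _, tp, fp = gt.roc_analytic(dp, spike_fraction=0.1)
    print(f"{dp:4.1f}   {rep.tp_rate:8.4f}   {tp:10.4f}     {rep.fp_rate:9.6f}   {fp:9.6f}")

print()
print("At d' = 4.1 roughly 94% of spikes are caught at ~0.005 false positives")
print("per frame; by d' = 10 detection is essentially perfect. The empirical")
print("threshold is chosen on the sample, so at small d' its rates wobble")
print("around the analytic optimum by a few tenths of a percent.")
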