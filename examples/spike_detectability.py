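"""Measure spike detectability (d') on a simulated whole-cell recording.

Simulates a 20-voxel somatic ASAP2s recording of a single AP at 925 Hz
(voxel counts summed into one whole-cell trace), measures d' from the
trace, and translates it into detection and false-positive rates via the
log-likelihood ROC procedure.
"""

import numpy as np

import gevitrace as gt
from gevitrace.trace import Event

waveform = gt.make_ap_waveform(4.0, 100.0, rest=-70.0, duration=700.0,
                               dt=0.1, center=400.0)
dff_model = gt.simulate_dff(gt.get_indicator("ASAP2s"), waveform)
v = waveform.voltages
onset = float(waveform.times[np.argmax(v > v[0] + 0.05 * (v.max() - v[0]))])

# whole cell = 20 voxels x 500 photons/dwell summed into one trace
schedule = gt.ScanSchedule(n_voxels=20)
trace = gt.simulate_photon_counts(dff_model, rest_rate=20 * 500.0,
                                  schedule=schedule, seed=7)
trace.events.append(Event("spike_trigger", onset))

record = gt.dprime_single(trace, search_ms=25.0)
print(f"F0                  : {record.f0_used:.0f} photons/frame")
print(f"|dF/F| at the peak  : {record.dff:.3f}")
print(f"decay tau           : {record.tau_used:.1f} frames")
print(f"measured d'         : {record.dprime:.1f}")

u, tp, fp = gt.roc_analytic(record.dprime, spike_fraction=0.1)
print(f"detection rate      : {100 * tp:.4f} %")
print(f"false positives     : {fp:.3g} per frame")
print()
print("d' combines response amplitude with the photon budget F0*tau; at this")
print("photon rate a single AP is essentially impossible to miss (detection")
print("~100%, false positives far below one per recording).")
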