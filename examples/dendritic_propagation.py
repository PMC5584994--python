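"""Track a back-propagating AP across dendritic voxels.

Simulates a five-voxel random-access recording (3700 Hz) of a spike that
attenuates linearly with distance and travels at 0.16 m/s, then recovers
the conduction velocity and the attenuation profile from the traces.
"""

from collections import defaultdict

import numpy as np

import gevitrace as gt
from gevitrace.trace import Event

waveform = gt.make_ap_waveform(4.0, 100.0, rest=-70.0, duration=700.0,
                               dt=0.1, center=400.0)
v = waveform.voltages
onset = float(waveform.times[np.argmax(v > v[0] + 0.05 * (v.max() - v[0]))])

distances = [0.0, 75.0, 110.0, 150.0, 195.0]  # µm from the soma
slope = 0.0026  # fractional amplitude loss per µm
geometry = gt.CellGeometry(
    voxels=tuple(gt.Voxel(i, d, 2000.0, 1.0 - slope * d)
                 for i, d in enumerate(distances)),
    conduction_velocity=0.16,
)
traces = gt.simulate_ramp_experiment(
    gt.get_indicator("ASAP2s"), waveform, geometry,
    schedule=gt.ScanSchedule(n_voxels=5), n_trials=31, seed=11,
)

by_voxel = defaultdict(list)
for tr in traces:
    by_voxel[tr.voxel_id].append(tr)

peak_points, amp_points = [], []
for vid, trs in sorted(by_voxel.items()):
    avg = trs[0].with_values(np.mean([t.values for t in trs], axis=0))
    avg.events = [Event("spike_trigger", onset)]
    dff = gt.compute_dff(avg, trigger=onset)
    amp, idx = gt.peak_amplitude(dff, trigger=onset, search_ms=25.0)
    d_um = trs[0].meta["distance_from_soma_um"]
    peak_points.append((d_um, gt.refine_peak_time(dff, idx)))
    amp_points.append((d_um, amp))

velocity, pairwise = gt.conduction_velocity(peak_points)
print(f"generating velocity : 0.160 m/s")
print(f"recovered velocity  : {velocity:.3f} m/s")
print("attenuation profile (generated vs recovered % reduction):")
for d_um, reduction in gt.attenuation_profile(amp_points):
    print(f"  {d_um:5.0f} um : {slope * d_um * 100:5.1f}  vs  {reduction:5.1f}")
print()
print("Peak times, refined below the 0.27 ms frame period by parabolic")
print("interpolation, recover the conduction velocity; peak amplitudes")
print("recover the attenuation line within shot-noise error.")
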