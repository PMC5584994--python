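"""Stimulus-locked analysis of a flash-responsive ROI.

Builds a synthetic ΔF/F trace for an ROI that depolarises during 300 ms
dark flashes and hyperpolarises during light flashes, sampled at the slow
imaging frame rate (38.9 Hz), then runs the full ROI pipeline: re-timing
against the stimulus, moving-average pooling (25 ms window / 8.33 ms
shift), the responding-ROI t-test, and per-phase quantification.
"""

import numpy as np

import gevitrace as gt
from gevitrace.trace import Trace

protocol = gt.StimulusProtocol.alternating(n_cycles=100, flash_duration_ms=300.0)
period = protocol.cycle_period


def l2_like(trel):
    """Transient depolarisation in the dark phase, hyperpolarisation in the
    light phase (as in fly lamina monopolar cells)."""
    half = period / 2
    rise = np.minimum(trel / 0.05, 1.0)
    dark = (trel < half) * 0.08 * rise * np.exp(-np.maximum(trel - 0.05, 0) / 0.1)
    rel = np.maximum(trel - half, 0.0)
    light = (trel >= half) * -0.06 * np.minimum(rel / 0.05, 1.0) * np.exp(
        -np.maximum(rel - 0.05, 0) / 0.1)
    return dark + light


rng = np.random.default_rng(0)
t = np.arange(0.0, 100 * period, 1.0 / protocol.frame_rate)
values = l2_like(np.mod(t, period)) + rng.normal(0.0, 0.02, t.size)
trace = Trace(times=t, values=values, kind="dff", frame_rate=protocol.frame_rate)

record = gt.analyze_roi(trace, protocol, roi_id="L2-terminal-1")
print(f"ROI                : {record.roi_id}")
print(f"responding         : {record.responding}")
for phase, m in (("dark flash ", record.dark), ("light flash", record.light)):
    tau = f"{m.tau_decay * 1e3:6.1f} ms" if m.tau_decay else "  (excluded)"
    print(f"{phase} : A_max {m.a_max:.3f}  t_peak {m.t_peak * 1e3:6.1f} ms"
          f"  tau_decay {tau}")
print()
print("The moving average pools 100 cycles onto an 8.33 ms grid, finer than")
print("the 25.7 ms frame period; the responding flag requires >= 3 consecutive")
print("grid points where dark and light responses differ at p < 0.01, and")
print("tau_decay is only reported when its exponential fit reaches r^2 > 0.5.")
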