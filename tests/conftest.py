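"""Shared fixtures: indicator presets and simulated reference recordings."""

from __future__ import annotations

import numpy as np
import pytest

import gevitrace as gt
from gevitrace.trace import Event


@pytest.fixture(scope="session")
def asap2s():
    return gt.get_indicator("ASAP2s")


@pytest.fixture(scope="session")
def asap1():
    return gt.get_indicator("ASAP1")


@pytest.fixture(scope="session")
def ap_waveform():
    """4 ms FWHM, 100 mV Gaussian AP surrogate centred at 400 ms."""
    return gt.make_ap_waveform(4.0, 100.0, rest=-70.0, duration=700.0, dt=0.1, center=400.0)


@pytest.fixture(scope="session")
def ap_onset(ap_waveform):
    """Time the surrogate voltage first exceeds 5% of the spike amplitude."""
    v = ap_waveform.voltages
    amp = v.max() - v[0]
    idx = int(np.argmax(v > v[0] + 0.05 * amp))
    return float(ap_waveform.times[idx])


@pytest.fixture(scope="session")
def ap_dff_asap2s(asap2s, ap_waveform):
    return gt.simulate_dff(asap2s, ap_waveform)


@pytest.fixture(scope="session")
def ap_dff_asap1(asap1, ap_waveform):
    return gt.simulate_dff(asap1, ap_waveform)


def average_trials(traces):
    """Mean-count trace across trials of identical geometry."""
    out = traces[0].with_values(np.mean([t.values for t in traces], axis=0))
    out.events = list(traces[0].events)
    return out


def annotate(trace, **events):
    """Attach events in place and return the trace (test convenience)."""
    for kind, time in events.items():
        trace.events.append(Event(kind, time))
    return trace
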