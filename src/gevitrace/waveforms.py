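"""Membrane-voltage waveforms used to drive the forward model.

All waveforms are sampled on a uniform grid starting at t = 0, with times in
seconds and voltages in millivolts. The action-potential surrogate is a
Gaussian bump parameterised by its full width at half maximum and peak
amplitude — the two properties of the physiological waveform that are
quantitatively specified — on top of a resting potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class VoltageWaveform:
    """Uniformly sampled V(t): times in s (starting at 0), voltages in mV."""

    times: np.ndarray
    voltages: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise InvalidArgumentError("times and voltages must be 1-D and equally long")
        if t.size and abs(t[0]) > 1e-12:
            raise InvalidArgumentError("waveform times must start at 0")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("waveform times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1])


def make_ap_waveform(
    fwhm: float,
    peak_amplitude: float,
    rest: float = -70.0,
    duration: float | None = None,
    dt: float = 0.1,
    center: float | None = None,
) -> VoltageWaveform:
    """Gaussian action-potential surrogate.

    Parameters are in milliseconds and millivolts: ``fwhm`` the full width at
    half maximum of the bump, ``peak_amplitude`` its height above ``rest``.
    The bump is centred at ``center`` ms (default: duration/2) within a trace
    of ``duration`` ms (default 10×fwhm) sampled every ``dt`` ms.
    """
    if not fwhm > 0:
        raise InvalidArgumentError("fwhm must be positive")
    if duration is None:
        duration = 10.0 * fwhm
    if duration < 3.0 * fwhm:
        raise InvalidArgumentError("duration must be at least 3×fwhm")
    if not dt < fwhm / 4.0:
        raise InvalidArgumentError("dt must be finer than fwhm/4")
    if center is None:
        center = duration / 2.0
    t_ms = np.arange(0.0, duration + dt / 2.0, dt)
    sigma = fwhm * _FWHM_TO_SIGMA
    v = rest + peak_amplitude * np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)
    return VoltageWaveform(times=t_ms * 1e-3, voltages=v)


def make_spike_train(
    freq: float,
    n_spikes: int,
    fwhm: float,
    peak_amplitude: float,
    rest: float = -70.0,
    dt: float = 0.1,
    pre: float | None = None,
    post: float | None = None,
) -> VoltageWaveform:
    """Superposition of ``n_spikes`` AP surrogates with onsets 1/freq apart.

    ``freq`` in Hz; all other parameters in ms/mV as in
    :func:`make_ap_waveform`. ``pre``/``post`` pad the train with resting
    potential (defaults 5×fwhm each).
    """
    if not freq > 0:
        raise InvalidArgumentError("freq must be positive")
    if n_spikes < 1:
        raise InvalidArgumentError("n_spikes must be >= 1")
    interval = 1000.0 / freq  # ms
    if interval <= fwhm:
        raise InvalidArgumentError(
            f"inter-spike interval {interval:g} ms <= fwhm {fwhm:g} ms: spikes would merge"
        )
    if pre is None:
        pre = 5.0 * fwhm
    if post is None:
        post = 5.0 * fwhm
    duration = pre + (n_spikes - 1) * interval + post
    t_ms = np.arange(0.0, duration + dt / 2.0, dt)
    sigma = fwhm * _FWHM_TO_SIGMA
    v = np.full_like(t_ms, float(rest))
    for k in range(n_spikes):
        v += peak_amplitude * np.exp(-0.5 * ((t_ms - (pre + k * interval)) / sigma) ** 2)
    return VoltageWaveform(times=t_ms * 1e-3, voltages=v)


def make_step_waveform(
    v_start: float,
    v_step: float,
    t_step: float,
    duration: float,
    dt: float = 0.1,
    t_return: float | None = None,
) -> VoltageWaveform:
    """Voltage step from ``v_start`` to ``v_step`` at ``t_step`` ms, optionally
    returning to ``v_start`` at ``t_return`` ms. Times in ms."""
    t_ms = np.arange(0.0, duration + dt / 2.0, dt)
    v = np.full_like(t_ms, float(v_start))
    if t_return is None:
        v[t_ms >= t_step] = v_step
    else:
        if t_return <= t_step:
            raise InvalidArgumentError("t_return must follow t_step")
        v[(t_ms >= t_step) & (t_ms < t_return)] = v_step
    return VoltageWaveform(times=t_ms * 1e-3, voltages=v)


def measure_fwhm(times: np.ndarray, values: np.ndarray) -> float:
    """Full width at half maximum of a unimodal bump, by linear interpolation
    between samples at the half-height crossings. Returns NaN when the trace
    never recrosses half height. ``values`` are measured relative to their
    first sample (the resting level); works for either polarity."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float) - float(values[0])
    peak = np.argmax(np.abs(y))
    sign = np.sign(y[peak]) or 1.0
    y = y * sign
    half = y[peak] / 2.0
    above = y >= half
    if not above.any() or above[0] or above[-1]:
        return float("nan")
    rise = np.flatnonzero(above)[0]
    fall = np.flatnonzero(above)[-1]
    # interpolate the outermost crossings
    t_lo = np.interp(half, [y[rise - 1], y[rise]], [t[rise - 1], t[rise]])
    t_hi = np.interp(half, [y[fall + 1], y[fall]], [t[fall + 1], t[fall]])
    return float(t_hi - t_lo)
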