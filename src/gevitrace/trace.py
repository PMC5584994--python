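"""The Trace container: a uniformly sampled fluorescence time series.

A :class:`Trace` holds either raw photon counts per frame (``kind="counts"``)
or a dimensionless fractional fluorescence change (``kind="dff"``), together
with acquisition metadata (frame rate, voxel/trial identity) and event
annotations (spike triggers, stimulus transitions). Times are in seconds with
t = 0 at acquisition start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidTraceError

COUNTS = "counts"
DFF = "dff"

#: Event kinds recognised on a trace.
EVENT_KINDS = ("spike_trigger", "stimulus_onset", "stimulus_transition")

#: Maximum allowed sampling jitter, as a fraction of the nominal period.
MAX_JITTER = 0.01


@dataclass(frozen=True)
class Event:
    kind: str
    time: float  # s

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise InvalidTraceError(
                f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}"
            )


@dataclass
class Trace:
    """Uniformly sampled photon-count or ΔF/F series.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing, uniform to within 1%
        of the nominal period.
    values : array of float
        Photon counts per frame or ΔF/F, matching ``kind``.
    kind : {"counts", "dff"}
    frame_rate : float
        Nominal sampling rate in Hz.
    polarity : {-1, +1}
        Expected sign of the fluorescence response to depolarisation.
        ASAP-family indicators dim on depolarisation, hence the default −1.
    meta : dict
        Free-form provenance (schedule, seed, baseline F0, ...).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = COUNTS
    frame_rate: float | None = None
    voxel_id: str | int | None = None
    trial_id: str | int | None = None
    events: list[Event] = field(default_factory=list)
    polarity: int = -1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidTraceError("times and values must be 1-D and equally long")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise InvalidTraceError(f"times not strictly increasing at sample {i + 1}")
            period = float(np.median(dt))
            if np.max(np.abs(dt - period)) > MAX_JITTER * period:
                raise InvalidTraceError("sampling jitter exceeds 1% of the frame period")
            if self.frame_rate is None:
                self.frame_rate = 1.0 / period
        if not np.all(np.isfinite(self.values)):
            raise InvalidTraceError("values contain non-finite entries")
        if self.kind not in (COUNTS, DFF):
            raise InvalidTraceError(f"unknown trace kind {self.kind!r}")
        t0, t1 = (self.times[0], self.times[-1]) if self.times.size else (0.0, 0.0)
        for ev in self.events:
            if not (t0 <= ev.time <= t1):
                raise InvalidTraceError(
                    f"event {ev.kind!r} at {ev.time} s lies outside the trace span"
                )

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def n(self) -> int:
        return self.times.size

    def event_times(self, kind: str) -> list[float]:
        return [ev.time for ev in self.events if ev.kind == kind]

    def first_event(self, kind: str) -> Event:
        for ev in self.events:
            if ev.kind == kind:
                return ev
        raise InvalidTraceError(f"trace has no {kind!r} event")

    def window(self, start: float, stop: float) -> np.ndarray:
        """Values with start <= t < stop (half-open frame convention)."""
        mask = (self.times >= start) & (self.times < stop)
        return self.values[mask]

    def with_values(self, values: np.ndarray, kind: str | None = None, **meta) -> "Trace":
        out = replace(self, values=np.asarray(values, dtype=float))
        if kind is not None:
            out.kind = kind
        out.meta = {**self.meta, **meta}
        out.events = list(self.events)
        return out
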