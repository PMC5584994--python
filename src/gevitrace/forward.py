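"""Forward model: voltage → indicator ΔF/F → Poisson photon counts.

The generator emulates random-access two-photon voltage imaging: a laser
visits a handful of membrane voxels in turn, dwelling ~50 µs at each, so the
per-voxel frame rate is the reciprocal of (number of voxels × per-voxel
period). Fluorescence collected at each visit is a photon count whose mean
follows the indicator's fractional response to the membrane potential,
scaled by a resting photon rate, a multiplicative photobleaching envelope,
and (for dendritic voxels) an attenuation factor, with a conduction delay
for back-propagating spikes.

The indicator response is integrated as two hidden first-order components
(fast and slow) that each relax toward the steady-state ΔF/F prescribed by
the F–V curve at the instantaneous voltage, with time constants and mixing
weight selected per sample from the four-regime kinetics table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .indicators import IndicatorKinetics
from .trace import DFF, Event, Trace
from .waveforms import VoltageWaveform

#: Per-voxel period (µs) calibrated so that 5 voxels give exactly 3700 Hz.
DEFAULT_PER_VOXEL_PERIOD_US = 1e6 / (5 * 3700.0)

#: Laser dwell time per voxel visit (µs).
DEFAULT_DWELL_US = 50.0

#: Default resting photon rate per voxel per dwell. Published per-voxel rates
#: are shown only graphically; this default is calibrated so that a summed
#: 20-voxel somatic recording lands in the tens-of-units d' regime typical of
#: bright two-photon photon-counting recordings.
DEFAULT_REST_RATE = 500.0


def scan_frequency(n_voxels: int, per_voxel_period: float = DEFAULT_PER_VOXEL_PERIOD_US) -> float:
    """Per-voxel frame rate (Hz) for ``n_voxels`` voxels visited every
    ``per_voxel_period`` µs each: 1 / (n × p)."""
    if n_voxels < 1:
        raise InvalidArgumentError("n_voxels must be >= 1")
    return 1.0 / (n_voxels * per_voxel_period * 1e-6)


@dataclass(frozen=True)
class ScanSchedule:
    """Random-access acquisition geometry.

    ``frame_rate`` is derived from the voxel count and per-voxel period and
    satisfies frame_rate × n_voxels × per_voxel_period = 1 exactly.
    """

    n_voxels: int
    dwell_time: float = DEFAULT_DWELL_US  # µs
    per_voxel_period: float = DEFAULT_PER_VOXEL_PERIOD_US  # µs

    def __post_init__(self):
        if self.n_voxels < 1:
            raise InvalidArgumentError("n_voxels must be >= 1")
        if self.per_voxel_period < self.dwell_time:
            raise InvalidArgumentError("per_voxel_period must be >= dwell_time")

    @property
    def frame_rate(self) -> float:
        return scan_frequency(self.n_voxels, self.per_voxel_period)

    def as_dict(self) -> dict:
        return {
            "n_voxels": self.n_voxels,
            "dwell_time_us": self.dwell_time,
            "per_voxel_period_us": self.per_voxel_period,
            "frame_rate_hz": self.frame_rate,
        }


@dataclass(frozen=True)
class BleachModel:
    """Multi-exponential photobleaching envelope, value 1 at t = 0.

    ``components`` is a list of (weight, tau [s]); weights are non-negative
    and sum to 1. A tau of ``inf`` contributes a non-bleaching plateau.
    """

    components: tuple[tuple[float, float], ...]

    def __post_init__(self):
        w = np.array([c[0] for c in self.components], dtype=float)
        taus = np.array([c[1] for c in self.components], dtype=float)
        if np.any(w < 0) or np.any(taus <= 0):
            raise InvalidArgumentError("weights must be >= 0 and taus > 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("bleach component weights must sum to 1")

    @classmethod
    def none(cls) -> "BleachModel":
        return cls(components=((1.0, math.inf),))

    @classmethod
    def biexponential(cls, w_fast: float, tau_fast: float, tau_slow: float) -> "BleachModel":
        return cls(components=((w_fast, tau_fast), (1.0 - w_fast, tau_slow)))

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for w, tau in self.components:
            out = out + (w if math.isinf(tau) else w * np.exp(-t / tau))
        return out


@dataclass(frozen=True)
class Voxel:
    voxel_id: int | str
    distance_from_soma: float  # µm
    rest_photon_rate: float  # photons per dwell (= per frame)
    attenuation_factor: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.attenuation_factor <= 1.0:
            raise InvalidArgumentError("attenuation_factor must lie in (0, 1]")
        if self.distance_from_soma < 0:
            raise InvalidArgumentError("distance_from_soma must be >= 0")


@dataclass(frozen=True)
class CellGeometry:
    """Imaged voxels on a soma/dendrite arbor plus a conduction velocity.

    Attenuation must be 1 at the soma (distance 0) and non-increasing with
    distance; spikes reach a voxel after distance / conduction_velocity.
    """

    voxels: tuple[Voxel, ...]
    conduction_velocity: float = 0.16  # m/s

    def __post_init__(self):
        if not self.voxels:
            raise InvalidArgumentError("geometry must contain at least one voxel")
        ordered = sorted(self.voxels, key=lambda v: v.distance_from_soma)
        for vox in ordered:
            if vox.distance_from_soma == 0 and vox.attenuation_factor != 1.0:
                raise InvalidArgumentError("attenuation_factor must be 1 at distance 0")
        att = [v.attenuation_factor for v in ordered]
        if np.any(np.diff(att) > 1e-12):
            raise InvalidArgumentError("attenuation_factor must be non-increasing with distance")
        has_dendrite = any(v.distance_from_soma > 0 for v in self.voxels)
        if self.conduction_velocity == 0 and has_dendrite:
            raise InvalidArgumentError(
                "zero conduction velocity with nonzero dendritic distances"
            )


def simulate_dff(kinetics: IndicatorKinetics, waveform: VoltageWaveform) -> Trace:
    """Integrate the indicator response to a voltage waveform.

    Two hidden components (fast, slow) each relax toward the steady-state
    ΔF/F given by the F–V curve at the instantaneous voltage; the output is
    their weighted sum with weight ``fraction_fast`` of the active regime.
    The regime is selected per sample from the side of the voltage relative
    to holding and whether the response is moving away from or back toward
    rest. Voltages outside the F–V anchor span are clamped with a warning.

    Returns a :class:`Trace` of kind ``dff`` on the waveform's time grid.
    """
    t = waveform.times
    v = waveform.voltages
    if t.size < 2:
        raise InvalidArgumentError("waveform must contain at least two samples")
    dt_ms = (t[1] - t[0]) * 1e3
    min_tau_fast = min(tr.tau_fast for tr in kinetics.transitions.values())
    if dt_ms >= min_tau_fast / 5.0:
        raise InvalidArgumentError(
            f"waveform sampling ({dt_ms:g} ms) must be finer than the fastest "
            f"time constant / 5 ({min_tau_fast / 5.0:g} ms)"
        )
    lo, hi = kinetics.voltage_span()
    if np.any(v < lo - 1e-9) or np.any(v > hi + 1e-9):
        warnings.warn(
            f"voltages outside the F–V anchor span [{lo:g}, {hi:g}] mV were "
            "clamped to the end anchors",
            stacklevel=2,
        )
    targets = kinetics.steady_state_dff(v)

    # Precompute per-regime relaxation factors for the uniform step dt.
    names = list(kinetics.transitions)
    alpha_f = np.empty(len(names))
    alpha_s = np.empty(len(names))
    w_fast = np.empty(len(names))
    for k, nm in enumerate(names):
        tr = kinetics.transitions[nm]
        alpha_f[k] = -np.expm1(-dt_ms / tr.tau_fast)
        alpha_s[k] = -np.expm1(-dt_ms / tr.tau_slow)
        w_fast[k] = tr.fraction_fast
    idx = {nm: k for k, nm in enumerate(names)}
    i_dep = idx["depolarization"]
    i_rep_d = idx["repolarization_from_depolarized"]
    i_hyp = idx["hyperpolarization"]
    i_rep_h = idx["repolarization_from_hyperpolarized"]

    r = kinetics.response_sign  # −1 for ASAP-type (dimming) indicators
    holding = kinetics.holding_potential
    tol = 1e-9

    out = np.zeros_like(targets)
    uf = us = y = 0.0
    for i in range(1, t.size):
        s = targets[i]
        vi = v[i]
        if vi > holding + tol:
            k = i_dep if r * s >= r * y else i_rep_d
        elif vi < holding - tol:
            k = i_hyp if -r * s >= -r * y else i_rep_h
        else:  # at holding: relax back from whichever side the response is on
            k = i_rep_d if r * y > 0 else i_rep_h
        uf += (s - uf) * alpha_f[k]
        us += (s - us) * alpha_s[k]
        y = w_fast[k] * uf + (1.0 - w_fast[k]) * us
        out[i] = y

    return Trace(
        times=t.copy(),
        values=out,
        kind=DFF,
        frame_rate=1.0 / (t[1] - t[0]),
        polarity=r,
        meta={"indicator": kinetics.name},
    )


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_photon_counts(
    dff: Trace,
    rest_rate: float,
    schedule: ScanSchedule,
    bleach: BleachModel | None = None,
    seed: int | np.random.Generator = 0,
    voxel_id=0,
    trial_id=0,
) -> Trace:
    """Draw per-frame Poisson photon counts from a ΔF/F series.

    Frames are instantaneous samples at frame midpoints with mean
    rest_rate × (1 + ΔF/F(t)) × bleach(t). Deterministic given ``seed``.
    """
    if rest_rate < 0:
        raise InvalidArgumentError("rest_rate must be >= 0")
    if dff.kind != DFF:
        raise InvalidArgumentError("simulate_photon_counts expects a dff-kind trace")
    if bleach is None:
        bleach = BleachModel.none()
    period = 1.0 / schedule.frame_rate
    n_frames = int(np.floor((dff.times[-1] - dff.times[0]) / period))
    if n_frames < 1:
        raise InvalidArgumentError("dff series shorter than one frame of the schedule")
    mid = dff.times[0] + (np.arange(n_frames) + 0.5) * period
    vals = np.interp(mid, dff.times, dff.values)
    if np.any(vals < -1.0):
        raise InvalidArgumentError("ΔF/F < −1 gives a negative photon rate")
    mean = rest_rate * (1.0 + vals) * bleach(mid - dff.times[0])
    rng = _resolve_rng(seed)
    counts = rng.poisson(mean).astype(float)
    events = [ev for ev in dff.events if mid[0] <= ev.time <= mid[-1]]
    return Trace(
        times=mid,
        values=counts,
        kind="counts",
        frame_rate=schedule.frame_rate,
        voxel_id=voxel_id,
        trial_id=trial_id,
        events=events,
        polarity=dff.polarity,
        meta={
            **dff.meta,
            "rest_rate": rest_rate,
            "schedule": schedule.as_dict(),
            "seed": None if isinstance(seed, np.random.Generator) else int(seed),
        },
    )


def simulate_ramp_experiment(
    kinetics: IndicatorKinetics,
    waveform: VoltageWaveform,
    geometry: CellGeometry,
    schedule: ScanSchedule | None = None,
    bleach: BleachModel | None = None,
    n_trials: int = 1,
    seed: int = 0,
    events: list[Event] | None = None,
) -> list[Trace]:
    """Simulate a multi-voxel, multi-trial random-access recording.

    For each voxel the somatic ΔF/F series is scaled by the voxel's
    attenuation factor and delayed by distance / conduction velocity, then
    ``n_trials`` photon-count traces are drawn with independent noise
    streams spawned deterministically from ``seed``.
    """
    if schedule is None:
        schedule = ScanSchedule(n_voxels=len(geometry.voxels))
    base = simulate_dff(kinetics, waveform)
    streams = np.random.SeedSequence(seed).spawn(len(geometry.voxels) * n_trials)
    traces: list[Trace] = []
    for iv, vox in enumerate(geometry.voxels):
        if math.isinf(geometry.conduction_velocity):
            delay = 0.0
        else:
            delay = vox.distance_from_soma * 1e-6 / geometry.conduction_velocity
        shifted = np.interp(
            base.times - delay, base.times, base.values, left=0.0, right=base.values[-1]
        )
        vox_dff = base.with_values(shifted * vox.attenuation_factor)
        vox_dff.events = [
            Event(ev.kind, ev.time + delay)
            for ev in (events or [])
            if base.times[0] <= ev.time + delay <= base.times[-1]
        ]
        for trial in range(n_trials):
            rng = np.random.default_rng(streams[iv * n_trials + trial])
            tr = simulate_photon_counts(
                vox_dff,
                rest_rate=vox.rest_photon_rate,
                schedule=schedule,
                bleach=bleach,
                seed=rng,
                voxel_id=vox.voxel_id,
                trial_id=trial,
            )
            tr.meta["seed"] = int(seed)
            tr.meta["distance_from_soma_um"] = vox.distance_from_soma
            tr.meta["attenuation_factor"] = vox.attenuation_factor
            traces.append(tr)
    return traces
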