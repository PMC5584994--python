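"""Spike detectability: the d′ statistic, spike trains, and ROC analysis.

The detectability index for a well-isolated spike on a stable baseline is

    d′ = |ΔF/F| · √(F0 · τ / 2)

where ΔF/F is the fractional fluorescence response to the spike, F0 the
resting fluorescence in photons per frame, and τ the indicator decay
constant expressed in frames. The product F0·τ is the photon budget of one
spike transient; larger responses, brighter baselines, and slower decays all
make spikes easier to distinguish from shot noise.

Detection rates are obtained two ways, which serve as mutual checks:

* a Monte-Carlo stream of Gaussian samples (noise mean 1, sd 1; every k-th
  sample from a signal distribution with mean 1 + d′), thresholded on the
  per-sample spike log-likelihood L(i) = f(i)·log(Sn/B) − Sn + B with the
  threshold that maximises (true positives − false positives);
* a closed form: L is affine in f, so thresholding L equals thresholding f,
  and the count-difference objective is maximised at
  u = d′/2 + ln((1−p)/p)/d′ above the noise mean (p the spike prevalence),
  giving tp = Φ(d′ − u) and fp = Φ(−u).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import (
    DegenerateLikelihoodError,
    EmptyReportError,
    FitError,
    InvalidArgumentError,
)
from .metrics import (
    DEFAULT_BASELINE_WINDOW,
    fit_monoexponential_decay,
    _event_time,
)
from .trace import COUNTS, Trace

#: Train frequencies (Hz) up to which all spikes share one F0 computed by
#: averaging the inter-spike fluorescence maxima.
SHARED_F0_MAX_FREQ = 30.0


def dprime(dff_peak: float, f0: float, tau: float) -> float:
    """d′ = |ΔF/F| · √(F0·τ/2); F0 in photons/frame, τ in frames."""
    if dff_peak < 0 or f0 < 0 or tau < 0:
        raise InvalidArgumentError("dprime arguments must be non-negative")
    return dff_peak * math.sqrt(f0 * tau / 2.0)


@dataclass(frozen=True)
class DprimeInput:
    """Harmonised inputs for the d′ formula (F0/frame, τ in frames)."""

    dff_peak: float
    f0: float
    tau: float

    def value(self) -> float:
        return dprime(self.dff_peak, self.f0, self.tau)


@dataclass
class SpikeRecord:
    """Per-spike measurement feeding a train-level d′."""

    spike_index: int
    f0_used: float | None
    tau_used: float | None  # frames
    dff: float | None
    dprime: float | None
    included: bool
    t_peak: float | None = None
    note: str = ""


@dataclass
class DetectionReport:
    """d′ value(s) with optional ROC threshold and rates."""

    dprime: float
    threshold_L: float | None = None
    threshold_f: float | None = None
    tp_rate: float | None = None
    fp_rate: float | None = None
    per_spike: list[SpikeRecord] = field(default_factory=list)

    @property
    def inclusion_fraction(self) -> float | None:
        if not self.per_spike:
            return None
        return sum(s.included for s in self.per_spike) / len(self.per_spike)

    def as_dict(self) -> dict:
        return {
            "dprime": self.dprime,
            "threshold_L": self.threshold_L,
            "threshold_f": self.threshold_f,
            "tp_rate": self.tp_rate,
            "fp_rate": self.fp_rate,
            "inclusion_fraction": self.inclusion_fraction,
            "per_spike": [
                {
                    "spike_index": s.spike_index,
                    "f0_used": s.f0_used,
                    "tau_used_frames": s.tau_used,
                    "dff": s.dff,
                    "dprime": s.dprime,
                    "included": s.included,
                    "t_peak": s.t_peak,
                    "note": s.note,
                }
                for s in self.per_spike
            ],
        }


# --------------------------------------------------------------------------
# measured d′ from traces


def _rest_extreme(values: np.ndarray, polarity: int) -> float:
    """Inter-spike fluorescence extreme on the resting side: the maximum for
    a dimming indicator, the minimum for a brightening one."""
    return float(values.max() if polarity < 0 else values.min())


def _spike_peak(trace: Trace, start: float, stop: float) -> tuple[float, int] | None:
    idxs = np.flatnonzero((trace.times >= start) & (trace.times < stop))
    if idxs.size == 0:
        return None
    seg = trace.values[idxs] * trace.polarity
    rel = int(np.argmax(seg))
    return float(trace.values[idxs[rel]]), int(idxs[rel])


def dprime_single(
    trace: Trace,
    spike_time=None,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    search_ms: float | None = None,
) -> SpikeRecord:
    """Measure d′ for one well-isolated spike on a bleach-corrected
    photon-count trace.

    F0 is the mean count over the baseline window before the trigger; ΔF/F
    is (peak − F0)/F0; τ comes from a mono-exponential fit of the decay from
    the peak back to baseline, converted to frames.
    """
    if trace.kind != COUNTS:
        raise InvalidArgumentError("dprime_single expects a counts-kind (photon) trace")
    t_spike = _event_time(trace, spike_time, "spike_trigger")
    w0, w1 = baseline_window
    baseline = trace.window(t_spike - w0 * 1e-3, t_spike - w1 * 1e-3)
    if baseline.size == 0:
        raise InvalidArgumentError("baseline window contains no samples")
    f0 = float(baseline.mean())
    if f0 <= 0:
        raise InvalidArgumentError("baseline F0 must be positive")
    stop = t_spike + (search_ms * 1e-3 if search_ms is not None else np.inf)
    peak = _spike_peak(trace, t_spike, min(stop, trace.times[-1] + trace.dt))
    if peak is None:
        raise EmptyReportError("no samples after the spike time")
    peak_val, idx = peak
    dff_val = abs(peak_val - f0) / f0
    try:
        tau_s, _ = fit_monoexponential_decay(trace, trace.times[idx])
        tau_frames = tau_s * trace.frame_rate
    except FitError as exc:
        return SpikeRecord(0, f0, None, dff_val, None, included=False, note=str(exc))
    if not math.isfinite(tau_frames):
        # a spikeless flat trace carries zero detectability, not an error
        dp = 0.0 if dff_val < 1e-9 else None
        return SpikeRecord(0, f0, None, dff_val, dp, included=False, note="flat decay")
    return SpikeRecord(
        spike_index=0,
        f0_used=f0,
        tau_used=tau_frames,
        dff=dff_val,
        dprime=dprime(dff_val, f0, tau_frames),
        included=True,
        t_peak=float(trace.times[idx]),
    )


def dprime_train(
    trace: Trace,
    spike_times: list[float],
    train_freq: float,
) -> DetectionReport:
    """d′ for a spike train, with the frequency-dependent F0 rule.

    For trains up to 30 Hz the baseline recovers enough between spikes that
    a single F0 — the average of the inter-spike fluorescence maxima — is
    shared by all spikes. For faster trains the baseline drifts within the
    train, so F0 is computed per spike as the fluorescence extreme over the
    following inter-spike interval. τ is refitted per spike on the decay
    within its interval; spikes whose peak cannot be located or whose decay
    cannot be fitted are excluded, and the inclusion fraction is reported.

    A single-spike train reduces exactly to :func:`dprime_single`.
    """
    if trace.kind != COUNTS:
        raise InvalidArgumentError("dprime_train expects a counts-kind (photon) trace")
    spike_times = sorted(float(t) for t in spike_times)
    if not spike_times:
        raise EmptyReportError("no spike times supplied")
    if len(spike_times) == 1:
        rec = dprime_single(trace, spike_times[0])
        return DetectionReport(dprime=rec.dprime if rec.dprime is not None else float("nan"),
                               per_spike=[rec])
    isi = 1.0 / train_freq
    bounds = spike_times + [spike_times[-1] + isi]

    peaks: list[tuple[float, int] | None] = [
        _spike_peak(trace, bounds[i], bounds[i + 1]) for i in range(len(spike_times))
    ]
    if all(p is None for p in peaks):
        raise EmptyReportError("no spike peaks could be located in the trace")

    # Shared F0 for slow trains: average of the maxima between consecutive peaks.
    shared_f0 = None
    if train_freq <= SHARED_F0_MAX_FREQ:
        gap_maxima = []
        located = [p for p in peaks if p is not None]
        for (_, i0), (_, i1) in zip(located[:-1], located[1:]):
            if i1 > i0 + 1:
                gap_maxima.append(
                    _rest_extreme(trace.values[i0 + 1 : i1], trace.polarity)
                )
        if not gap_maxima:
            raise EmptyReportError("no inter-spike samples to estimate the shared F0")
        shared_f0 = float(np.mean(gap_maxima))

    records: list[SpikeRecord] = []
    for k, peak in enumerate(peaks):
        if peak is None:
            records.append(SpikeRecord(k, None, None, None, None, False, note="no peak"))
            continue
        peak_val, idx = peak
        t_peak = float(trace.times[idx])
        if shared_f0 is not None:
            f0 = shared_f0
        else:
            mask = (trace.times > t_peak) & (trace.times < bounds[k + 1])
            if not mask.any():
                records.append(
                    SpikeRecord(k, None, None, None, None, False, note="empty interval")
                )
                continue
            f0 = _rest_extreme(trace.values[mask], trace.polarity)
        if f0 <= 0:
            records.append(SpikeRecord(k, f0, None, None, None, False, note="F0 <= 0"))
            continue
        dff_val = abs(peak_val - f0) / f0
        try:
            tau_s, _ = fit_monoexponential_decay(trace, t_peak, end_time=bounds[k + 1])
        except FitError as exc:
            records.append(
                SpikeRecord(k, f0, None, dff_val, None, False, t_peak, note=str(exc))
            )
            continue
        if not math.isfinite(tau_s):
            records.append(
                SpikeRecord(k, f0, None, dff_val, None, False, t_peak, note="flat decay")
            )
            continue
        tau_frames = tau_s * trace.frame_rate
        records.append(
            SpikeRecord(
                k, f0, tau_frames, dff_val,
                dprime(dff_val, f0, tau_frames), True, t_peak,
            )
        )
    included = [r.dprime for r in records if r.included]
    if not included:
        raise EmptyReportError("no spikes survived peak location and decay fitting")
    return DetectionReport(dprime=float(np.mean(included)), per_spike=records)


# --------------------------------------------------------------------------
# ROC: Monte-Carlo stream and closed form


@dataclass(frozen=True)
class RocConfig:
    """Configuration of the simulated detection stream.

    One sample in every ``spike_period`` is drawn from the signal
    distribution Normal(1 + d′, 1); the rest from the noise distribution
    Normal(1, 1). Spikes occupy a single sample (N = 1).
    """

    n_samples: int = 10**6
    spike_period: int = 10
    noise_mean: float = 1.0
    noise_sd: float = 1.0
    n_per_spike: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.spike_period < 2:
            raise InvalidArgumentError("spike_period must be >= 2")
        if self.noise_sd != 1.0:
            raise InvalidArgumentError("the detection stream is defined with unit noise sd")
        if self.n_per_spike != 1:
            raise InvalidArgumentError("multi-sample spikes are out of scope (N = 1)")


def roc_simulate(dprime_value: float, config: RocConfig | None = None) -> DetectionReport:
    """Monte-Carlo ROC: simulate the stream, threshold the log-likelihood,
    report the empirical rates at the threshold maximising TP − FP counts.

    Ties are broken toward the lowest threshold achieving the maximum. The
    reported ``fp_rate`` is per frame (per noise sample).
    """
    if dprime_value <= 0:
        raise DegenerateLikelihoodError(
            "d' must be > 0 for a non-degenerate log-likelihood"
        )
    cfg = config or RocConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    f = rng.normal(cfg.noise_mean, cfg.noise_sd, size=n)
    sig_idx = np.arange(cfg.spike_period - 1, n, cfg.spike_period)
    f[sig_idx] = rng.normal(cfg.noise_mean + dprime_value, cfg.noise_sd, size=sig_idx.size)

    log_ratio = math.log((cfg.noise_mean + dprime_value) / cfg.noise_mean)

    sig_sorted = np.sort(f[sig_idx])
    noise_mask = np.ones(n, dtype=bool)
    noise_mask[sig_idx] = False
    noise_sorted = np.sort(f[noise_mask])
    n_sig, n_noise = sig_sorted.size, noise_sorted.size

    # Sweep thresholds at every observed value; "above threshold" is strict.
    candidates = np.sort(f)
    tp = n_sig - np.searchsorted(sig_sorted, candidates, side="right")
    fp = n_noise - np.searchsorted(noise_sorted, candidates, side="right")
    objective = tp - fp
    best = int(np.argmax(objective))  # first occurrence = lowest threshold
    thr_f = float(candidates[best])
    report = DetectionReport(
        dprime=dprime_value,
        threshold_f=thr_f,
        threshold_L=thr_f * log_ratio - dprime_value,
        tp_rate=tp[best] / n_sig,
        fp_rate=fp[best] / n_noise,
    )
    return report


def roc_analytic(
    dprime_value: float, spike_fraction: float = 0.1
) -> tuple[float, float, float]:
    """Closed-form optimum of the count-difference objective.

    Returns (threshold above the noise mean, tp_rate, fp_rate):
    u = d′/2 + ln((1−p)/p)/d′, tp = Φ(d′ − u), fp = Φ(−u).
    """
    if dprime_value <= 0:
        raise DegenerateLikelihoodError("d' must be > 0")
    if not 0.0 < spike_fraction < 1.0:
        raise InvalidArgumentError("spike_fraction must lie in (0, 1)")
    u = dprime_value / 2.0 + math.log((1.0 - spike_fraction) / spike_fraction) / dprime_value
    tp = float(norm.cdf(dprime_value - u))
    fp = float(norm.cdf(-u))
    return u, tp, fp
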