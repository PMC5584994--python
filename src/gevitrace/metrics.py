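"""Trace-level measurements: ΔF/F, noise, SNR, bleach correction and fits.

The conventions follow common practice in two-photon voltage imaging:

* ΔF/F = (F − F0)/F0 with F0 the mean fluorescence over a window
  (default 110–10 ms) preceding the spike trigger.
* Noise is the sample standard deviation of ΔF/F over the 200 ms preceding
  stimulus onset; SNR is the peak |ΔF/F| divided by that noise.
* Photobleaching is corrected either additively (fit a single exponential to
  resting segments, subtract it, and re-add its value at a reference time so
  the resting photon count stays constant — required when absolute photon
  counts feed a detectability statistic) or divisively (divide by a fitted
  double exponential, the natural choice when only fractional responses are
  needed).
* Kinetics are quantified with single- or bi-exponential least-squares fits;
  r² = 1 − SS_res/SS_tot on the fitted segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    FitError,
    InvalidArgumentError,
    InvalidReferenceError,
    InvalidTraceError,
    UndefinedSNRError,
    UndefinedVelocityError,
    WindowTooShortError,
)
from .trace import COUNTS, DFF, Event, Trace
from .waveforms import measure_fwhm

DEFAULT_BASELINE_WINDOW = (110.0, 10.0)  # ms before trigger
DEFAULT_NOISE_WINDOW_MS = 200.0  # ms before stimulus onset


# --------------------------------------------------------------------------
# result containers


@dataclass
class ResponseMetrics:
    """Shape metrics of one fluorescence response."""

    a_max: float  # |ΔF/F| at the peak
    t_peak: float  # s, absolute time of the peak
    time_to_peak: float | None = None  # s, from trigger to peak
    tau_decay: float | None = None  # s
    fwhm: float | None = None  # s
    snr: float | None = None
    noise_sd: float | None = None
    fit_r2: float | None = None
    flags: dict = field(default_factory=dict)


@dataclass
class BiExpFit:
    """Least-squares fit of a·e^(−b·t) + c·e^(−d·t) (+ offset).

    By convention ``tau_fast <= tau_slow`` (ms) and ``fraction_fast`` is the
    fast term's share of the total amplitude |a| + |c|.
    """

    a: float
    b: float  # 1/s
    c: float
    d: float  # 1/s
    offset: float
    r2: float
    near_degenerate: bool = False

    @property
    def tau_fast(self) -> float:  # ms
        return 1e3 / max(self.b, self.d)

    @property
    def tau_slow(self) -> float:  # ms
        return 1e3 / min(self.b, self.d)

    @property
    def fraction_fast(self) -> float:
        fast_amp = self.a if self.b >= self.d else self.c
        total = abs(self.a) + abs(self.c)
        return abs(fast_amp) / total if total > 0 else float("nan")


# --------------------------------------------------------------------------
# ΔF/F, noise, SNR


def _event_time(trace: Trace, which, kind: str) -> float:
    if which is None:
        return trace.first_event(kind).time
    if isinstance(which, Event):
        return which.time
    return float(which)


def compute_dff(
    trace: Trace,
    trigger=None,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> Trace:
    """Convert a photon-count trace to ΔF/F.

    F0 is the mean count over [trigger − w0, trigger − w1) ms; the window
    defaults to 110–10 ms before the spike trigger. F0 is stored on the
    result (``meta["f0"]``) so the transform is invertible.
    """
    if trace.kind != COUNTS:
        raise InvalidTraceError("compute_dff expects a counts-kind trace")
    t_trig = _event_time(trace, trigger, "spike_trigger")
    w0, w1 = baseline_window
    if w0 <= w1:
        raise InvalidArgumentError("baseline window must satisfy w0 > w1 (ms before trigger)")
    start, stop = t_trig - w0 * 1e-3, t_trig - w1 * 1e-3
    if start < trace.times[0] - 0.5 * trace.dt:
        raise WindowTooShortError(
            f"baseline window starts {trace.times[0] - start:.4f} s before the trace"
        )
    baseline = trace.window(start, stop)
    if baseline.size == 0:
        raise WindowTooShortError("baseline window contains no samples")
    f0 = float(baseline.mean())
    if f0 <= 0:
        raise InvalidTraceError(f"baseline F0 = {f0:g} must be positive")
    out = trace.with_values((trace.values - f0) / f0, kind=DFF, f0=f0)
    return out


def dff_to_counts(trace: Trace) -> Trace:
    """Invert :func:`compute_dff` using the stored F0 (exact round trip)."""
    if trace.kind != DFF or "f0" not in trace.meta:
        raise InvalidTraceError("trace is not a compute_dff output (missing f0)")
    f0 = trace.meta["f0"]
    return trace.with_values(f0 * (1.0 + trace.values), kind=COUNTS)


def baseline_noise(
    trace: Trace,
    stimulus_onset=None,
    window_ms: float = DEFAULT_NOISE_WINDOW_MS,
) -> float:
    """Sample standard deviation of the window (default 200 ms) ending at
    stimulus onset."""
    t_on = _event_time(trace, stimulus_onset, "stimulus_onset")
    start = t_on - window_ms * 1e-3
    if start < trace.times[0] - 0.5 * trace.dt:
        shortfall = trace.times[0] - start
        raise WindowTooShortError(
            f"need {window_ms:g} ms of pre-stimulus data; short by {shortfall * 1e3:.1f} ms"
        )
    vals = trace.window(start, t_on)
    if vals.size < 2:
        raise WindowTooShortError("noise window contains fewer than 2 samples")
    return float(np.std(vals, ddof=1))


def peak_amplitude(trace: Trace, trigger=None, search_ms: float | None = None) -> tuple[float, int]:
    """|peak| ΔF/F after the trigger, honouring the trace polarity.

    Returns (amplitude, sample index). ``search_ms`` limits the search
    window after the trigger."""
    t_trig = _event_time(trace, trigger, "spike_trigger")
    mask = trace.times >= t_trig
    if search_ms is not None:
        mask &= trace.times < t_trig + search_ms * 1e-3
    idxs = np.flatnonzero(mask)
    if idxs.size == 0:
        raise InvalidArgumentError("no samples after the trigger")
    seg = trace.values[idxs] * trace.polarity
    rel = int(np.argmax(seg))
    return float(abs(trace.values[idxs[rel]])), int(idxs[rel])


def refine_peak_time(trace: Trace, idx: int) -> float:
    """Sub-sample peak time by 3-point parabolic interpolation.

    For a smooth transient sampled near its extremum, fitting a parabola
    through the peak sample and its neighbours removes most of the
    frame-quantization error in the peak time. Falls back to the sample time
    at the trace boundary or where the three points are collinear.
    """
    if idx <= 0 or idx >= trace.n - 1:
        return float(trace.times[idx])
    y0, y1, y2 = trace.values[idx - 1 : idx + 2]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(trace.times[idx])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(trace.times[idx] + delta * trace.dt)


def snr(trace: Trace, trigger=None, stimulus_onset=None, search_ms: float | None = None) -> float:
    """Peak |ΔF/F| divided by the pre-stimulus noise standard deviation.

    ``search_ms`` restricts the peak search to a window after the trigger,
    which avoids crediting shot-noise extremes far from the response."""
    if trace.kind != DFF:
        raise InvalidTraceError("snr expects a dff-kind trace")
    noise = baseline_noise(trace, stimulus_onset)
    if noise == 0:
        raise UndefinedSNRError("baseline noise is zero; SNR undefined")
    amp, _ = peak_amplitude(trace, trigger, search_ms=search_ms)
    return amp / noise


# --------------------------------------------------------------------------
# exponential fitting primitives


def _r2(y: np.ndarray, fit: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum((y - fit) ** 2)) / ss_tot


def fit_monoexponential(
    times: np.ndarray,
    values: np.ndarray,
    with_offset: bool = True,
) -> tuple[float, float, float, float]:
    """Fit A·e^(−t/τ) + C by nonlinear least squares with multi-start over
    decades of τ. Times are rebased to the first sample.

    Returns (A, tau [s], C, r2). A flat input returns (0, inf, mean, nan).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < (4 if with_offset else 3):
        raise FitError("too few points for an exponential fit")
    t = t - t[0]
    span = t[-1] if t[-1] > 0 else 1.0
    if np.ptp(y) <= 1e-12 * max(1.0, abs(y.mean())):
        return 0.0, math.inf, float(y.mean()), float("nan")

    c0 = y[-1] if with_offset else 0.0
    a0 = y[0] - c0
    best = None
    for tau0 in (span / 30.0, span / 10.0, span / 3.0, span, span * 3.0):
        try:
            if with_offset:
                popt, _ = curve_fit(
                    lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
                    t, y, p0=[a0, tau0, c0], maxfev=10000,
                    bounds=([-np.inf, span * 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                )
                a, tau, c = popt
            else:
                popt, _ = curve_fit(
                    lambda tt, a, tau: a * np.exp(-tt / tau),
                    t, y, p0=[a0 if a0 != 0 else y[0], tau0], maxfev=10000,
                    bounds=([-np.inf, span * 1e-6], [np.inf, np.inf]),
                )
                a, tau = popt
                c = 0.0
        except (RuntimeError, ValueError):
            continue
        fit = a * np.exp(-t / tau) + c
        ssr = float(np.sum((y - fit) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, a, tau, c, fit)
    if best is None:
        raise FitError(
            "mono-exponential fit failed to converge",
            diagnostics={"n": int(t.size), "span_s": float(span)},
        )
    _, a, tau, c, fit = best
    return float(a), float(tau), float(c), _r2(y, fit)


def fit_biexponential(segment, with_offset: bool = True) -> BiExpFit:
    """Fit a·e^(−b·t) + c·e^(−d·t) (+ offset) to a monotone-trend segment.

    ``segment`` is a :class:`Trace` or a (times, values) pair; times are
    rebased to the segment start. Multi-start over pairs of decade-spaced
    time constants; the best sum of squares wins. A near-degenerate fit
    (b ≈ d within 5%) is flagged rather than rejected.
    """
    if isinstance(segment, Trace):
        t, y = segment.times, segment.values
    else:
        t, y = segment
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < (6 if with_offset else 5):
        raise FitError("too few points for a bi-exponential fit")
    t = t - t[0]
    span = t[-1] if t[-1] > 0 else 1.0

    off0 = y[-1] if with_offset else 0.0
    amp0 = y[0] - off0
    if amp0 == 0:
        amp0 = np.ptp(y) or 1.0

    def model(tt, a, b, c, d, off):
        return a * np.exp(-b * tt) + c * np.exp(-d * tt) + off

    starts = []
    for tf in (span / 300.0, span / 100.0, span / 30.0, span / 10.0):
        for ts in (span / 10.0, span / 3.0, span):
            if ts > tf:
                starts.append((tf, ts))
    best = None
    for tf0, ts0 in starts:
        p0 = [0.6 * amp0, 1.0 / tf0, 0.4 * amp0, 1.0 / ts0, off0]
        if not with_offset:
            p0 = p0[:4]
        inf = np.inf
        try:
            if with_offset:
                popt, _ = curve_fit(
                    model, t, y, p0=p0, maxfev=20000,
                    bounds=([-inf, 0.0, -inf, 0.0, -inf], [inf, inf, inf, inf, inf]),
                )
                a, b, c, d, off = popt
            else:
                popt, _ = curve_fit(
                    lambda tt, a, b, c, d: model(tt, a, b, c, d, 0.0),
                    t, y, p0=p0, maxfev=20000,
                    bounds=([-inf, 0.0, -inf, 0.0], [inf, inf, inf, inf]),
                )
                a, b, c, d = popt
                off = 0.0
        except (RuntimeError, ValueError):
            continue
        fit = model(t, a, b, c, d, off)
        ssr = float(np.sum((y - fit) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, a, b, c, d, off, fit)
    if best is None:
        raise FitError(
            "bi-exponential fit failed to converge after multi-start",
            diagnostics={"n": int(t.size), "span_s": float(span)},
        )
    _, a, b, c, d, off, fit = best
    hi, lo = max(b, d), min(b, d)
    near_deg = hi > 0 and (hi - lo) / hi < 0.05
    return BiExpFit(
        a=float(a), b=float(b), c=float(c), d=float(d),
        offset=float(off), r2=_r2(y, fit), near_degenerate=bool(near_deg),
    )


def fit_monoexponential_decay(
    trace: Trace,
    peak_time: float,
    end_time: float | None = None,
) -> tuple[float, float]:
    """Fit the decay from a response peak back toward baseline with a single
    exponential. Returns (tau [s], r2). Fewer than 5 points is an error; a
    flat segment returns tau = inf."""
    mask = trace.times >= peak_time
    if end_time is not None:
        mask &= trace.times <= end_time
    t = trace.times[mask]
    y = trace.values[mask]
    if t.size < 5:
        raise FitError(f"decay segment has {t.size} points; need at least 5")
    _, tau, _, r2 = fit_monoexponential(t, y, with_offset=True)
    return float(tau), float(r2)


# --------------------------------------------------------------------------
# photobleaching correction


def bleach_correct_additive(
    trace: Trace,
    rest_segments: list[tuple[float, float]],
    reference_time: float,
) -> Trace:
    """Additive bleach correction that keeps the resting photon count
    constant at its value at ``reference_time`` (typically the start of the
    first spike).

    A single exponential (plus offset) g(t) is fitted to the resting
    segments; the corrected trace is f(t) − g(t) + g(reference_time). When
    the fit is exact the rest level is constant and spike heights (in
    photons) are unchanged.
    """
    if not rest_segments:
        raise InvalidArgumentError("rest_segments must be non-empty")
    if not (trace.times[0] <= reference_time <= trace.times[-1]):
        raise InvalidArgumentError("reference_time lies outside the trace")
    mask = np.zeros(trace.n, dtype=bool)
    for start, stop in rest_segments:
        mask |= (trace.times >= start) & (trace.times < stop)
    if mask.sum() < 4:
        raise InvalidArgumentError("rest segments contain too few samples to fit")
    a, tau, c, r2 = fit_monoexponential(trace.times[mask], trace.values[mask])
    t0 = trace.times[mask][0]
    g = a * np.exp(-(trace.times - t0) / tau) + c if math.isfinite(tau) else np.full(trace.n, c)
    g_ref = float(np.interp(reference_time, trace.times, g))
    corrected = trace.values - g + g_ref
    return trace.with_values(
        corrected,
        bleach_fit={"a": a, "tau_s": tau, "offset": c, "r2": r2},
        bleach_reference_time=reference_time,
    )


def bleach_correct_divisive(trace: Trace) -> Trace:
    """Divisive bleach correction: ΔF/F(t) = (F(t) − g₂(t)) / g₂(t) with g₂
    a double-exponential fit to the whole series (the fitted value at each
    time serves as F0)."""
    fit = fit_biexponential((trace.times, trace.values), with_offset=False)
    t = trace.times - trace.times[0]
    g2 = fit.a * np.exp(-fit.b * t) + fit.c * np.exp(-fit.d * t)
    if np.any(g2 <= 0):
        raise FitError("fitted bleach curve crosses zero", diagnostics={"fit": fit})
    out = trace.with_values(
        (trace.values - g2) / g2,
        kind=DFF,
        bleach_fit={"a": fit.a, "b": fit.b, "c": fit.c, "d": fit.d, "r2": fit.r2},
    )
    return out


# --------------------------------------------------------------------------
# response shape, binning, propagation


def peak_metrics(
    trace: Trace,
    trigger=None,
    search_ms: float | None = None,
    stimulus_onset=None,
) -> ResponseMetrics:
    """Peak amplitude, time-to-peak, FWHM and decay constant of a response.

    FWHM is measured by linear interpolation at the half-height crossings;
    when the response never recrosses half height (e.g. the peak sits at the
    trace boundary) FWHM is reported absent and flagged. τ_decay comes from
    :func:`fit_monoexponential_decay`; SNR/noise are filled in when a
    stimulus onset is available.
    """
    if trace.kind != DFF:
        raise InvalidTraceError("peak_metrics expects a dff-kind trace")
    t_trig = _event_time(trace, trigger, "spike_trigger")
    amp, idx = peak_amplitude(trace, trigger=t_trig, search_ms=search_ms)
    t_peak = float(trace.times[idx])
    flags: dict = {}

    seg_mask = trace.times >= t_trig
    fwhm = measure_fwhm(trace.times[seg_mask], trace.values[seg_mask])
    if math.isnan(fwhm):
        fwhm = None
        flags["fwhm_absent"] = True

    tau_decay = r2 = None
    try:
        tau_decay, r2 = fit_monoexponential_decay(trace, t_peak)
        if not math.isfinite(tau_decay):
            flags["flat_decay"] = True
            tau_decay = None
    except FitError as exc:
        flags["decay_fit_failed"] = str(exc)

    snr_val = noise = None
    try:
        noise = baseline_noise(trace, stimulus_onset)
        if noise > 0:
            snr_val = amp / noise
    except (WindowTooShortError, InvalidTraceError):
        pass

    return ResponseMetrics(
        a_max=amp,
        t_peak=t_peak,
        time_to_peak=t_peak - t_trig,
        tau_decay=tau_decay,
        fwhm=fwhm,
        snr=snr_val,
        noise_sd=noise,
        fit_r2=r2,
        flags=flags,
    )


def bin_timepoints(trace: Trace, k: int) -> Trace:
    """Bin ``k`` adjacent time points: counts are summed (emulating a k-fold
    longer dwell), ΔF/F is averaged; the frame rate drops k-fold. A trailing
    partial bin is dropped."""
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k == 1:
        return trace.with_values(trace.values.copy())
    n_bins = trace.n // k
    if n_bins == 0:
        raise InvalidArgumentError(f"trace of {trace.n} samples cannot be binned by {k}")
    vals = trace.values[: n_bins * k].reshape(n_bins, k)
    times = trace.times[: n_bins * k].reshape(n_bins, k).mean(axis=1)
    binned = vals.sum(axis=1) if trace.kind == COUNTS else vals.mean(axis=1)
    out = Trace(
        times=times,
        values=binned,
        kind=trace.kind,
        frame_rate=trace.frame_rate / k,
        voxel_id=trace.voxel_id,
        trial_id=trace.trial_id,
        events=[ev for ev in trace.events if times[0] <= ev.time <= times[-1]],
        polarity=trace.polarity,
        meta={**trace.meta, "bin_factor": k},
    )
    sched = out.meta.get("schedule")
    if isinstance(sched, dict) and "dwell_time_us" in sched:
        out.meta["schedule"] = {
            **sched,
            "dwell_time_us": sched["dwell_time_us"] * k,
            "frame_rate_hz": sched.get("frame_rate_hz", trace.frame_rate) / k,
        }
    return out


def conduction_velocity(
    peak_times: list[tuple[float, float]],
) -> tuple[float, list[float]]:
    """Conduction velocity (m/s) from (distance [µm], peak time [s]) pairs.

    Fits distance = v × delay by least squares through the soma reference
    (the distance-0 entry); also returns the pairwise velocities of each
    dendritic point against the soma.
    """
    if len(peak_times) < 2:
        raise InvalidArgumentError("need at least two (distance, t_peak) points")
    soma = [tp for d, tp in peak_times if d == 0]
    if not soma:
        raise InvalidArgumentError("a soma reference (distance 0) is required")
    t0 = soma[0]
    d = np.array([dd for dd, _ in peak_times], dtype=float) * 1e-6  # m
    delay = np.array([tp - t0 for _, tp in peak_times], dtype=float)  # s
    if np.allclose(delay, 0.0):
        raise UndefinedVelocityError("all peak delays are zero; velocity undefined")
    v = float(np.sum(d * delay) / np.sum(delay**2))
    pairwise = [
        float(dd * 1e-6 / (tp - t0)) if tp != t0 else math.inf
        for dd, tp in peak_times
        if dd > 0
    ]
    return v, pairwise


def attenuation_profile(
    amplitudes: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Percent reduction of peak amplitude versus the soma, per location.

    Input: (distance [µm], a_max) pairs including a distance-0 soma
    reference. Output: (distance, percent_reduction) pairs.
    """
    soma = [a for d, a in amplitudes if d == 0]
    if not soma:
        raise InvalidReferenceError("a soma reference (distance 0) is required")
    a0 = soma[0]
    if a0 == 0:
        raise InvalidReferenceError("soma amplitude is zero")
    return [(d, (1.0 - a / a0) * 100.0) for d, a in amplitudes]


def amplitude_f0_correlation(a_maxes, f0s) -> tuple[float, float]:
    """Pearson correlation (r, p) between response amplitude and resting
    photon rate; used to check that amplitudes at locations of different
    brightness are comparable (the expectation is no correlation)."""
    from scipy.stats import pearsonr

    r, p = pearsonr(np.asarray(a_maxes, float), np.asarray(f0s, float))
    return float(r), float(p)


def percent_improvement(new: float, old: float) -> float:
    """Percent improvement of |new| over |old|: (|new|/|old| − 1) × 100."""
    if old == 0:
        raise InvalidArgumentError("reference value must be nonzero")
    return (abs(new) / abs(old) - 1.0) * 100.0
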