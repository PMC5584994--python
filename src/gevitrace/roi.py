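"""ROI-level analysis of stimulus-locked responses.

Designed for imaging experiments in which a periodic stimulus (alternating
dark and light flashes) drives many regions of interest at a frame rate that
is slow and incommensurate with the stimulus period. Frames are re-timed
relative to the stimulus cycle and pooled across repeats with a simple
moving average on a fine regular grid, which recovers an effective temporal
resolution finer than the frame rate.

An ROI counts as *responding* when time-matched points of the dark-flash and
light-flash responses differ significantly (two-sample t-test, p < 0.01) for
at least three consecutive grid points — ROIs whose receptive fields missed
the stimulus fail this criterion. Each phase (depolarising dark response,
hyperpolarising light response) is quantified by its peak amplitude A_max,
time-to-peak t_peak, and decay constant τ_decay; τ_decay is reported only
when the single-exponential fit achieves r² > 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ttest_ind

from .errors import FitError, InsufficientTrialsError, InvalidArgumentError
from .metrics import ResponseMetrics, fit_monoexponential
from .trace import Trace

DARK_TO_LIGHT = "dark_to_light"
LIGHT_TO_DARK = "light_to_dark"

#: Minimum r² for a decay fit to be reported.
TAU_DECAY_MIN_R2 = 0.5


@dataclass(frozen=True)
class StimulusProtocol:
    """Alternating-flash stimulus and averaging parameters.

    ``transition_times`` is a sorted list of (time [s], label) with labels
    alternating between ``light_to_dark`` (a dark flash begins) and
    ``dark_to_light``. A cycle is one dark flash followed by one light
    flash. ``timing_shift_ms`` is a hardware-specific constant subtracted
    from frame times before re-timing (default 0).
    """

    transition_times: tuple[tuple[float, str], ...]
    flash_duration_ms: float = 300.0
    frame_rate: float = 38.9
    average_window_ms: float = 25.0
    average_shift_ms: float = 8.33
    timing_shift_ms: float = 0.0

    def __post_init__(self):
        labels = [lab for _, lab in self.transition_times]
        for lab in labels:
            if lab not in (DARK_TO_LIGHT, LIGHT_TO_DARK):
                raise InvalidArgumentError(f"unknown transition label {lab!r}")
        for a, b in zip(labels[:-1], labels[1:]):
            if a == b:
                raise InvalidArgumentError("transition labels must alternate")
        if self.average_shift_ms > self.average_window_ms:
            raise InvalidArgumentError("average_shift must be <= average_window")

    @classmethod
    def alternating(
        cls, n_cycles: int, start: float = 0.0, flash_duration_ms: float = 300.0, **kw
    ) -> "StimulusProtocol":
        """Dark/light alternation: each cycle is dark then light flash."""
        flash = flash_duration_ms * 1e-3
        transitions = []
        for k in range(n_cycles):
            t0 = start + k * 2 * flash
            transitions.append((t0, LIGHT_TO_DARK))
            transitions.append((t0 + flash, DARK_TO_LIGHT))
        return cls(
            transition_times=tuple(transitions),
            flash_duration_ms=flash_duration_ms,
            **kw,
        )

    @property
    def cycle_period(self) -> float:
        return 2.0 * self.flash_duration_ms * 1e-3

    def cycle_starts(self) -> np.ndarray:
        return np.array(
            [t for t, lab in self.transition_times if lab == LIGHT_TO_DARK], dtype=float
        )


@dataclass
class AveragedResponse:
    """Stimulus-locked moving-average response on a regular grid.

    ``grid`` holds times relative to cycle start (dark-flash onset), spaced
    by the configured shift. ``counts`` is the number of frames inside each
    grid point's averaging window; windows with no frames are NaN in
    ``values`` and flagged in ``gaps``.
    """

    grid: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    per_cycle: np.ndarray  # cycles × grid, NaN where a window is empty

    @property
    def gaps(self) -> np.ndarray:
        return self.counts == 0


def stimulus_locked_average(trace: Trace, protocol: StimulusProtocol) -> AveragedResponse:
    """Re-time frames relative to their stimulus cycle and average.

    Each frame is assigned to the most recent cycle start; a moving average
    with the protocol's window, evaluated every shift, pools frames across
    all complete cycles. Per-cycle rows are retained for trial-resolved
    statistics.
    """
    starts = protocol.cycle_starts()
    if starts.size < 2:
        raise InvalidArgumentError("need at least 2 stimulus cycles")
    period = protocol.cycle_period
    shift = protocol.average_shift_ms * 1e-3
    half_win = protocol.average_window_ms * 1e-3 / 2.0
    t = trace.times - protocol.timing_shift_ms * 1e-3

    grid = np.arange(0.0, period - 1e-12, shift)
    n_cycles = starts.size
    per_cycle = np.full((n_cycles, grid.size), np.nan)
    counts = np.zeros(grid.size, dtype=int)
    sums = np.zeros(grid.size)

    cycle_idx = np.searchsorted(starts, t, side="right") - 1
    for ic in range(n_cycles):
        in_cycle = cycle_idx == ic
        t_rel = t[in_cycle] - starts[ic]
        keep = t_rel < period
        t_rel = t_rel[keep]
        vals = trace.values[in_cycle][keep]
        if t_rel.size == 0:
            continue
        for ig, g in enumerate(grid):
            sel = np.abs(t_rel - g) <= half_win
            if sel.any():
                per_cycle[ic, ig] = vals[sel].mean()
                counts[ig] += int(sel.sum())
                sums[ig] += float(vals[sel].sum())

    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AveragedResponse(grid=grid, values=mean, counts=counts, per_cycle=per_cycle)


def responding_roi_test(
    dark_responses: np.ndarray,
    light_responses: np.ndarray,
    alpha: float = 0.01,
    min_consecutive: int = 3,
    equal_var: bool = True,
) -> bool:
    """Is this ROI responding? t-test at each time-matched grid point; true
    iff at least ``min_consecutive`` consecutive points have p < alpha.

    Inputs are trials × timepoints matrices on matched grids.
    """
    dark = np.asarray(dark_responses, dtype=float)
    light = np.asarray(light_responses, dtype=float)
    if dark.ndim != 2 or light.ndim != 2 or dark.shape[1] != light.shape[1]:
        raise InvalidArgumentError("responses must be trials × timepoints on matched grids")
    if dark.shape[0] < 2 or light.shape[0] < 2:
        raise InsufficientTrialsError("need at least 2 trials per phase")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = ttest_ind(dark, light, axis=0, equal_var=equal_var, nan_policy="omit")
    sig = np.asarray(pvals) < alpha
    run = 0
    for s in sig:
        run = run + 1 if s else 0
        if run >= min_consecutive:
            return True
    return False


def quantify_phase_response(
    grid: np.ndarray,
    values: np.ndarray,
    phase_window: tuple[float, float],
) -> ResponseMetrics:
    """A_max / t_peak / τ_decay for one stimulus phase of an averaged
    response. ``phase_window`` is (start, end) in seconds on the grid's
    time base; t_peak is reported relative to the phase (flash) start.
    τ_decay is included only when the decay fit reaches r² > 0.5."""
    t0, t1 = phase_window
    mask = (grid >= t0) & (grid < t1) & np.isfinite(values)
    if not mask.any():
        raise InvalidArgumentError("phase window contains no finite grid points")
    tt = grid[mask]
    vv = values[mask]
    ipk = int(np.argmax(np.abs(vv)))
    a_max = float(abs(vv[ipk]))
    t_peak = float(tt[ipk])
    flags: dict = {}
    tau = r2 = None
    decay_t, decay_v = tt[ipk:], vv[ipk:]
    if decay_t.size >= 5:
        try:
            _, tau_s, _, r2_val = fit_monoexponential(decay_t, decay_v)
            if math.isfinite(tau_s) and not math.isnan(r2_val) and r2_val > TAU_DECAY_MIN_R2:
                tau, r2 = float(tau_s), float(r2_val)
            else:
                flags["tau_decay_excluded"] = f"r2={r2_val:.3g}" if not math.isnan(r2_val) else "flat"
        except FitError as exc:
            flags["tau_decay_excluded"] = str(exc)
    else:
        flags["tau_decay_excluded"] = "too few decay points"
    return ResponseMetrics(
        a_max=a_max,
        t_peak=t_peak,
        time_to_peak=t_peak - t0,
        tau_decay=tau,
        fit_r2=r2,
        flags=flags,
    )


@dataclass
class RoiRecord:
    """Summary of one ROI: responding flag and per-phase metrics."""

    roi_id: str | int
    responding: bool
    dark: ResponseMetrics | None = None
    light: ResponseMetrics | None = None
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        def metrics_dict(m: ResponseMetrics | None):
            if m is None:
                return None
            return {
                "a_max": m.a_max,
                "t_peak_s": m.t_peak,
                "time_to_peak_s": m.time_to_peak,
                "tau_decay_s": m.tau_decay,
                "fit_r2": m.fit_r2,
                "flags": m.flags,
            }

        return {
            "roi_id": self.roi_id,
            "responding": self.responding,
            "dark": metrics_dict(self.dark),
            "light": metrics_dict(self.light),
            **self.meta,
        }


def analyze_roi(trace: Trace, protocol: StimulusProtocol, roi_id=None) -> RoiRecord:
    """Full single-ROI pipeline: stimulus-locked average, responding test on
    the dark-vs-light per-cycle matrices, per-phase quantification."""
    avg = stimulus_locked_average(trace, protocol)
    flash = protocol.flash_duration_ms * 1e-3
    dark_cols = avg.grid < flash
    light_cols = (avg.grid >= flash) & (avg.grid < 2 * flash)
    n_pts = min(dark_cols.sum(), light_cols.sum())
    responding = responding_roi_test(
        avg.per_cycle[:, np.flatnonzero(dark_cols)[:n_pts]],
        avg.per_cycle[:, np.flatnonzero(light_cols)[:n_pts]],
    )
    dark = quantify_phase_response(avg.grid, avg.values, (0.0, flash))
    light = quantify_phase_response(avg.grid, avg.values, (flash, 2 * flash))
    return RoiRecord(
        roi_id=roi_id if roi_id is not None else trace.voxel_id,
        responding=responding,
        dark=dark,
        light=light,
        meta={"n_cycles": int(avg.per_cycle.shape[0])},
    )
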