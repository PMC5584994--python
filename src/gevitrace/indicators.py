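"""Indicator kinetics: direction-dependent bi-exponential relaxation models.

A GEVI's fluorescence response to a voltage step is well described by a
weighted sum of two exponentials whose time constants depend on the direction
of the step. Four transition regimes are distinguished, named after the step
protocols used to measure them:

* ``depolarization``                      — rest → depolarised
* ``repolarization_from_depolarized``     — depolarised → rest
* ``hyperpolarization``                   — rest → hyperpolarised
* ``repolarization_from_hyperpolarized``  — hyperpolarised → rest

Each regime carries (tau_fast [ms], tau_slow [ms], fraction_fast). The
steady-state response is a voltage → ΔF/F curve stored as ordered anchor
points and interpolated piecewise-linearly (clamped outside the span).

Presets for ASAP1, ASAP2s and ArcLight Q239 ship the published HEK293A
constants measured at 22 °C. The steady-state anchor at +30 mV encodes the
response to a 100 mV step from −70 mV (−38.7% for ASAP2s, −23.3% for ASAP1);
the anchor at −100 mV is a configuration default, since published
hyperpolarisation responses are graphical only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

REGIMES = (
    "depolarization",
    "repolarization_from_depolarized",
    "hyperpolarization",
    "repolarization_from_hyperpolarized",
)


@dataclass(frozen=True)
class Transition:
    """One relaxation regime: weighted sum of two exponentials."""

    tau_fast: float  # ms
    tau_slow: float  # ms
    fraction_fast: float  # dimensionless, in [0, 1]

    def __post_init__(self):
        if not self.tau_fast > 0:
            raise InvalidArgumentError("tau_fast must be positive")
        if self.tau_slow < self.tau_fast:
            raise InvalidArgumentError("tau_slow must be >= tau_fast")
        if not 0.0 <= self.fraction_fast <= 1.0:
            raise InvalidArgumentError("fraction_fast must lie in [0, 1]")


@dataclass(frozen=True)
class IndicatorKinetics:
    """Named indicator: four transition regimes plus a steady-state F–V curve.

    ``fv_curve`` is an ordered list of (voltage [mV], steady-state ΔF/F)
    anchors, strictly monotone in voltage and passing through
    (holding_potential, 0).
    """

    name: str
    transitions: dict[str, Transition]
    fv_curve: tuple[tuple[float, float], ...]
    holding_potential: float = -70.0  # mV

    def __post_init__(self):
        missing = set(REGIMES) - set(self.transitions)
        if missing:
            raise InvalidArgumentError(f"missing transition regimes: {sorted(missing)}")
        volts = np.array([v for v, _ in self.fv_curve], dtype=float)
        if volts.size < 2 or np.any(np.diff(volts) <= 0):
            raise InvalidArgumentError("fv_curve must be strictly monotone in voltage")
        dff_at_rest = self._interp(np.array([self.holding_potential]))[0]
        if abs(dff_at_rest) > 1e-9:
            raise InvalidArgumentError(
                "fv_curve must pass through (holding_potential, 0); "
                f"got ΔF/F={dff_at_rest:g} at {self.holding_potential} mV"
            )

    def _interp(self, voltage: np.ndarray) -> np.ndarray:
        volts = np.array([v for v, _ in self.fv_curve], dtype=float)
        dff = np.array([d for _, d in self.fv_curve], dtype=float)
        return np.interp(voltage, volts, dff)  # np.interp clamps at the ends

    def steady_state_dff(self, voltage) -> np.ndarray | float:
        """Steady-state ΔF/F at the given voltage(s), clamped to the anchor span."""
        v = np.asarray(voltage, dtype=float)
        out = self._interp(np.atleast_1d(v))
        return float(out[0]) if v.ndim == 0 else out

    def voltage_span(self) -> tuple[float, float]:
        volts = [v for v, _ in self.fv_curve]
        return min(volts), max(volts)

    @property
    def response_sign(self) -> int:
        """Sign of the steady-state response to depolarisation (−1 for ASAPs)."""
        hi = self.fv_curve[-1][1]
        return -1 if hi < 0 else 1


def _preset(name, depol, repol_d, hyper, repol_h, ss_depol, ss_hyper):
    return IndicatorKinetics(
        name=name,
        transitions={
            "depolarization": Transition(*depol),
            "repolarization_from_depolarized": Transition(*repol_d),
            "hyperpolarization": Transition(*hyper),
            "repolarization_from_hyperpolarized": Transition(*repol_h),
        },
        fv_curve=((-100.0, ss_hyper), (-70.0, 0.0), (30.0, ss_depol)),
    )


# Published bi-exponential constants (HEK293A cells, 22 °C):
# (tau_fast ms, tau_slow ms, fraction fast). Steady-state anchors: the +30 mV
# value is the published response to a 100 mV step; the −100 mV value is a
# configuration default (see module docstring).
PRESETS: dict[str, IndicatorKinetics] = {
    "ASAP1": _preset(
        "ASAP1",
        depol=(2.9, 161.0, 0.74),
        repol_d=(2.3, 177.0, 0.63),
        hyper=(11.0, 131.0, 0.59),
        repol_h=(15.0, 131.0, 0.52),
        ss_depol=-0.233,
        ss_hyper=0.08,
    ),
    "ASAP2s": _preset(
        "ASAP2s",
        depol=(5.2, 63.0, 0.56),
        repol_d=(24.0, 106.0, 0.49),
        hyper=(8.2, 104.0, 0.53),
        repol_h=(13.0, 114.0, 0.51),
        ss_depol=-0.387,
        ss_hyper=0.12,
    ),
    "ArcLight": _preset(
        "ArcLight",
        depol=(20.0, 267.0, 0.37),
        repol_d=(113.0, 367.0, 0.53),
        hyper=(20.0, 208.0, 0.49),
        repol_h=(42.0, 265.0, 0.57),
        ss_depol=-0.33,
        ss_hyper=0.10,
    ),
}


def get_indicator(name: str) -> IndicatorKinetics:
    """Look up a packaged indicator preset by name (case-insensitive)."""
    for key, val in PRESETS.items():
        if key.lower() == name.lower():
            return val
    raise InvalidArgumentError(
        f"unknown indicator {name!r}; available: {sorted(PRESETS)}"
    )
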