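"""Tracer infusion protocol and the input function u(t).

The SILK protocol delivers ``13C6``-leucine as a short intravenous bolus
followed by a constant-rate infusion; the tracer is available for protein
synthesis only during the label window (bolus + infusion, 9 h by default).
The model input is the *normalized* step function ``u(t)`` whose infusion
plateau is 1, so the tracer-availability compartment g(t) saturates at or
below 1 under realistic kinetic rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InfusionProtocol", "tracer_input"]


@dataclass(frozen=True)
class InfusionProtocol:
    """Bolus + infusion tracer delivery schedule.

    Parameters
    ----------
    bolus_duration : float
        Duration of the initial bolus in hours (default 10 min).
    bolus_rate : float
        Delivery rate during the bolus, in dose units per hour. The default
        corresponds to 2 mg/kg delivered over 10 min.
    infusion_duration : float
        Duration of the constant infusion in hours (default 8 h 50).
    infusion_rate : float
        Delivery rate during the infusion (default 2 mg/kg/h).
    total_label_window : float
        Time after which no tracer is available (default 9 h).
    input_shape : str
        ``"two_level"`` keeps the bolus/infusion step structure;
        ``"single_level"`` collapses u(t) to a unit step over the whole
        label window (an accepted simplification).
    availability_rate : float
        First-order rate (1/h) at which the tracer-availability compartment
        g(t) equilibrates with the delivered input, g' = k_g (u(t) - g).
        This reflects the precursor pool feeding protein synthesis
        (intracellular free leucine and aminoacyl-tRNA, plus secretory
        transit), which decays much more slowly than plasma free leucine;
        it is a property of the tracer and the subject rather than of any
        one protein, so it is a fixed model constant (not fitted) shared by
        all model variants. The default of 0.15/h lets RIA curves keep
        rising well past the 9 h label window, as slow-turnover proteins do.
    """

    bolus_duration: float = 10.0 / 60.0
    bolus_rate: float = 12.0
    infusion_duration: float = 8.0 + 50.0 / 60.0
    infusion_rate: float = 2.0
    total_label_window: float = 9.0
    input_shape: str = "two_level"
    availability_rate: float = 0.15

    def __post_init__(self) -> None:
        for name in ("bolus_duration", "bolus_rate", "infusion_duration",
                     "infusion_rate", "total_label_window",
                     "availability_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.input_shape not in ("two_level", "single_level"):
            raise ValueError(f"unknown input_shape {self.input_shape!r}")

    # -- raw input (dose-rate units) ---------------------------------------
    def rate_at(self, t: float) -> float:
        """Raw delivery rate at time ``t`` (piecewise constant)."""
        if t < 0:
            raise ValueError("tracer input is undefined for t < 0")
        if t >= self.total_label_window:
            return 0.0
        if t < self.bolus_duration:
            return self.bolus_rate
        return self.infusion_rate

    # -- normalized input used by the kinetic models ----------------------
    def levels(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints and normalized u(t) levels on each interval.

        Returns ``(breaks, levels)`` where u(t) = levels[i] on
        ``[breaks[i], breaks[i+1])`` and 0 after ``breaks[-1]``.
        """
        if self.input_shape == "single_level":
            level = 1.0 if (self.infusion_rate > 0 or self.bolus_rate > 0) \
                else 0.0
            return (np.array([0.0, self.total_label_window]),
                    np.array([level]))
        scale = self.infusion_rate if self.infusion_rate > 0 \
            else (self.bolus_rate if self.bolus_rate > 0 else 1.0)
        breaks = np.array([0.0, self.bolus_duration, self.total_label_window])
        return breaks, np.array([self.bolus_rate / scale,
                                 self.infusion_rate / scale])

    def u(self, t: float) -> float:
        """Normalized input level at time ``t``."""
        if t < 0:
            raise ValueError("tracer input is undefined for t < 0")
        breaks, levels = self.levels()
        if t >= breaks[-1]:
            return 0.0
        idx = int(np.searchsorted(breaks, t, side="right") - 1)
        return float(levels[idx])


def tracer_input(protocol: InfusionProtocol, t: float) -> float:
    """Raw tracer delivery rate at time ``t`` (dose units per hour).

    Piecewise constant: bolus rate on ``[0, bolus_duration)``, infusion rate
    on ``[bolus_duration, total_label_window)``, 0 afterwards. Raises
    ``ValueError`` for negative ``t``.
    """
    return protocol.rate_at(t)
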