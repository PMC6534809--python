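"""Diel light schedule (light:dark cycle) used to phase growth and
rhythm analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class LightSchedule:
    """Periodic light:dark cycle.

    ``dawn_h`` is the time of lights-on relative to experiment start,
    ``photoperiod_h`` the length of the light phase, ``cycle_h`` the full
    cycle (default 12:12 h light:dark).
    """

    dawn_h: float = 0.0
    photoperiod_h: float = 12.0
    cycle_h: float = 24.0

    def __post_init__(self) -> None:
        if not 0.0 < self.photoperiod_h < self.cycle_h:
            raise ConfigurationError("need 0 < photoperiod < cycle")

    def is_light(self, t) -> np.ndarray:
        f = np.mod(np.asarray(t, dtype=float) - self.dawn_h, self.cycle_h)
        return f < self.photoperiod_h

    def first_dusk_h(self) -> float:
        """First lights-off time at or after t = 0."""
        dusk = self.dawn_h + self.photoperiod_h
        return float(np.mod(dusk, self.cycle_h))

    def phase_of_interval(self, t0: float, t1: float) -> str:
        """Classify [t0, t1]: 'light', 'dark', or 'transition' if it
        spans a lights-on/off boundary."""
        if t1 < t0:
            raise ConfigurationError("interval end before start")
        # transition times are dawn + k*cycle and dusk + k*cycle
        for offset in (0.0, self.photoperiod_h):
            k0 = np.ceil((t0 - self.dawn_h - offset) / self.cycle_h)
            boundary = self.dawn_h + offset + k0 * self.cycle_h
            if boundary <= t0:
                boundary += self.cycle_h
            if t0 < boundary < t1:
                return "transition"
        return "light" if bool(self.is_light((t0 + t1) / 2.0)) else "dark"
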