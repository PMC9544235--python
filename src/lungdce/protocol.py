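"""Acquisition protocol for the whole-chest VFA + dynamic SPGR exam.

The defaults mirror a 1.5 T coronal spoiled-gradient-echo lung protocol:
TR/TE = 2.03/0.83 ms, VFA flip angles 4/2/7/10 degrees (10 repeats each),
then a dynamic series of 170 volumes at 2.5 s/volume with a half-dose
gadolinium bolus injected at the start of the 15th dynamic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

#: Gadobutrol longitudinal relaxivity at 1.5 T, L mmol^-1 s^-1 (literature value).
DEFAULT_RELAXIVITY = 5.0

#: Native T1 of whole blood at 1.5 T, ms (literature value).
DEFAULT_BLOOD_T1_MSEC = 1440.0

#: Hematocrit fallback when no per-subject value is supplied.
DEFAULT_HEMATOCRIT = 0.42


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing, flip-angle and contrast-dose parameters of one DCE exam.

    ``injection_dynamic`` is the 1-based index of the first post-injection
    dynamic volume; dynamics ``1 .. injection_dynamic - 1`` form the
    pre-contrast baseline. Dynamic ``k`` is acquired at ``(k - 1) * dt_sec``
    seconds (half-open convention: each stamp marks the start of its volume).
    """

    tr_msec: float = 2.03
    te_msec: float = 0.83
    flip_angles_deg: tuple[float, ...] = (4.0, 2.0, 7.0, 10.0)
    vfa_repeats: int = 10
    n_dynamics: int = 170
    dt_sec: float = 2.5
    injection_dynamic: int = 15
    dynamic_flip_deg: float = 10.0
    dose_mmol_per_kg: float = 0.05
    relaxivity_per_mM_per_sec: float = DEFAULT_RELAXIVITY
    field_strength_T: float = 1.5

    def __post_init__(self) -> None:
        if self.tr_msec <= 0 or self.te_msec <= 0 or self.dt_sec <= 0:
            raise ValueError("tr_msec, te_msec and dt_sec must be positive")
        if len(self.flip_angles_deg) == 0:
            raise ValueError("at least one VFA flip angle is required")
        for a in self.flip_angles_deg:
            if not 0.0 < a <= 90.0:
                raise ValueError(f"flip angle {a} deg outside (0, 90]")
        if not 0.0 < self.dynamic_flip_deg <= 90.0:
            raise ValueError("dynamic flip angle outside (0, 90]")
        if self.n_dynamics < 2:
            raise ValueError("n_dynamics must be >= 2")
        if not 2 <= self.injection_dynamic <= self.n_dynamics:
            raise ValueError(
                "injection_dynamic must lie in [2, n_dynamics] so that a "
                "pre-contrast baseline exists"
            )
        if self.vfa_repeats < 1:
            raise ValueError("vfa_repeats must be >= 1")
        if self.dose_mmol_per_kg <= 0:
            raise ValueError("dose must be positive")
        if self.relaxivity_per_mM_per_sec <= 0:
            raise ValueError("relaxivity must be positive")

    @property
    def dynamic_times_sec(self) -> np.ndarray:
        """Start time of each dynamic volume, seconds from series start."""
        return np.arange(self.n_dynamics) * self.dt_sec

    @property
    def n_baseline(self) -> int:
        """Number of pre-injection dynamics."""
        return self.injection_dynamic - 1

    @property
    def injection_time_sec(self) -> float:
        """Time of the start of the first post-injection dynamic."""
        return (self.injection_dynamic - 1) * self.dt_sec

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flip_angles_deg"] = list(self.flip_angles_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        d = dict(d)
        if "flip_angles_deg" in d:
            d["flip_angles_deg"] = tuple(float(a) for a in d["flip_angles_deg"])
        return cls(**d)
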