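"""Time-integrated activity (cumulated activity) and residence times.

Turns per-organ uptake time-series into the quantity phantom dose software
consumes: the integral of the organ's fraction of injected activity over
time (MBq*h per MBq injected, i.e. hours), computed by trapezoidal
integration of the *non-decay-corrected* curve with a configurable
extrapolation beyond the last sample.

Numerical conventions
---------------------
* An anchor point (0, 0) is prepended: the tracer is injected intravenously
  at t=0, so organ activity starts at zero.
* Decay-corrected input curves are automatically un-corrected before
  integration (cumulated activity must include physical decay); the state
  is tracked by an explicit flag, never guessed.
* Tail beyond the last sample: ``physical_decay`` (default; only physical
  decay, biological retention assumed — conservative), ``zero`` (truncate),
  or ``fitted_exp`` (biological rate fitted log-linearly to the last points,
  floored at zero, added to the physical rate).

No organ can outlive the isotope: every residence time is bounded by
``half_life / ln 2 = 1.443 * half_life`` hours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from predose.quantify import CU64_HALF_LIFE_H

TAIL_MODES = ("physical_decay", "zero", "fitted_exp")


@dataclass
class TimeActivityCurve:
    """Fraction of injected activity in one organ versus time."""

    organ: str
    times_h: np.ndarray
    fraction_in_organ: np.ndarray
    decay_corrected: bool
    half_life_h: float = CU64_HALF_LIFE_H

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.fraction_in_organ = np.asarray(self.fraction_in_organ, dtype=float)
        if self.times_h.size != self.fraction_in_organ.size:
            raise ValueError("times and fractions must have equal length")
        if self.times_h.size and (
            np.any(self.times_h <= 0) or np.any(np.diff(self.times_h) <= 0)
        ):
            raise ValueError("times must be strictly increasing and > 0")
        if np.any(self.fraction_in_organ < 0) or np.any(self.fraction_in_organ > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")


@dataclass
class ResidenceTimeSet:
    """Per-source-organ residence times tau (hours per unit injected)."""

    taus_h: Dict[str, float]
    tail_mode: str = "physical_decay"
    remainder_included: bool = False
    half_life_h: float = CU64_HALF_LIFE_H

    def __post_init__(self) -> None:
        bound = 1.443 * self.half_life_h
        for organ, tau in self.taus_h.items():
            if tau < 0:
                raise ValueError(f"negative residence time for {organ}")
        total = sum(self.taus_h.values())
        if total > bound * (1 + 1e-9):
            raise ValueError(
                f"total residence time {total:.3f} h exceeds the pure-decay "
                f"bound {bound:.3f} h"
            )


def to_organ_fraction(pid_per_g: float, organ_mass_g: float) -> float:
    """%ID/g times organ mass over 100: the fraction of injected activity.

    A result above 1 (more than the whole injected dose in one organ) is
    physically inconsistent and raises rather than being silently clipped.
    """
    if pid_per_g < 0 or organ_mass_g <= 0:
        raise ValueError("pid_per_g must be >= 0 and organ_mass_g > 0")
    frac = pid_per_g * organ_mass_g / 100.0
    if frac > 1.0:
        raise ValueError(
            f"organ fraction {frac:.3f} exceeds 1: %ID/g and organ mass are "
            "inconsistent with the injected dose"
        )
    return frac


def integrate_tia(curve: TimeActivityCurve, tail_mode: str = "physical_decay",
                  tail_fit_points: int = 3) -> float:
    """Cumulated activity (hours) by trapezoidal integration plus a tail.

    The integral runs over ``[(0, 0)] + samples`` of the non-decay-corrected
    curve; see the module docstring for tail conventions.
    """
    if tail_mode not in TAIL_MODES:
        raise ValueError(f"tail_mode must be one of {TAIL_MODES}")
    t = curve.times_h
    if t.size < 2:
        raise ValueError("need >= 2 time points to integrate")
    a = curve.fraction_in_organ
    if curve.decay_corrected:  # integration needs the physical curve
        a = a * 2.0 ** (-t / curve.half_life_h)
    tt = np.concatenate([[0.0], t])
    aa = np.concatenate([[0.0], a])
    tia = float(np.trapezoid(aa, tt))

    lam_phys = math.log(2.0) / curve.half_life_h
    a_last = float(a[-1])
    if tail_mode == "zero" or a_last <= 0:
        tail = 0.0
    elif tail_mode == "physical_decay":
        tail = a_last / lam_phys
    else:  # fitted_exp: biological rate from the decay-corrected late points
        n = max(2, min(tail_fit_points, t.size))
        tf = t[-n:]
        af_bio = a[-n:] * 2.0 ** (tf / curve.half_life_h)
        if np.any(af_bio <= 0):
            lam_fit = 0.0
        else:
            slope = np.polyfit(tf, np.log(af_bio), 1)[0]
            lam_fit = max(0.0, -float(slope))
        tail = a_last / (lam_phys + lam_fit)
    return tia + tail


def residence_time(tia_h: float) -> float:
    """Residence time tau = cumulated activity per unit injected activity.

    With activities normalised to 1 MBq injected this is the identity; it is
    kept as an explicit named step of the schema.
    """
    if tia_h < 0:
        raise ValueError("cumulated activity must be >= 0")
    return float(tia_h)


def remainder_of_body(
    organ_taus: ResidenceTimeSet,
    whole_body_curve: Optional[TimeActivityCurve] = None,
    tail_mode: str = "physical_decay",
) -> float:
    """Residence time of the remainder-of-body source.

    With a whole-body curve, the remainder is the whole-body residence time
    minus the organ total, floored at zero (with a warning if negative).
    Without one no remainder can be inferred; zero is returned with a
    warning rather than assuming unmeasured retention.
    """
    organ_total = sum(organ_taus.taus_h.values())
    if whole_body_curve is None:
        warnings.warn(
            "no whole-body curve supplied; remainder-of-body residence time "
            "set to 0",
            stacklevel=2,
        )
        return 0.0
    tau_wb = residence_time(integrate_tia(whole_body_curve, tail_mode=tail_mode))
    rem = tau_wb - organ_total
    if rem < 0:
        warnings.warn(
            f"organ residence times ({organ_total:.3f} h) exceed the "
            f"whole-body value ({tau_wb:.3f} h); remainder floored at 0",
            stacklevel=2,
        )
        return 0.0
    return rem


def build_tac(
    measurements,
    organ: str,
    organ_mass_g: float,
    half_life_h: float = CU64_HALF_LIFE_H,
) -> TimeActivityCurve:
    """Average replicate animals of one organ into a TimeActivityCurve.

    ``measurements`` is a long-format table with columns ``organ``,
    ``time_h``, ``pid_per_g`` and ``decay_corrected`` (one consistent state
    per organ).
    """
    sub = measurements[measurements["organ"] == organ]
    if sub.empty:
        raise ValueError(f"no measurements for organ {organ!r}")
    states = sub["decay_corrected"].unique()
    if len(states) != 1:
        raise ValueError(f"mixed decay-correction states for organ {organ!r}")
    prof = sub.groupby("time_h", sort=True)["pid_per_g"].mean()
    fractions = np.array(
        [to_organ_fraction(v, organ_mass_g) for v in prof.to_numpy()]
    )
    return TimeActivityCurve(
        organ=organ,
        times_h=prof.index.to_numpy(dtype=float),
        fraction_in_organ=fractions,
        decay_corrected=bool(states[0]),
        half_life_h=half_life_h,
    )
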