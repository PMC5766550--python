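"""Quantification of raw biodistribution measurements.

Converts gamma-counter counts (or pre-quantified ROI values) into percent
injected dose per gram (%ID/g), manages physical-decay correction state, and
computes the descriptive statistics used in preclinical tracer studies:
target-to-background uptake ratios, caliper tumor volumes and unpaired
two-tailed Student's t comparisons between cohorts.

Conventions
-----------
%ID/g is defined as ``100 * (organ counts - background) / (injected-dose
counts * organ mass in g)``, optionally decay-corrected back to the time of
injection.  Decay correction multiplies by ``2**(t / half_life)``;
un-correction is its exact inverse.  Every quantified value carries a
``decay_corrected`` flag so downstream integration knows which state it is in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

#: Physical half-life of Cu-64 in hours.
CU64_HALF_LIFE_H = 12.7


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OrganMeasurement:
    """One raw observation of one organ of one animal at one time point.

    Exactly one of ``raw_counts_cpm`` / ``pid_per_g`` must be present: a
    measurement is either a gamma-counter reading awaiting quantification or
    an already-quantified %ID/g value (e.g. from a PET ROI).
    """

    animal_id: str
    group: str
    organ: str
    time_h: float
    organ_mass_g: float
    raw_counts_cpm: Optional[float] = None
    background_cpm: Optional[float] = None
    pid_per_g: Optional[float] = None
    injected_dose_cpm_equiv: Optional[float] = None
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        if (self.raw_counts_cpm is None) == (self.pid_per_g is None):
            raise ValueError(
                "exactly one of raw_counts_cpm / pid_per_g must be present"
            )
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")
        if self.organ_mass_g <= 0:
            raise ValueError(f"organ_mass_g must be > 0, got {self.organ_mass_g}")
        if (
            self.raw_counts_cpm is not None
            and self.background_cpm is not None
            and self.raw_counts_cpm < self.background_cpm
        ):
            raise ValueError("raw_counts_cpm must be >= background_cpm")


@dataclass
class TumorGeometry:
    """Caliper dimensions of a subcutaneous tumor, millimetres."""

    length_mm: float
    width_mm: float
    height_mm: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("length_mm", "width_mm", "height_mm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")


class UptakeRatio(NamedTuple):
    ratio: float
    sd: float


class GroupComparison(NamedTuple):
    t: float
    p: float
    significant: bool


# ---------------------------------------------------------------------------
# decay management
# ---------------------------------------------------------------------------


def decay_correct(x, t_h, half_life_h: float = CU64_HALF_LIFE_H):
    """Rescale a measured activity-like value to its value at injection time.

    Multiplies by ``2**(t/half_life)``; exact inverse of :func:`decay_uncorrect`.
    """
    if half_life_h <= 0:
        raise ValueError(f"half_life_h must be > 0, got {half_life_h}")
    t_h = np.asarray(t_h, dtype=float)
    if np.any(t_h < 0):
        raise ValueError("t_h must be >= 0")
    out = np.asarray(x, dtype=float) * 2.0 ** (t_h / half_life_h)
    return float(out) if out.ndim == 0 else out


def decay_uncorrect(x, t_h, half_life_h: float = CU64_HALF_LIFE_H):
    """Apply physical decay to an injection-time value; inverse of decay_correct."""
    if half_life_h <= 0:
        raise ValueError(f"half_life_h must be > 0, got {half_life_h}")
    t_h = np.asarray(t_h, dtype=float)
    if np.any(t_h < 0):
        raise ValueError("t_h must be >= 0")
    out = np.asarray(x, dtype=float) * 2.0 ** (-t_h / half_life_h)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


def cpm_to_pid_per_g(
    m: OrganMeasurement,
    half_life_h: float = CU64_HALF_LIFE_H,
    correct_to_injection: bool = True,
) -> float:
    """Convert a gamma-counter measurement to %ID/g.

    Background-subtracts, normalises by the counts-per-minute equivalent of
    the injected dose and the organ mass, and (optionally) decay-corrects
    back to the time of injection.  The resulting decay-correction state
    equals ``correct_to_injection``.
    """
    if m.raw_counts_cpm is None:
        raise ValueError("measurement has no raw_counts_cpm")
    if m.injected_dose_cpm_equiv is None or m.injected_dose_cpm_equiv <= 0:
        raise ValueError("injected_dose_cpm_equiv must be present and > 0")
    bg = m.background_cpm or 0.0
    net = m.raw_counts_cpm - bg
    if net < 0:
        raise ValueError("background exceeds raw counts")
    pid = 100.0 * net / (m.injected_dose_cpm_equiv * m.organ_mass_g)
    if correct_to_injection:
        pid = decay_correct(pid, m.time_h, half_life_h)
    return float(pid)


def uptake_ratio(
    target_values: Sequence[float], reference_values: Sequence[float]
) -> UptakeRatio:
    """Mean(target)/mean(reference) with first-order propagated SD.

    The two samples must share a decay-correction state (the ratio is
    invariant to a common decay factor, so either state gives the same
    answer as long as it is common).
    """
    t = np.asarray(target_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("both value lists must be non-empty")
    mt, mr = t.mean(), r.mean()
    if mr == 0:
        raise ValueError("reference mean is zero")
    ratio = mt / mr
    st = t.std(ddof=1) if t.size > 1 else 0.0
    sr = r.std(ddof=1) if r.size > 1 else 0.0
    sd = abs(ratio) * math.sqrt((st / mt) ** 2 + (sr / mr) ** 2) if mt != 0 else 0.0
    return UptakeRatio(float(ratio), float(sd))


def tumor_volume(g: TumorGeometry, estimate_height: bool = False) -> float:
    """Ellipsoid tumor volume V = pi*h*w*l/6 in mm^3.

    When the height cannot be measured by caliper it is estimated as
    two-thirds of the length (``h = 2l/3``).
    """
    h = g.height_mm
    if h is None:
        if not estimate_height:
            raise ValueError("height missing and estimate_height=False")
        h = 2.0 * g.length_mm / 3.0
    return math.pi * h * g.width_mm * g.length_mm / 6.0


def group_compare(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> GroupComparison:
    """Unpaired two-tailed Student's t test (classical pooled variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return GroupComparison(t, p, p < alpha)
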