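"""Mouse-to-human extrapolation by relative organ mass.

The interspecies scaling converts a mouse organ concentration into a human
per-organ uptake:

    (%ID/organ)_human = (%ID/g)_mouse * M_body,mouse * M_organ,human / M_body,human

(all masses in grams).  Applied pointwise over a time-activity curve it
preserves times and decay-correction state, and — being linear — commutes
with time integration.  Composing the scaling with trapezoidal integration
yields human-equivalent residence times ready for S-value dose weighting.

Organs measured in the mouse but absent from the human phantom (e.g. the
tumor itself, or a blood sample whose pool the heart ROI already carries)
are excluded from scaling and reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Tuple

import pandas as pd

from predose.kinetics import (
    ResidenceTimeSet,
    TimeActivityCurve,
    integrate_tia,
    residence_time,
)
from predose.quantify import CU64_HALF_LIFE_H
from predose.synthetic import MOUSE_ORGAN_MASS_G

#: Default mapping from measured-organ names to phantom source organs.
#: ``None`` means the organ has no phantom counterpart and is excluded from
#: human scaling (reported separately).  The heart ROI of an antibody tracer
#: is dominated by the blood pool, so it feeds the "heart contents" source;
#: a separate ex-vivo blood sample would duplicate that pool and is excluded.
DEFAULT_SOURCE_MAP: Dict[str, Optional[str]] = {
    "heart": "heart_contents",
    "blood": None,
    "tumor": None,
    "large_intestine": "uli_wall",
    "stomach": "stomach_wall",
}


@dataclass
class HumanPhantom:
    """Reference human phantom: organ masses and total body mass, grams."""

    phantom_id: str
    organ_mass_g: Dict[str, float]
    total_body_mass_g: float

    def __post_init__(self) -> None:
        if self.total_body_mass_g <= 0:
            raise ValueError("total_body_mass_g must be > 0")
        for organ, m in self.organ_mass_g.items():
            if m <= 0:
                raise ValueError(f"mass of {organ} must be > 0")
        if sum(self.organ_mass_g.values()) > self.total_body_mass_g:
            raise ValueError("organ masses exceed total body mass")


@dataclass
class AnimalContext:
    """The source animal: body mass and (optionally) organ masses, grams."""

    body_mass_g: float = 23.0
    organ_mass_g: Dict[str, float] = field(
        default_factory=lambda: dict(MOUSE_ORGAN_MASS_G)
    )

    def __post_init__(self) -> None:
        if self.body_mass_g <= 0:
            raise ValueError("body_mass_g must be > 0")


def load_phantom(path=None) -> HumanPhantom:
    """Load a phantom organ-mass table (CSV: organ, mass_g).

    Without a path, the packaged 73.7 kg adult-male phantom is used; its
    ``total_body`` row supplies the body mass.
    """
    if path is None:
        src = resources.files("predose.data") / "phantom_adult_male.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
        phantom_id = "adult_male"
    else:
        df = pd.read_csv(path)
        phantom_id = str(path)
    masses = dict(zip(df["organ"], df["mass_g"].astype(float)))
    total = masses.pop("total_body", None)
    if total is None:
        raise ValueError("phantom table must include a total_body row")
    return HumanPhantom(phantom_id=phantom_id, organ_mass_g=masses, total_body_mass_g=total)


def kirschner_scale(
    mouse_pid_per_g,
    animal: AnimalContext,
    phantom: HumanPhantom,
    organ: str,
):
    """Human-equivalent %ID/organ from a mouse %ID/g value (or array).

    Pointwise linear in the input, so it preserves times and decay-
    correction state when applied over a curve.
    """
    if organ not in phantom.organ_mass_g:
        raise KeyError(f"organ {organ!r} not present in phantom {phantom.phantom_id!r}")
    factor = (
        animal.body_mass_g
        * phantom.organ_mass_g[organ]
        / phantom.total_body_mass_g
    )
    return mouse_pid_per_g * factor


def human_residence_times(
    measurements: pd.DataFrame,
    animal: AnimalContext,
    phantom: HumanPhantom,
    tail_mode: str = "physical_decay",
    half_life_h: float = CU64_HALF_LIFE_H,
    source_map: Optional[Dict[str, Optional[str]]] = None,
) -> Tuple[ResidenceTimeSet, Dict[str, float]]:
    """Human-equivalent residence times from a mouse measurement table.

    For each organ: average replicate animals per time point, scale each
    point to human %ID/organ, convert to a fraction, and integrate
    trapezoidally with the requested tail.  Returns the residence-time set
    of phantom source organs plus a separate map of mouse residence times
    (in mouse organ-fraction units) for organs excluded from scaling.
    """
    smap = dict(DEFAULT_SOURCE_MAP)
    if source_map:
        smap.update(source_map)
    taus: Dict[str, float] = {}
    excluded: Dict[str, float] = {}
    for organ in sorted(measurements["organ"].unique()):
        sub = measurements[measurements["organ"] == organ]
        states = sub["decay_corrected"].unique()
        if len(states) != 1:
            raise ValueError(f"mixed decay-correction states for organ {organ!r}")
        prof = sub.groupby("time_h", sort=True)["pid_per_g"].mean()
        source = smap.get(organ, organ)
        if source is None or source not in phantom.organ_mass_g:
            if source is not None:
                warnings.warn(
                    f"organ {organ!r} has no phantom counterpart; excluded "
                    "from human scaling",
                    stacklevel=2,
                )
            # report the mouse-side residence time separately
            mass = animal.organ_mass_g.get(organ, 1.0)
            curve = TimeActivityCurve(
                organ=organ,
                times_h=prof.index.to_numpy(dtype=float),
                fraction_in_organ=prof.to_numpy() * mass / 100.0,
                decay_corrected=bool(states[0]),
                half_life_h=half_life_h,
            )
            excluded[organ] = residence_time(integrate_tia(curve, tail_mode=tail_mode))
            continue
        human_pid = kirschner_scale(prof.to_numpy(), animal, phantom, source)
        curve = TimeActivityCurve(
            organ=source,
            times_h=prof.index.to_numpy(dtype=float),
            fraction_in_organ=human_pid / 100.0,
            decay_corrected=bool(states[0]),
            half_life_h=half_life_h,
        )
        tau = residence_time(integrate_tia(curve, tail_mode=tail_mode))
        taus[source] = taus.get(source, 0.0) + tau
    return (
        ResidenceTimeSet(
            taus_h=taus,
            tail_mode=tail_mode,
            remainder_included=False,
            half_life_h=half_life_h,
        ),
        excluded,
    )
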