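"""MIRD-schema organ dosimetry, ICRP effective-dose weighting and limits.

The absorbed dose coefficient of a target organ T is the residence-time-
weighted sum over source organs S of precomputed S-values:

    D_T [uSv/MBq] = sum_S tau_S [h] * S(T<-S) [mSv/(MBq*h)] * 1000

S-values are *consumed as data* (they embody phantom Monte Carlo transport,
which is out of scope here).  For tests and end-to-end property checks a
small synthetic Cu-64 adult-male S-value generator is provided, built from
first-order physics: locally absorbed non-penetrating (beta/Auger) energy,
a cube-root self-absorbed fraction for the annihilation-photon component,
and a uniform whole-body photon cross-fire term.

Two tissue-weighting schemes are shipped: ICRP Publication 60 (effective
dose; mass-weighted remainder) and ICRP Publication 26 (effective dose
equivalent; five highest remaining organs at 0.06 each).  Regulatory limits
follow the classical research-subject rules: 50 mSv/y (30 mSv per study)
whole body / gonads / blood-forming organs, 150 mSv/y (50 mSv per study)
for other organs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd
import yaml

from predose.humanize import HumanPhantom
from predose.kinetics import ResidenceTimeSet

# Cu-64 mean energy emitted per decay, MeV: beta-/beta+ plus Auger
# (non-penetrating) and annihilation + gamma photons (penetrating).
CU64_DELTA_NP_MEV = 0.125
CU64_DELTA_P_MEV = 0.186
_J_PER_MEV_PER_MBQ_H = 1.602e-13 * 3.6e9  # decays per MBq*h times J per MeV


# ---------------------------------------------------------------------------
# S-value matrix
# ---------------------------------------------------------------------------


@dataclass
class SValueMatrix:
    """S-values S(target <- source) in mSv/(MBq*h) for one radionuclide."""

    radionuclide: str
    phantom_id: str
    entries: Dict[Tuple[str, str], float]

    def __post_init__(self) -> None:
        for (t, s), v in self.entries.items():
            if v < 0:
                raise ValueError(f"negative S-value for ({t} <- {s})")
        for t in self.targets:
            if self.entries.get((t, t), 0.0) <= 0 and t in self.sources:
                raise ValueError(f"target {t!r} lacks a positive self-dose entry")

    @property
    def targets(self):
        return sorted({t for t, _ in self.entries})

    @property
    def sources(self):
        return sorted({s for _, s in self.entries})

    @classmethod
    def from_csv(cls, path, radionuclide="Cu-64", phantom_id="adult_male"):
        df = pd.read_csv(path)
        entries = {
            (r.target, r.source): float(r.S_mSv_per_MBq_h) for r in df.itertuples()
        }
        return cls(radionuclide=radionuclide, phantom_id=phantom_id, entries=entries)

    def to_csv(self, path) -> None:
        rows = [
            {"target": t, "source": s, "S_mSv_per_MBq_h": v}
            for (t, s), v in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def synthetic_cu64_svalue_matrix(
    phantom: HumanPhantom,
    sources: Optional[Sequence[str]] = None,
    wall_from_contents_af: float = 0.10,
    photon_body_af: float = 0.30,
) -> SValueMatrix:
    """Synthetic Cu-64 S-value matrix from first-order absorbed-fraction physics.

    This is a stand-in fixture for a published phantom S-value table, for
    tests and qualitative end-to-end runs; production dosimetry should load
    a real table with :meth:`SValueMatrix.from_csv`.

    Model: non-penetrating energy is absorbed entirely in the source organ
    (for the heart-contents source, a fraction ``wall_from_contents_af``
    reaches the heart wall); the photon component has a self-absorbed
    fraction ``min(0.35, 0.0137 * m_g**(1/3))`` and a uniform whole-body
    cross-fire term ``photon_body_af / m_body``.  A ``remainder`` source is
    included with its activity spread over the non-itemised body mass.
    """
    e_np = CU64_DELTA_NP_MEV * _J_PER_MEV_PER_MBQ_H  # J/(MBq*h)
    e_p = CU64_DELTA_P_MEV * _J_PER_MEV_PER_MBQ_H
    masses_kg = {o: m / 1000.0 for o, m in phantom.organ_mass_g.items()}
    body_kg = phantom.total_body_mass_g / 1000.0
    if sources is None:
        sources = sorted(masses_kg)
    # heart contents (the blood pool) is a source-only region: it receives
    # no reportable organ dose of its own
    targets = sorted(o for o in masses_kg if o != "heart_contents")
    cross_p = e_p * photon_body_af / body_kg  # Gy/(MBq*h), any T from any S
    m_rem_kg = body_kg - sum(masses_kg.values())

    entries: Dict[Tuple[str, str], float] = {}
    for s in list(sources) + ["remainder"]:
        for t in targets:
            val = cross_p
            if s == "remainder":
                val += e_np / m_rem_kg  # uniform concentration in the remainder
            elif t == s:
                phi_self = min(0.35, 0.0137 * phantom.organ_mass_g[t] ** (1.0 / 3.0))
                val += e_np / masses_kg[s] + e_p * phi_self / masses_kg[t]
            elif s == "heart_contents" and t == "heart_wall":
                val += e_np * wall_from_contents_af / masses_kg[t]
            entries[(t, s)] = val * 1000.0  # Gy == Sv here; report mSv
    return SValueMatrix(
        radionuclide="Cu-64", phantom_id=phantom.phantom_id, entries=entries
    )


def organ_doses(
    taus: ResidenceTimeSet | Dict[str, float], s: SValueMatrix
) -> Dict[str, float]:
    """Absorbed dose coefficients D_T = sum_S tau_S * S(T<-S), in uSv/MBq."""
    tau_map = taus.taus_h if isinstance(taus, ResidenceTimeSet) else dict(taus)
    targets = s.targets
    doses = {t: 0.0 for t in targets}
    for source, tau in tau_map.items():
        if tau < 0:
            raise ValueError(f"negative residence time for {source}")
        for t in targets:
            try:
                sval = s.entries[(t, source)]
            except KeyError:
                raise KeyError(
                    f"S-value matrix has no entry for (target={t!r}, "
                    f"source={source!r})"
                ) from None
            doses[t] += tau * sval * 1000.0  # mSv -> uSv
    return doses


# ---------------------------------------------------------------------------
# tissue weighting
# ---------------------------------------------------------------------------


@dataclass
class TissueWeightScheme:
    """A tissue-weighting factor scheme (ICRP 26 or 60 conventions)."""

    scheme_id: str
    weights: Dict[str, float]
    remainder_rule: str
    remainder_weight: float
    gonads_organ: str = "testes"
    remainder_organs: Sequence[str] = field(default_factory=list)
    remainder_excluded: Sequence[str] = field(default_factory=list)
    aliases: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()) or self.remainder_weight < 0:
            raise ValueError("weights must be >= 0")
        total = sum(self.weights.values()) + self.remainder_weight
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights plus remainder must sum to 1, got {total}")


def _load_scheme(name: str) -> TissueWeightScheme:
    src = resources.files("predose.data") / name
    with resources.as_file(src) as p, open(p) as fh:
        payload = yaml.safe_load(fh)
    return TissueWeightScheme(
        scheme_id=payload["scheme_id"],
        weights=payload["weights"],
        remainder_rule=payload["remainder_rule"],
        remainder_weight=payload["remainder_weight"],
        gonads_organ=payload.get("gonads_organ", "testes"),
        remainder_organs=payload.get("remainder_organs", []),
        remainder_excluded=payload.get("remainder_excluded", []),
        aliases=payload.get("aliases", {}),
    )


def icrp60_scheme() -> TissueWeightScheme:
    """ICRP-60 effective-dose weights with mass-weighted remainder."""
    return _load_scheme("weights_icrp60.yaml")


def icrp26_scheme() -> TissueWeightScheme:
    """ICRP-26 effective-dose-equivalent weights, top-5 remainder at 0.06."""
    return _load_scheme("weights_icrp26.yaml")


def _aliased_doses(
    organ_dose: Dict[str, float],
    scheme: TissueWeightScheme,
    phantom: HumanPhantom,
) -> Dict[str, float]:
    """Resolve organ aliases (ULI/LLI -> colon mass-weighted, thymus ->
    esophagus surrogate, gonads organ) into scheme tissue names."""
    doses = dict(organ_dose)
    groups: Dict[str, list] = {}
    for organ, tissue in scheme.aliases.items():
        if organ in doses:
            groups.setdefault(tissue, []).append(organ)
    for tissue, organs in groups.items():
        w = [phantom.organ_mass_g.get(o, 1.0) for o in organs]
        doses[tissue] = sum(doses[o] * wi for o, wi in zip(organs, w)) / sum(w)
    if scheme.gonads_organ in doses:
        doses["gonads"] = doses[scheme.gonads_organ]
    return doses


def effective_dose(
    organ_dose: Dict[str, float],
    scheme: Optional[TissueWeightScheme] = None,
    phantom: Optional[HumanPhantom] = None,
) -> float:
    """ICRP-60 effective dose: ED = sum_T w_T * H_T, uSv/MBq.

    The colon dose is the mass-weighted ULI/LLI combination, the thymus
    stands in for the esophagus, and the remainder term is the mass-weighted
    mean dose of the remainder-organ set times the remainder weight.
    Tissues missing from the input default to zero with a warning.
    """
    from predose.humanize import load_phantom

    if scheme is None:
        scheme = icrp60_scheme()
    if phantom is None:
        phantom = load_phantom()
    doses = _aliased_doses(organ_dose, scheme, phantom)
    ed = 0.0
    for tissue, w in scheme.weights.items():
        if tissue not in doses:
            warnings.warn(f"tissue {tissue!r} missing; dose taken as 0", stacklevel=2)
        ed += w * doses.get(tissue, 0.0)
    rem = [o for o in scheme.remainder_organs if o in doses]
    if rem:
        masses = [phantom.organ_mass_g.get(o, 1.0) for o in rem]
        mean = sum(doses[o] * m for o, m in zip(rem, masses)) / sum(masses)
        ed += scheme.remainder_weight * mean
    return ed


def effective_dose_equivalent(
    organ_dose: Dict[str, float],
    scheme: Optional[TissueWeightScheme] = None,
    phantom: Optional[HumanPhantom] = None,
) -> float:
    """ICRP-26 effective dose equivalent, uSv/MBq.

    Named tissues carry their ICRP-26 weights; the five highest-dosed
    remaining organs receive 0.06 each (all remaining organs, with a
    warning, if fewer than five are available).
    """
    from predose.humanize import load_phantom

    if scheme is None:
        scheme = icrp26_scheme()
    if phantom is None:
        phantom = load_phantom()
    doses = _aliased_doses(organ_dose, scheme, phantom)
    ede = 0.0
    for tissue, w in scheme.weights.items():
        if tissue not in doses:
            warnings.warn(f"tissue {tissue!r} missing; dose taken as 0", stacklevel=2)
        ede += w * doses.get(tissue, 0.0)
    consumed = set(scheme.weights) | set(scheme.remainder_excluded) | {"gonads"}
    candidates = {
        o: d
        for o, d in organ_dose.items()
        if o not in consumed and scheme.weights.get(o) is None
    }
    n_slots = 5
    top = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))[:n_slots]
    if len(candidates) < n_slots:
        warnings.warn(
            f"only {len(candidates)} remainder organs available (5 expected)",
            stacklevel=2,
        )
    per_slot = scheme.remainder_weight / n_slots
    ede += per_slot * sum(d for _, d in top)
    return ede


# ---------------------------------------------------------------------------
# limits and reporting
# ---------------------------------------------------------------------------

#: Organ-dose rows that are whole-body summaries, not target organs.
_SUMMARY_ROWS = {"total_body", "effective_dose", "effective_dose_equivalent"}


def dose_limiting_organ(organ_dose: Dict[str, float]) -> str:
    """The organ attaining the maximum dose coefficient (lexicographic ties)."""
    organs = {o: d for o, d in organ_dose.items() if o not in _SUMMARY_ROWS}
    if not organs:
        raise ValueError("organ dose map is empty")
    return min(organs, key=lambda o: (-organs[o], o))


@dataclass
class RegulatoryLimits:
    """Research-subject dose limits, mSv."""

    whole_body_annual: float = 50.0
    whole_body_single: float = 30.0
    other_organ_annual: float = 150.0
    other_organ_single: float = 50.0

    def __post_init__(self) -> None:
        if self.whole_body_single > self.whole_body_annual:
            raise ValueError("whole-body single-study limit exceeds annual")
        if self.other_organ_single > self.other_organ_annual:
            raise ValueError("organ single-study limit exceeds annual")


def administrable_activity(
    organ_dose: Dict[str, float],
    effective_dose_uSv_per_MBq: float,
    limits: Optional[RegulatoryLimits] = None,
    per_scan_MBq: float = 185.0,
) -> Dict[str, float]:
    """Maximum administrable activity (MBq) under each regulatory constraint.

    Each constraint is limit (uSv) divided by the governing coefficient
    (uSv/MBq): the per-organ limits divide by the maximum organ dose, the
    whole-body limits by the effective dose.  The binding constraint is the
    minimum.  ``scans_per_year`` reports how many administrations of
    ``per_scan_MBq`` fit under the binding annual constraint.
    """
    if limits is None:
        limits = RegulatoryLimits()
    organs = {o: d for o, d in organ_dose.items() if o not in _SUMMARY_ROWS}
    if not organs or any(d <= 0 for d in organs.values()):
        raise ValueError("organ doses must be present and > 0")
    if effective_dose_uSv_per_MBq <= 0:
        raise ValueError("effective dose must be > 0")
    max_dose = max(organs.values())
    out = {
        "organ_single_MBq": limits.other_organ_single * 1000.0 / max_dose,
        "organ_annual_MBq": limits.other_organ_annual * 1000.0 / max_dose,
        "whole_body_single_MBq": limits.whole_body_single
        * 1000.0
        / effective_dose_uSv_per_MBq,
        "whole_body_annual_MBq": limits.whole_body_annual
        * 1000.0
        / effective_dose_uSv_per_MBq,
    }
    binding = min(out, key=out.get)
    annual = min(out["organ_annual_MBq"], out["whole_body_annual_MBq"])
    out["binding_MBq"] = out[binding]
    out["scans_per_year"] = math.floor(annual / per_scan_MBq)
    return out


@dataclass
class DoseReport:
    """Full dosimetry result for one cohort arm."""

    organ_dose: Dict[str, float]  # uSv/MBq
    effective_dose: float  # uSv/MBq, ICRP-60
    effective_dose_equivalent: float  # uSv/MBq, ICRP-26
    dose_limiting_organ: str
    administrable: Dict[str, float]  # MBq per constraint

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.organ_dose.values()):
            raise ValueError("doses must be >= 0")
        if self.dose_limiting_organ != dose_limiting_organ(self.organ_dose):
            raise ValueError("dose_limiting_organ does not attain the maximum")

    def to_dict(self) -> dict:
        return {
            "organ_dose_uSv_per_MBq": {
                o: round(d, 3) for o, d in sorted(self.organ_dose.items())
            },
            "effective_dose_uSv_per_MBq": round(self.effective_dose, 3),
            "effective_dose_equivalent_uSv_per_MBq": round(
                self.effective_dose_equivalent, 3
            ),
            "dose_limiting_organ": self.dose_limiting_organ,
            "administrable_MBq": {
                k: round(v, 2) for k, v in self.administrable.items()
            },
            "administrable_GBq": {
                k: round(v / 1000.0, 2)
                for k, v in self.administrable.items()
                if k.endswith("_MBq")
            },
        }


def load_reference_organ_doses() -> pd.DataFrame:
    """Published reference organ dose coefficients (uSv/MBq) for the Cu-64
    anti-PD-1 antibody tracer in an adult phantom.

    Columns: two quantification routes (PET/CT ROI, ex vivo) x two cohorts
    (blk/nblk); ``kind`` distinguishes per-organ rows from whole-body
    summary rows (effective dose / effective dose equivalent).
    """
    src = resources.files("predose.data") / "reference_organ_doses.csv"
    with resources.as_file(src) as p:
        return pd.read_csv(p)
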