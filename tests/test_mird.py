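"""Dose engine: S-value weighting, ICRP schemes, limits."""

import numpy as np
import pytest

from predose.humanize import HumanPhantom
from predose.kinetics import ResidenceTimeSet
from predose.mird import (
    RegulatoryLimits,
    SValueMatrix,
    TissueWeightScheme,
    administrable_activity,
    dose_limiting_organ,
    effective_dose,
    effective_dose_equivalent,
    organ_doses,
    synthetic_cu64_svalue_matrix,
)


def _random_smatrix(rng, organs):
    entries = {}
    for t in organs:
        for s in organs:
            entries[(t, s)] = rng.uniform(0.001, 0.01) if t != s else rng.uniform(0.01, 0.05)
    return SValueMatrix("Cu-64", "toy", entries)


class TestOrganDoses:
    def test_zero_taus_give_zero_doses(self, rng):
        smat = _random_smatrix(rng, ["a", "b"])
        doses = organ_doses({"a": 0.0, "b": 0.0}, smat)
        assert all(d == 0.0 for d in doses.values())

    def test_single_source_one_term_product(self):
        smat = SValueMatrix("Cu-64", "toy", {("t", "s"): 0.003, ("s", "s"): 0.01, ("t", "t"): 0.01})
        doses = organ_doses({"s": 2.0}, smat)
        assert doses["t"] == pytest.approx(6.0)  # 2 h x 0.003 mSv -> 6 uSv

    def test_matches_brute_force_triple_loop(self, rng):
        organs = ["a", "b", "c", "d", "e"]
        smat = _random_smatrix(rng, organs)
        taus = {o: rng.uniform(0, 2) for o in organs}
        doses = organ_doses(taus, smat)
        for t in organs:
            expected = 0.0
            for s in organs:
                expected += taus[s] * smat.entries[(t, s)] * 1000.0
            assert doses[t] == pytest.approx(expected, rel=1e-14)

    def test_linearity_in_taus(self, rng):
        organs = ["a", "b", "c"]
        smat = _random_smatrix(rng, organs)
        taus = {o: rng.uniform(0, 2) for o in organs}
        d1 = organ_doses(taus, smat)
        d2 = organ_doses({o: 3.0 * v for o, v in taus.items()}, smat)
        for o in organs:
            assert d2[o] == pytest.approx(3.0 * d1[o], rel=1e-14)

    def test_unmapped_source_raises_naming_the_pair(self, rng):
        smat = _random_smatrix(rng, ["a", "b"])
        with pytest.raises(KeyError, match="pancreas"):
            organ_doses({"pancreas": 1.0}, smat)

    def test_accepts_residence_time_set(self, rng):
        smat = _random_smatrix(rng, ["a", "b"])
        rts = ResidenceTimeSet(taus_h={"a": 1.0, "b": 0.5})
        assert organ_doses(rts, smat) == organ_doses({"a": 1.0, "b": 0.5}, smat)


class TestSyntheticSMatrix:
    def test_self_dose_positive_and_dominant(self, phantom):
        smat = synthetic_cu64_svalue_matrix(phantom)
        for t in smat.targets:
            self_s = smat.entries[(t, t)]
            assert self_s > 0
            cross = [smat.entries[(t, s)] for s in smat.sources if s not in (t, "heart_contents")]
            assert self_s > max(cross)

    def test_blood_pool_is_source_only(self, phantom):
        smat = synthetic_cu64_svalue_matrix(phantom)
        assert "heart_contents" in smat.sources
        assert "heart_contents" not in smat.targets
        assert smat.entries[("heart_wall", "heart_contents")] > 0

    def test_remainder_source_present(self, phantom):
        smat = synthetic_cu64_svalue_matrix(phantom)
        assert "remainder" in smat.sources

    def test_csv_round_trip(self, phantom, tmp_path):
        smat = synthetic_cu64_svalue_matrix(phantom)
        path = tmp_path / "s.csv"
        smat.to_csv(path)
        back = SValueMatrix.from_csv(path)
        assert back.entries == pytest.approx(smat.entries)


class TestEffectiveDose:
    def test_uniform_dose_is_fixed_point(self, icrp60, phantom):
        organs = list(phantom.organ_mass_g) + ["total_body"]
        doses = {o: 7.0 for o in organs}
        assert effective_dose(doses, icrp60, phantom) == pytest.approx(7.0)

    def test_liver_only_single_term(self, icrp60, phantom):
        with pytest.warns(UserWarning):
            ed = effective_dose({"liver": 20.0}, icrp60, phantom)
        assert ed == pytest.approx(0.05 * 20.0)

    def test_colon_is_mass_weighted_uli_lli(self, icrp60, phantom):
        with pytest.warns(UserWarning):
            ed = effective_dose({"uli_wall": 2.0, "lli_wall": 1.0}, icrp60, phantom)
        m_uli = phantom.organ_mass_g["uli_wall"]
        m_lli = phantom.organ_mass_g["lli_wall"]
        colon = (2.0 * m_uli + 1.0 * m_lli) / (m_uli + m_lli)
        assert ed == pytest.approx(0.12 * colon)

    def test_bad_weight_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TissueWeightScheme(
                scheme_id="bad", weights={"liver": 0.5}, remainder_rule="mass_weighted_mean",
                remainder_weight=0.4,
            )

    def test_bounded_by_min_and_max_organ_dose(self, icrp60, phantom, rng):
        organs = list(phantom.organ_mass_g)
        doses = {o: float(rng.uniform(1, 30)) for o in organs}
        ed = effective_dose(doses, icrp60, phantom)
        assert min(doses.values()) <= ed <= max(doses.values())


class TestEffectiveDoseEquivalent:
    def test_uniform_dose_is_fixed_point(self, icrp26, phantom):
        organs = list(phantom.organ_mass_g)
        doses = {o: 7.0 for o in organs}
        assert effective_dose_equivalent(doses, icrp26, phantom) == pytest.approx(7.0)

    def test_single_unnamed_organ_fills_one_remainder_slot(self, icrp26, phantom):
        with pytest.warns(UserWarning):
            ede = effective_dose_equivalent({"pancreas": 10.0}, icrp26, phantom)
        assert ede == pytest.approx(0.06 * 10.0)


class TestDoseLimitingOrgan:
    def test_reference_like_map(self):
        doses = {"liver": 35.15, "heart_wall": 17.05, "spleen": 6.705}
        assert dose_limiting_organ(doses) == "liver"

    def test_lexicographic_tie_break(self):
        assert dose_limiting_organ({"b": 1.0, "a": 1.0}) == "a"

    def test_single_entry(self):
        assert dose_limiting_organ({"spleen": 0.1}) == "spleen"

    def test_total_body_not_a_candidate(self):
        assert dose_limiting_organ({"total_body": 99.0, "liver": 1.0}) == "liver"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dose_limiting_organ({})


class TestAdministrableActivity:
    def test_limits_divided_by_coefficients(self):
        doses = {"liver": 25.0, "spleen": 10.0}
        out = administrable_activity(doses, effective_dose_uSv_per_MBq=5.0)
        assert out["organ_single_MBq"] == pytest.approx(50_000 / 25.0)
        assert out["organ_annual_MBq"] == pytest.approx(150_000 / 25.0)
        assert out["whole_body_single_MBq"] == pytest.approx(30_000 / 5.0)
        assert out["whole_body_annual_MBq"] == pytest.approx(50_000 / 5.0)
        assert out["binding_MBq"] == pytest.approx(min(
            out[k] for k in (
                "organ_single_MBq", "organ_annual_MBq",
                "whole_body_single_MBq", "whole_body_annual_MBq",
            )
        ))

    def test_scans_per_year_at_default_activity(self):
        out = administrable_activity({"liver": 25.0}, 5.0, per_scan_MBq=185.0)
        annual = min(150_000 / 25.0, 50_000 / 5.0)
        assert out["scans_per_year"] == int(annual // 185.0)

    def test_zero_coefficient_rejected(self):
        with pytest.raises(ValueError):
            administrable_activity({"liver": 0.0}, 5.0)

    def test_inconsistent_limits_rejected(self):
        with pytest.raises(ValueError):
            RegulatoryLimits(whole_body_annual=20.0, whole_body_single=30.0)
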