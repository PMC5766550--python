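"""Time-integrated activity: trapezoid + tail, residence times, remainder."""

import math

import numpy as np
import pytest

from predose.kinetics import (
    ResidenceTimeSet,
    TimeActivityCurve,
    build_tac,
    integrate_tia,
    remainder_of_body,
    residence_time,
    to_organ_fraction,
)

T_HALF = 12.7
LAMBDA = math.log(2) / T_HALF


def _pure_decay_curve(n, t_max=96.0, frac0=1.0):
    """Fully retained source: only physical decay, sampled on n points."""
    t = np.linspace(t_max / n, t_max, n)
    return TimeActivityCurve(
        organ="x", times_h=t, fraction_in_organ=frac0 * 2.0 ** (-t / T_HALF),
        decay_corrected=False, half_life_h=T_HALF,
    )


class TestOrganFraction:
    @pytest.mark.parametrize(
        "pid,mass,expected",
        [(5.0, 2.0, 0.10), (100.0, 1.0, 1.0), (7.3, 1.5, 0.1095)],
    )
    def test_examples(self, pid, mass, expected):
        assert to_organ_fraction(pid, mass) == pytest.approx(expected)

    def test_fraction_above_one_flagged(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            to_organ_fraction(60.0, 2.0)


class TestIntegrateTia:
    def test_pure_decay_converges_to_closed_form(self):
        # closed form: integral of 2^(-t/T) dt = T/ln2 = 18.323 h.  The
        # (0,0) anchor misses ~dt/2 of the first interval, so convergence
        # is first-order in the sampling interval.
        tia = integrate_tia(_pure_decay_curve(20_000), tail_mode="physical_decay")
        assert tia == pytest.approx(T_HALF / math.log(2), rel=5e-4)

    def test_all_zero_curve_integrates_to_zero(self):
        c = TimeActivityCurve("x", [1.0, 24.0, 48.0], [0, 0, 0], False)
        assert integrate_tia(c) == 0.0

    def test_refinement_reduces_error_monotonically(self):
        closed = T_HALF / math.log(2)
        errors = [
            abs(integrate_tia(_pure_decay_curve(n)) - closed) for n in (6, 12, 24, 48, 96)
        ]
        assert all(e1 > e2 for e1, e2 in zip(errors, errors[1:]))
        # the first-interval anchor term dominates: halving dt halves the error
        assert errors[-2] / errors[-1] == pytest.approx(2.0, rel=0.3)

    def test_sampled_biexponential_matches_fine_grid_oracle(self):
        """Trapezoid on the sparse PET schedule agrees with a brute-force
        fine-grid integration of the same rule, within the coarse-grid
        discretisation bias."""
        f = lambda t: np.exp(-0.1 * t) * 2.0 ** (-t / T_HALF)
        t_coarse = np.array([1.0, 2.0, 4.0, 18.0, 24.0, 48.0])
        coarse = integrate_tia(
            TimeActivityCurve("x", t_coarse, f(t_coarse), False), "physical_decay"
        )
        t_fine = np.linspace(1e-4, 48.0, 200_001)
        fine = np.trapezoid(f(t_fine), t_fine) + f(48.0) / LAMBDA
        # chords over a convex decaying curve overestimate; the coarse value
        # must stay within the discretisation bias of the sparse schedule
        assert coarse == pytest.approx(fine, rel=0.15)

    def test_decay_corrected_input_auto_uncorrected(self):
        t = np.linspace(0.5, 48, 400)
        ndc = TimeActivityCurve("x", t, 0.5 * 2.0 ** (-t / T_HALF), False)
        dc = TimeActivityCurve("x", t, np.full_like(t, 0.5), True)
        assert integrate_tia(dc) == pytest.approx(integrate_tia(ndc), rel=1e-9)

    def test_tail_mode_ordering(self):
        # zero <= fitted_exp <= physical_decay for clearing late-time data
        t = np.array([1.0, 12.0, 24.0, 48.0])
        a = 0.3 * np.exp(-0.05 * t) * 2.0 ** (-t / T_HALF)
        c = TimeActivityCurve("x", t, a, False)
        z = integrate_tia(c, "zero")
        fe = integrate_tia(c, "fitted_exp")
        pd_ = integrate_tia(c, "physical_decay")
        assert z < fe < pd_

    def test_fitted_exp_recovers_biological_rate(self):
        lam_bio = 0.08
        t = np.linspace(1, 48, 60)
        a = 0.2 * np.exp(-lam_bio * t) * 2.0 ** (-t / T_HALF)
        c = TimeActivityCurve("x", t, a, False)
        tail = integrate_tia(c, "fitted_exp") - integrate_tia(c, "zero")
        assert tail == pytest.approx(a[-1] / (LAMBDA + lam_bio), rel=1e-6)

    def test_single_point_rejected(self):
        c = TimeActivityCurve("x", [24.0], [0.5], False)
        with pytest.raises(ValueError):
            integrate_tia(c)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            TimeActivityCurve("x", [1.0, 0.5, 2.0], [0.1, 0.1, 0.1], False)


class TestResidenceTime:
    @pytest.mark.parametrize("tia", [0.0, 18.323, 0.5])
    def test_identity(self, tia):
        assert residence_time(tia) == tia

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            residence_time(-0.1)

    def test_tau_cannot_exceed_pure_decay_bound(self):
        with pytest.raises(ValueError, match="pure-decay bound"):
            ResidenceTimeSet(taus_h={"a": 10.0, "b": 10.0}, half_life_h=T_HALF)

    def test_residence_times_bounded_by_isotope_lifetime(self, rng):
        # any physical curve (fraction <= 1) integrates below T/ln2
        bound = T_HALF / math.log(2)
        for _ in range(20):
            t = np.sort(rng.uniform(0.5, 96, 8))
            f = rng.uniform(0, 1, 8) * 2.0 ** (-t / T_HALF)
            c = TimeActivityCurve("x", t, f, False)
            assert integrate_tia(c, "physical_decay") <= bound + 1e-9


class TestRemainderOfBody:
    def _taus(self, total):
        return ResidenceTimeSet(taus_h={"liver": total * 0.7, "spleen": total * 0.3})

    def test_whole_body_minus_organs(self):
        t = np.linspace(0.5, 48, 500)
        wb = TimeActivityCurve("whole_body", t, 0.9 * 2.0 ** (-t / T_HALF), False)
        tau_wb = integrate_tia(wb)
        rem = remainder_of_body(self._taus(tau_wb * 0.7), wb)
        assert rem == pytest.approx(tau_wb * 0.3, rel=1e-9)

    def test_negative_remainder_floored_with_warning(self):
        t = np.linspace(0.5, 48, 100)
        wb = TimeActivityCurve("whole_body", t, 0.1 * 2.0 ** (-t / T_HALF), False)
        with pytest.warns(UserWarning, match="floored"):
            assert remainder_of_body(self._taus(5.0), wb) == 0.0

    def test_no_whole_body_curve_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="whole-body"):
            assert remainder_of_body(self._taus(1.0), None) == 0.0


def test_build_tac_averages_replicates():
    import pandas as pd

    df = pd.DataFrame(
        {
            "organ": ["liver"] * 4,
            "time_h": [1.0, 1.0, 24.0, 24.0],
            "pid_per_g": [4.0, 6.0, 1.0, 3.0],
            "decay_corrected": [False] * 4,
        }
    )
    tac = build_tac(df, "liver", organ_mass_g=1.3)
    assert tac.times_h.tolist() == [1.0, 24.0]
    assert tac.fraction_in_organ == pytest.approx([5.0 * 1.3 / 100, 2.0 * 1.3 / 100])
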