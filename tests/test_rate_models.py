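import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapsched.rate_models import (
    RESISTANT,
    SENSITIVE,
    CalibrationError,
    CalibrationParams,
    CombinationCycle,
    RateModel,
    combined_rates,
    default_calibration,
    default_params,
    validate_calibration,
)

C_LARGE = 1e6  # uM, saturating erlotinib concentration


class TestControlAndErlotinib:
    def test_zero_drug_limit_is_control(self, rate_model):
        for g in (SENSITIVE, RESISTANT):
            for i in (1, 16, 32):
                assert rate_model.erlotinib_rates(g, i, 0.0) == pytest.approx(
                    rate_model.control_rates(g, i)
                )

    def test_control_net_growth_positive_everywhere(self, rate_model):
        for i in range(1, 33):
            lam, mu = rate_model.control_rates(SENSITIVE, i)
            assert lam - mu > 0

    def test_sensitive_killed_at_high_oxygen(self, rate_model):
        birth, death = rate_model.erlotinib_rates(SENSITIVE, 32, C_LARGE)
        assert birth - death < 0

    def test_sensitive_net_crosses_zero_at_finite_dose(self, rate_model):
        from scipy.optimize import brentq

        def net(C):
            b, d = rate_model.erlotinib_rates(SENSITIVE, 32, C)
            return b - d

        root = brentq(net, 1e-6, 100.0)
        assert 0 < root < 10.0  # crossing within the clinical range

    def test_resistant_unaffected_in_most_hypoxic_compartment(self, rate_model):
        b0, d0 = rate_model.erlotinib_rates(RESISTANT, 1, 0.0)
        b1, d1 = rate_model.erlotinib_rates(RESISTANT, 1, C_LARGE)
        assert (b1 - d1) == pytest.approx(b0 - d0, rel=0.05)

    def test_resistant_partially_inhibited_near_vessel(self, rate_model):
        b0, d0 = rate_model.erlotinib_rates(RESISTANT, 32, 0.0)
        b1, d1 = rate_model.erlotinib_rates(RESISTANT, 32, C_LARGE)
        bs, ds = rate_model.erlotinib_rates(SENSITIVE, 32, C_LARGE)
        assert 0 < (b0 - d0) - (b1 - d1)  # some inhibition
        assert (b1 - d1) > (bs - ds)  # but far less than sensitive cells

    def test_unknown_compartment_rejected(self, rate_model):
        with pytest.raises(KeyError):
            rate_model.erlotinib_rates(SENSITIVE, 99, 1.0)

    @settings(max_examples=40, deadline=None)
    @given(
        i=st.integers(1, 32),
        C=st.floats(0.0, 50.0),
        genotype=st.sampled_from([SENSITIVE, RESISTANT]),
    )
    def test_rates_nonnegative(self, rate_model, i, C, genotype):
        b, d = rate_model.erlotinib_rates(genotype, i, C)
        assert b >= 0 and d >= 0


class TestEvofosfamideResponse:
    def test_zero_concentration_is_control(self, rate_model):
        for g in (SENSITIVE, RESISTANT):
            assert rate_model.evofosfamide_rates(g, 5, 0.0) == pytest.approx(
                rate_model.control_rates(g, 5)
            )
        assert rate_model.viability(5, 0.0) == 1.0

    def test_death_increment_is_half_log_viability(self, rate_model):
        # v = exp(-2)  =>  death = mu_c + 1
        from scipy.optimize import brentq

        _, mu_c = rate_model.control_rates(SENSITIVE, 1)
        target = np.exp(-2.0)
        vmin = rate_model.viability(1, 1e9)
        if vmin < target:  # reachable for the most hypoxic compartment
            C2 = brentq(lambda c: rate_model.viability(1, c) - target, 1e-9, 1e9)
            _, death = rate_model.evofosfamide_rates(SENSITIVE, 1, C2)
            assert death == pytest.approx(mu_c + 1.0, rel=1e-9)

    def test_death_nondecreasing_in_concentration(self, rate_model):
        C2 = np.linspace(0, 30, 40)
        for i in (1, 16, 32):
            _, death = rate_model.evofosfamide_rates(SENSITIVE, i, C2)
            assert np.all(np.diff(death) >= -1e-12)

    def test_births_untouched_by_evofosfamide(self, rate_model):
        for i in (1, 32):
            lam_c, _ = rate_model.control_rates(RESISTANT, i)
            birth, _ = rate_model.evofosfamide_rates(RESISTANT, i, 20.0)
            assert birth == pytest.approx(lam_c)

    def test_hypoxia_activation_ordering(self, rate_model):
        # potency strictly greater at lower oxygen for C2 > 0
        v_hypoxic = rate_model.viability(1, 10.0)
        v_oxic = rate_model.viability(32, 10.0)
        assert v_hypoxic < v_oxic < 1.0

    def test_literal_form_uses_sensitive_birth_for_resistant(self, compartment_model):
        params = dataclasses.replace(default_params(), literal_eq9=True)
        model = RateModel(compartment_model, params)
        lam_sens_c, _ = model.control_rates(SENSITIVE, 32)
        birth, _ = model.evofosfamide_rates(RESISTANT, 32, 5.0)
        assert birth == pytest.approx(lam_sens_c)


class TestCombinedCycle:
    @pytest.fixture()
    def cycle(self, rate_model):
        return CombinationCycle(
            t1=120.0,
            t2=48.0,
            erlotinib_conc=lambda t, i: 2.0 if t < 130.0 else 0.5,
            evo_conc=lambda t: 10.0 * np.exp(-2.0 * max(t - 120.0, 0.0)),
        )

    def test_zero_drug_cycle_gives_control(self, rate_model):
        cyc = CombinationCycle(100.0, 50.0, lambda t, i: 0.0, lambda t: 0.0)
        rates = combined_rates(rate_model, cyc, 7, 42.0)
        lam_c, mu_c = rate_model.control_rates(SENSITIVE, 7)
        assert rates[0] == pytest.approx(lam_c) and rates[1] == pytest.approx(mu_c)

    def test_erlotinib_phase_matches_curves(self, rate_model, cycle):
        rates = combined_rates(rate_model, cycle, 16, 60.0)
        assert rates[:2] == pytest.approx(rate_model.erlotinib_rates(SENSITIVE, 16, 2.0))
        assert rates[2:] == pytest.approx(rate_model.erlotinib_rates(RESISTANT, 16, 2.0))

    def test_evo_phase_mixes_residual_erlotinib_and_evo_death(self, rate_model, cycle):
        t = 125.0
        lam_X, mu_X, lam_Y, mu_Y = combined_rates(rate_model, cycle, 16, t)
        birth_exp, _ = rate_model.erlotinib_rates(SENSITIVE, 16, 2.0)
        _, death_exp = rate_model.evofosfamide_rates(SENSITIVE, 16, cycle.evo_conc(t))
        assert lam_X == pytest.approx(birth_exp)
        assert mu_X == pytest.approx(death_exp)
        assert mu_X > rate_model.control_rates(SENSITIVE, 16)[1]

    def test_periodicity(self, rate_model, cycle):
        for t in (10.0, 123.0, 150.0):
            assert combined_rates(rate_model, cycle, 4, t) == pytest.approx(
                combined_rates(rate_model, cycle, 4, t + cycle.period)
            )

    def test_out_of_cycle_rejected_when_not_periodic(self, rate_model):
        cyc = CombinationCycle(10.0, 5.0, lambda t, i: 0.0, lambda t: 0.0, periodic=False)
        with pytest.raises(ValueError):
            combined_rates(rate_model, cyc, 1, 20.0)


class TestCalibrationArtifact:
    def test_default_passes_validation(self, rate_model):
        validate_calibration(rate_model)  # should not raise

    def test_serialization_round_trip(self, compartment_model, tmp_path, rate_model):
        path = tmp_path / "cal.json"
        default_params().to_json(path)
        model2 = RateModel(compartment_model, CalibrationParams.from_json(path))
        probes = np.linspace(0, 20, 100)
        for i in (1, 17, 32):
            for g in (SENSITIVE, RESISTANT):
                a = rate_model.erlotinib_rates(g, i, probes)
                b = model2.erlotinib_rates(g, i, probes)
                np.testing.assert_allclose(a, b)
            np.testing.assert_allclose(
                rate_model.viability(i, probes), model2.viability(i, probes)
            )

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"control_death": 0.01, "bogus_knob": 3}')
        with pytest.raises(CalibrationError, match="bogus_knob"):
            CalibrationParams.from_json(path)

    def test_violating_parameters_name_the_constraint(self, compartment_model):
        # shrinking tumor off-drug violates constraint (i)
        bad = dataclasses.replace(default_params(), control_net_base=-0.05)
        with pytest.raises(CalibrationError, match=r"\(i\)"):
            default_calibration(compartment_model, bad)
        # resistant inhibition stronger than sensitive violates (iii)
        bad = dataclasses.replace(default_params(), res_imax_top=1.0)
        with pytest.raises(CalibrationError, match=r"\(iii\)"):
            default_calibration(compartment_model, bad)
        # oxygen-increasing potency violates (iv)
        bad = dataclasses.replace(default_params(), viab_k_o=-20.0)
        with pytest.raises(CalibrationError):
            default_calibration(compartment_model, bad)
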