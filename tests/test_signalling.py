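"""Transducin/PDE6 observables and the minimal cascade kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photocascade import signalling as S
from photocascade.instrument import render_series, render_spectrum
from photocascade.quant import ChargeSeries
from photocascade.spectra import (
    CGMP_DELTA,
    GDP_DELTA,
    AbundanceTrace,
    LightSchedule,
    SpeciesDef,
)

from tests.conftest import make_instrument

# fixture masses: order-of-magnitude stand-ins, not measured values
GT_MASS = 85_000.0
PDE6_MASS = 215_000.0


@pytest.fixture
def gt_registry():
    return {
        "gt_gdp": SpeciesDef("gt_gdp", GT_MASS, GDP_DELTA, 14, 18, 10.0),
        "gt_apo": SpeciesDef("gt_apo", GT_MASS, 0.0, 14, 18, 10.0),
    }


def gt_instrument(noise_sd=0.0):
    return make_instrument(noise_sd, mz_min=4200.0, mz_max=6800.0,
                           charge_envelope={"gt_gdp": (16.0, 1.0), "gt_apo": (16.0, 1.0)})


def gt_series_from_fractions(registry, fracs, noise_sd=0.0, seed=5):
    times = np.arange(float(len(fracs)))
    truth = AbundanceTrace(times, np.asarray(fracs, dtype=float), list(registry))
    return render_series(truth, registry, gt_instrument(noise_sd), LightSchedule.dark(), seed)


class TestGtRatio:
    def test_dark_ratio_4_1_recovered(self, gt_registry):
        """A dark fixture built at G_t•GDP:apo = 4.1 quantifies back to 4.1."""
        f = 4.1 / 5.1
        series = gt_series_from_fractions(gt_registry, [[f, 1 - f]] * 3, noise_sd=0.005)
        _, ratios = S.gt_ratio(series, gt_registry["gt_gdp"], gt_registry["gt_apo"])
        assert np.median(ratios) == pytest.approx(4.1, abs=0.15)

    def test_first_order_conversion_is_monotone_decreasing(self, gt_registry):
        t = np.linspace(0.0, 15.0, 8)
        gdp = 0.8 * np.exp(-0.2 * t)
        fracs = np.column_stack([gdp, 1 - gdp]) / 1.0
        series = gt_series_from_fractions(gt_registry, fracs)
        _, ratios = S.gt_ratio(series, gt_registry["gt_gdp"], gt_registry["gt_apo"])
        assert np.all(np.diff(ratios) < 0)

    def test_absent_apo_flagged_infinite(self, gt_registry):
        series = gt_series_from_fractions(gt_registry, [[1.0, 0.0]])
        _, ratios = S.gt_ratio(series, gt_registry["gt_gdp"], gt_registry["gt_apo"])
        assert np.isinf(ratios[0])

    def test_proteoform_sub_series_are_summed(self, gt_registry):
        """Declaring the same state as two proteoform envelopes must not change the ratio."""
        reg = dict(gt_registry)
        reg["gt_gdp_a2"] = SpeciesDef("gt_gdp_a2", GT_MASS + 1500.0, GDP_DELTA, 14, 18, 10.0)
        inst = make_instrument(0.0, mz_min=4200.0, mz_max=6800.0,
                               charge_envelope={n: (16.0, 1.0) for n in reg})
        truth = AbundanceTrace(np.array([0.0]), np.array([[0.4, 0.2, 0.4]]), list(reg))
        series = render_series(truth, reg, inst, LightSchedule.dark(), seed=3)
        _, ratios = S.gt_ratio(series, [reg["gt_gdp"], reg["gt_gdp_a2"]], [reg["gt_apo"]])
        assert ratios[0] == pytest.approx((0.4 + 0.4) / 0.2, rel=1e-3)


class TestPde6Occupancy:
    def _registry(self):
        return {
            "pde6": SpeciesDef("pde6", PDE6_MASS, 0.0, 27, 33, 4.0),
            "pde6_cgmp": SpeciesDef("pde6_cgmp", PDE6_MASS, CGMP_DELTA, 27, 33, 4.0),
        }

    def _spectrum(self, pops, registry):
        env = {n: (30.0, 1.2) for n in registry}
        inst = make_instrument(0.0, mz_min=6200.0, mz_max=8500.0, charge_envelope=env)
        return render_spectrum(pops, registry, inst)

    def test_half_occupancy_is_one_to_one(self):
        reg = self._registry()
        spec = self._spectrum({"pde6": 0.5, "pde6_cgmp": 0.5}, reg)
        ratio, frac = S.pde6_occupancy(spec, reg["pde6"], reg["pde6_cgmp"])
        assert ratio == pytest.approx(1.0, abs=1e-5)
        assert frac == 0.0

    @pytest.mark.parametrize("occ", [0.85, 0.4, 0.25])
    def test_reported_occupancies_recovered(self, occ):
        """The 1:0.85 / 1:0.4 / 1:0.25 occupancy fixtures quantify back correctly."""
        reg = self._registry()
        spec = self._spectrum({"pde6": 1.0 / (1 + occ), "pde6_cgmp": occ / (1 + occ)}, reg)
        ratio, _ = S.pde6_occupancy(spec, reg["pde6"], reg["pde6_cgmp"])
        assert ratio == pytest.approx(occ, abs=0.01)

    def test_galpha_complex_detected_above_threshold(self):
        reg = self._registry()
        reg["pde6_ga"] = SpeciesDef("pde6_ga", PDE6_MASS + 40_000.0, 0.0, 27, 33, 4.0)
        env = {n: (30.0, 1.2) for n in reg}
        inst = make_instrument(0.0, mz_min=6200.0, mz_max=9600.0, charge_envelope=env)
        spec = render_spectrum({"pde6": 0.45, "pde6_cgmp": 0.45, "pde6_ga": 0.10}, reg, inst)
        ratio, frac = S.pde6_occupancy(spec, reg["pde6"], reg["pde6_cgmp"], reg["pde6_ga"])
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_no_complex_peak_gives_zero_fraction(self):
        reg = self._registry()
        reg["pde6_ga"] = SpeciesDef("pde6_ga", PDE6_MASS + 40_000.0, 0.0, 27, 33, 4.0)
        env = {n: (30.0, 1.2) for n in reg}
        inst = make_instrument(0.0, mz_min=6200.0, mz_max=9600.0, charge_envelope=env)
        spec = render_spectrum({"pde6": 0.5, "pde6_cgmp": 0.5, "pde6_ga": 0.0}, reg, inst)
        _, frac = S.pde6_occupancy(spec, reg["pde6"], reg["pde6_cgmp"], reg["pde6_ga"])
        assert frac == 0.0


class TestCascade:
    def test_dark_fixed_point(self):
        """No rho* drive and no GTP: nothing moves."""
        gt0 = S.GtState(gt_gdp=1.0)
        pde0 = S.Pde6State(pde6_apo=0.1, pde6_cgmp=0.9)
        gt1, pde1 = S.cascade_step(gt0, pde0, rho_star=0.0, params=S.CascadeParams(), dt=10.0)
        assert gt1.gt_gdp == pytest.approx(1.0)
        assert pde1.pde6_cgmp == pytest.approx(0.9)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            S.cascade_step(S.GtState(), S.Pde6State(), 0.0, S.CascadeParams(), -1.0)

    def test_gtp_replenishment(self):
        """With GTP the G_t•GDP pool is replenished; without it, it drains away."""
        t = np.linspace(0.0, 15.0, 61)
        pde0 = S.Pde6State(pde6_apo=0.03, pde6_cgmp=0.27)
        no_gtp = S.simulate_cascade(S.GtState(gt_gdp=1.0, gtp_pool=0.0), pde0, t,
                                    S.CascadeParams(), rho_star=0.2)
        with_gtp = S.simulate_cascade(S.GtState(gt_gdp=1.0, gtp_pool=1.0), pde0, t,
                                      S.CascadeParams(), rho_star=0.2)
        assert with_gtp.gt_gdp.iloc[-1] > 3 * no_gtp.gt_gdp.iloc[-1]

    def test_gtpgs_analogue_keeps_galpha_active_with_intermediate_plateau(self):
        """Non-hydrolysable analogue: Gα stays active and occupancy plateaus midway."""
        t = np.linspace(0.0, 60.0, 241)
        pde0 = S.Pde6State(pde6_apo=0.03, pde6_cgmp=0.27)
        df = S.simulate_cascade(S.GtState(gt_gdp=0.2, gtp_pool=0.2), pde0, t,
                                S.CascadeParams(k_gtpase=0.0), rho_star=0.5)
        last = df.iloc[-1]
        active = last.galpha_gtp + last.pde6_galpha + last.pde6_galpha_cgmp
        occ = (last.pde6_cgmp + last.pde6_galpha_cgmp) / (last.pde6_apo + last.pde6_galpha)
        dark_occ = 0.27 / 0.03
        assert active > 0.15                    # Gα stays loaded with the analogue
        assert 0.05 < occ < 0.5 * dark_occ      # intermediate plateau, not full hydrolysis
        # plateau: occupancy nearly flat over the last quarter
        tail = df.iloc[-60:]
        occ_tail = (tail.pde6_cgmp + tail.pde6_galpha_cgmp) / (tail.pde6_apo + tail.pde6_galpha)
        assert occ_tail.iloc[0] - occ_tail.iloc[-1] < 0.1 * dark_occ

    def test_condition_ordering_matches_observed_pattern(self):
        """Occupancy after light: +GTP < GTPγS < endogenous < dark."""
        t = np.linspace(0.0, 60.0, 241)
        pde0 = S.Pde6State(pde6_apo=0.03, pde6_cgmp=0.27)
        conds = {
            "dark": (S.GtState(gt_gdp=0.2, gtp_pool=0.2), S.CascadeParams(), 0.0),
            "endogenous": (S.GtState(gt_gdp=0.2, gtp_pool=0.02), S.CascadeParams(), 0.5),
            "gtp": (S.GtState(gt_gdp=0.2, gtp_pool=1.0), S.CascadeParams(), 0.5),
            "gtpgs": (S.GtState(gt_gdp=0.2, gtp_pool=0.2), S.CascadeParams(k_gtpase=0.0), 0.5),
        }
        occ = {}
        for name, (gt0, p, drive) in conds.items():
            last = S.simulate_cascade(gt0, pde0, t, p, rho_star=drive).iloc[-1]
            occ[name] = (last.pde6_cgmp + last.pde6_galpha_cgmp) / (last.pde6_apo + last.pde6_galpha)
        assert occ["gtp"] < occ["gtpgs"] < occ["endogenous"] < occ["dark"]

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 3.0), min_size=7, max_size=7), st.floats(0.0, 1.0))
    def test_positivity_and_conservation_under_random_rates(self, rates, drive):
        """All pools stay >= 0 and subunits are conserved for any positive rates."""
        params = S.CascadeParams(*rates)
        gt0 = S.GtState(gt_gdp=0.5, gt_apo=0.1, galpha_gtp=0.1, galpha_gdp=0.1,
                        gbg=0.3, gtp_pool=0.5, gdp_pool=0.1)
        pde0 = S.Pde6State(pde6_apo=0.1, pde6_cgmp=0.4, pde6_galpha=0.05,
                           pde6_galpha_cgmp=0.05, cgmp_pool=0.3, gmp_pool=0.0)
        alpha0 = S.alpha_total(gt0, pde0)
        bg0 = gt0.beta_gamma_total
        pde_tot0 = pde0.total
        cg0 = S.cgmp_total(pde0)
        gt, pde6 = gt0, pde0
        for _ in range(20):
            gt, pde6 = S.cascade_step(gt, pde6, drive, params, 0.5)
        for v in list(gt.__dict__.values()) + list(pde6.__dict__.values()):
            assert v >= 0.0
        assert abs(S.alpha_total(gt, pde6) - alpha0) < 1e-8
        assert abs(gt.beta_gamma_total - bg0) < 1e-8
        assert abs(pde6.total - pde_tot0) < 1e-8
        assert abs(S.cgmp_total(pde6) - cg0) < 1e-8

    def test_ratio_non_increasing_during_first_phase(self):
        """gt_gdp:gt_apo falls monotonically while rho* drives exchange."""
        t = np.linspace(0.0, 10.0, 41)
        df = S.simulate_cascade(S.GtState(gt_gdp=0.8, gt_apo=0.2, gtp_pool=0.0),
                                S.Pde6State(), t, S.CascadeParams(), rho_star=0.5)
        ratio = df.gt_gdp / df.gt_apo
        assert np.all(np.diff(ratio) <= 1e-12)
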