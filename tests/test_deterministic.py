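"""Dose equations, hazard quotients/index, cancer risk, full-table engine."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dustrisk as dr
from dustrisk.deterministic import (
    add_dermal,
    add_ingestion,
    add_inhalation,
    cancer_risk,
    concentration_from_ingestion_hq,
    hazard_index,
    hazard_quotient,
)
from dustrisk.io_config import ParameterError

from conftest import DER_ING_RATIO, INH_ING_RATIO, RISK_COMPOUNDS, grid, station_body

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


def factors(**overrides):
    base = dict(ir_ing=50.0, ir_inh=15.7, ef=300.0, ed=30.0, bw=70.0,
                pef=1.36e9, sa=4000.0, af=0.07, abs=0.001)
    base.update(overrides)
    return dr.ExposureFactors(**base)


class TestDoseEquations:
    def test_worked_example_station1_dmp(self, adult, scenario):
        """cs = 0.0121667 μg/g with the adult occupational factors and
        RfD = 10 reproduces the published station-1 DMP quotients."""
        tox = scenario.toxicity["DMP"]
        cs = 0.0121667
        assert hazard_quotient(add_inhalation(cs, adult), tox, "inhalation") \
            == pytest.approx(1.6492e-13, rel=1e-4)
        assert hazard_quotient(add_ingestion(cs, adult), tox, "ingestion") \
            == pytest.approx(7.1429e-10, rel=1e-4)
        assert hazard_quotient(add_dermal(cs, adult), tox, "dermal") \
            == pytest.approx(4.0e-12, rel=1e-4)

    def test_direct_product_formula(self, adult):
        """Doses equal their brute-force arithmetic products."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            cs, iring, ef, ed, bw, at = rng.uniform(0.1, 100, 6)
            f = factors(ir_ing=iring, ef=min(ef, 365), ed=ed, bw=bw,
                        at_noncarc=at)
            expect = cs * iring * min(ef, 365) * ed * 1e-6 / (bw * at)
            assert add_ingestion(cs, f) == pytest.approx(expect, rel=1e-12)

    @given(cs=positive, scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_concentration(self, cs, scale):
        f = factors()
        for fn in (add_inhalation, add_ingestion, add_dermal):
            assert fn(cs * scale, f) == pytest.approx(scale * fn(cs, f),
                                                      rel=1e-12)
            assert fn(0.0, f) == 0.0

    def test_doubling_exposure_frequency_doubles_dose(self):
        f150, f300 = factors(ef=150), factors(ef=300)
        rng = np.random.default_rng(11)
        for cs in rng.uniform(0.01, 50, 20):
            for fn in (add_inhalation, add_ingestion, add_dermal):
                assert fn(cs, f300) == pytest.approx(2 * fn(cs, f150),
                                                     rel=1e-12)

    def test_zero_intake_rates_give_zero_dose(self):
        f = factors()
        f.ir_ing = 0.0
        assert add_ingestion(1.0, f) == 0.0
        f2 = factors()
        f2.abs = 0.0
        assert add_dermal(1.0, f2) == 0.0

    def test_carcinogenic_averaging_time(self, adult):
        ratio = add_ingestion(1.0, adult) / add_ingestion(1.0, adult,
                                                          carcinogenic=True)
        assert ratio == pytest.approx(adult.at_carc / adult.at_noncarc)

    def test_nonpositive_parameters_rejected(self):
        f = factors()
        f.bw = 0.0
        with pytest.raises(ParameterError, match="bw"):
            add_ingestion(1.0, f)

    def test_inactive_group_contributes_zero(self):
        child = dr.ExposureFactors(group="child", active=False)
        total = dr.pathway_dose("ingestion", 1.0, [factors(), child])
        assert total == add_ingestion(1.0, factors())

    def test_dermal_over_ingestion_ratio_closed_form(self, adult):
        for cs in (0.01, 1.0, 300.0):
            ratio = add_dermal(cs, adult) / add_ingestion(cs, adult)
            assert ratio == pytest.approx(DER_ING_RATIO, rel=1e-12)
        assert DER_ING_RATIO == pytest.approx(5.6e-3)


class TestHazard:
    def test_quotient_threshold_cases(self, scenario):
        tox = scenario.toxicity["DMP"]
        assert hazard_quotient(0.0, tox, "ingestion") == 0.0
        assert hazard_quotient(tox.rfd_oral, tox, "ingestion") == 1.0

    def test_quotient_requires_reference_dose(self):
        tox = dr.ToxicityReference("BEHP")
        with pytest.raises(ParameterError, match="reference dose"):
            hazard_quotient(1.0, tox, "ingestion")

    def test_index_is_plain_sum(self):
        assert hazard_index([]) == 0.0
        assert hazard_index([0.37]) == 0.37
        assert hazard_index([1.6492e-13, 7.1429e-10, 4e-12]) \
            == pytest.approx(7.18451e-10, rel=1e-4)
        assert hazard_index([2.711e-9, 1.83467e-5, 1.02742e-7]) \
            == pytest.approx(1.84522e-5, rel=1e-4)

    def test_cancer_risk_product_and_absence(self, scenario):
        bbp = scenario.toxicity["BBP"]
        assert cancer_risk(0.0, bbp) == 0.0
        assert cancer_risk(1e-8, bbp) == pytest.approx(1.9e-11)
        with pytest.raises(ParameterError, match="slope factor"):
            cancer_risk(1e-8, scenario.toxicity["DMP"])

    def test_cr_pathway_ratios_closed_form(self, adult, scenario):
        bbp = scenario.toxicity["BBP"]
        cr = {p: cancer_risk(dr.pathway_dose(p, 3.7, [adult], True), bbp)
              for p in dr.PATHWAYS}
        assert cr["inhalation"] / cr["ingestion"] == pytest.approx(
            INH_ING_RATIO, rel=1e-12)
        assert cr["dermal"] / cr["ingestion"] == pytest.approx(
            DER_ING_RATIO, rel=1e-12)
        assert INH_ING_RATIO == pytest.approx(2.3088e-4, rel=1e-4)


class TestPublishedTableReproduction:
    """Back-derive each station's concentration from the published ingestion
    quotient, push it through the engine, and compare with the published
    inhalation/dermal quotients."""

    @pytest.fixture()
    def engine_grids(self, fixtures, scenario, adult):
        ing = grid(fixtures["table5"])
        inh = np.empty_like(ing)
        der = np.empty_like(ing)
        for j, comp in enumerate(RISK_COMPOUNDS):
            tox = scenario.toxicity[comp]
            cs = np.array([concentration_from_ingestion_hq(h, tox, adult)
                           for h in ing[:, j]])
            inh[:, j] = hazard_quotient(add_inhalation(cs, adult), tox,
                                        "inhalation")
            der[:, j] = hazard_quotient(add_dermal(cs, adult), tox, "dermal")
        return inh, der

    def test_station2_dmp_full_chain(self, scenario, adult):
        tox = scenario.toxicity["DMP"]
        cs = concentration_from_ingestion_hq(6.9978e-8, tox, adult)
        hq_inh = hazard_quotient(add_inhalation(cs, adult), tox, "inhalation")
        assert hq_inh == pytest.approx(1.6157e-11, rel=1e-3)

    def test_dermal_table_reproduced_everywhere(self, engine_grids, fixtures):
        _, der = engine_grids
        np.testing.assert_allclose(der, grid(fixtures["table6"]), rtol=5e-3)

    def test_inhalation_table_reproduced_for_unified_rfd_compounds(
            self, engine_grids, fixtures):
        inh = engine_grids[0]
        t4 = grid(fixtures["table4"])
        for comp in ("DMP", "DEP", "DOP"):
            j = RISK_COMPOUNDS.index(comp)
            np.testing.assert_allclose(inh[:, j], t4[:, j], rtol=5e-3)

    def test_published_inhalation_deviation_is_exactly_rfd_substitution(
            self, engine_grids, fixtures, scenario):
        """For IBP, DBP and BBP the published inhalation quotients sit at a
        station-independent factor RfD_oral/0.8 below the unified-RfD
        prediction — i.e. they were computed against a reference dose of
        0.8 mg/kg/day instead of the compound's own.  This documents the
        source table's internal inconsistency; the engine follows the stated
        unified-RfD convention."""
        inh = engine_grids[0]
        t4 = grid(fixtures["table4"])
        for comp in ("IBP", "DBP", "BBP"):
            j = RISK_COMPOUNDS.index(comp)
            implied = t4[:, j] / inh[:, j]
            expected = scenario.toxicity[comp].rfd_oral / 0.8
            np.testing.assert_allclose(implied, expected, rtol=2e-3)


class TestRunDeterministic:
    def test_mean_row_is_arithmetic_station_mean(self, fixtures):
        t8 = station_body(fixtures["table8"])
        assert t8["cr_inh"].mean() == pytest.approx(5.5027e-15, rel=1e-4)

    def test_full_run_rows_and_invariants(self, synth_table, scenario):
        out = dr.run_deterministic(synth_table, scenario)
        body = out[out["station"] != "Mean"]
        # 15 stations x 6 risk compounds (BEHP/DiOP skipped)
        assert len(body) == 15 * 6
        # HI additivity with fixed summation order
        np.testing.assert_array_equal(
            body["hi"].to_numpy(),
            (body["hq_inh"] + body["hq_ing"] + body["hq_der"]).to_numpy())
        bbp = body[body["compound"] == "BBP"]
        np.testing.assert_array_equal(
            bbp["cr_total"].to_numpy(),
            (bbp["cr_inh"] + bbp["cr_ing"] + bbp["cr_der"]).to_numpy())
        assert (body.drop(columns=["station", "compound"]).fillna(0) >= 0).all().all()
        # appended Mean rows equal the arithmetic mean of station rows
        mean_bbp = out[(out["station"] == "Mean") & (out["compound"] == "BBP")]
        assert mean_bbp["hi"].iloc[0] == pytest.approx(bbp["hi"].mean())

    def test_all_zero_concentrations_give_zero_risk(self, scenario):
        df = pd.DataFrame({"station": ["S1"] * 6, "compound": RISK_COMPOUNDS,
                           "step": "R1", "value": 0.0})
        out = dr.run_deterministic(dr.ConcentrationTable(df), scenario)
        assert (out[["hq_inh", "hq_ing", "hq_der", "hi"]] == 0).all().all()

    def test_deterministic_ordering(self, synth_table, scenario):
        out = dr.run_deterministic(synth_table, scenario)
        again = dr.run_deterministic(synth_table, scenario)
        pd.testing.assert_frame_equal(out, again)
        body = out[out["station"] != "Mean"]
        stations = body["station"].unique().tolist()
        assert stations == sorted(stations, key=lambda s: int(s[1:]))
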