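"""Deterministic hazard and cancer-risk computation and its published anchors."""

import numpy as np
import pandas as pd
import pytest

import breadrisk as br
from breadrisk import datasets


@pytest.fixture(scope="module")
def published_hq():
    return datasets.load_regional_hazard_quotients()


@pytest.fixture(scope="module")
def published_hi():
    return datasets.load_published_hazard_index()


@pytest.fixture(scope="module")
def published_cr():
    return datasets.load_regional_cancer_risks()


class TestHazardQuotient:
    def test_definition(self):
        assert br.hazard_quotient(0.003, 0.003) == 1.0
        assert br.hazard_quotient(0.0, 0.003) == 0.0

    def test_division_anchor(self):
        # back-set CDI 1.563e-2 against the arsenic RfD gives the published
        # South-adult HQ of 5.21
        assert br.hazard_quotient(1.563e-2, 0.003) == pytest.approx(5.21)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            br.hazard_quotient(1.0, 0.0)
        with pytest.raises(ValueError):
            br.hazard_quotient(-1.0, 0.003)


class TestHazardIndex:
    def test_published_columns_sum_to_published_hi(self, published_hq,
                                                   published_hi):
        """Additivity holds for every published regional HQ column."""
        for key in published_hq.index:
            hi = br.hazard_index(published_hq.loc[key])
            assert hi == pytest.approx(published_hi[key], abs=1e-9), key

    @pytest.mark.parametrize("region,cohort,expected", [
        ("South", "adult", 7.6446),
        ("South", "child", 8.7673),
        ("North", "adult", 5.228),
    ])
    def test_spot_anchors(self, published_hq, region, cohort, expected):
        assert br.hazard_index(published_hq.loc[(region, cohort)]) == \
            pytest.approx(expected, abs=1e-9)

    def test_zeros_and_empty(self):
        assert br.hazard_index([0.0] * 10) == 0.0
        with pytest.raises(ValueError, match="empty"):
            br.hazard_index([])


class TestCancerRisk:
    def test_slope_factor_model(self):
        assert br.cancer_risk(0.0, 1.5) == 0.0
        assert br.cancer_risk(1e-3, 1.5) == pytest.approx(1.5e-3)

    def test_published_cdi_back_implied(self):
        # published South-adult As CR / OSF gives the CDI the CR implies
        assert 4.69e-3 / 1.5 == pytest.approx(3.1267e-3, abs=5e-7)

    def test_total_cancer_risk_anchors(self, published_cr):
        center_adult = published_cr.loc[("Center", "adult")]
        assert br.total_cancer_risk([center_adult["As"], center_adult["Cd"]]) \
            == pytest.approx(4.8995e-3, abs=1e-12)
        north_child = published_cr.loc[("North", "child")]
        assert br.total_cancer_risk([north_child["As"], north_child["Cd"]]) \
            == pytest.approx(4.5031e-3, abs=1e-12)
        assert br.total_cancer_risk([0.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            br.total_cancer_risk([])

    def test_component_sums_match_printed_totals(self, published_cr):
        """As + Cd reproduces the printed TCR except the West-adult misprint."""
        for key, row in published_cr.iterrows():
            total = br.total_cancer_risk([row["As"], row["Cd"]])
            if key == ("West", "adult"):
                # printed 4.23e-3 is inconsistent with its own components
                assert total == pytest.approx(4.77e-3, abs=5e-6)
                assert abs(total - row["tcr_printed"]) > 1e-4
            else:
                # components are printed at 3 significant figures, so their
                # sum can drift from the printed total by the accumulated
                # half-ulps (~1.5e-5)
                assert total == pytest.approx(row["tcr_printed"],
                                              abs=1.5e-5), key


class TestClassify:
    def _table(self, hq_values, tcr):
        idx = pd.MultiIndex.from_tuples([("North", "adult")],
                                        names=["region", "cohort"])
        hq = pd.DataFrame([hq_values], index=idx)
        cdi = hq * 0.003
        cr = pd.DataFrame({"As": [tcr]}, index=idx)
        return br.RiskTable.from_components(cdi=cdi, hq=hq, cr=cr)

    def test_hi_above_one_is_flagged(self):
        flags = br.classify(self._table({"As": 7.6446}, 1e-6))
        assert bool(flags["hi_flag"].iloc[0])

    def test_cr_above_1e4_is_unacceptable(self):
        flags = br.classify(self._table({"As": 0.5}, 4.9e-3))
        assert flags["cr_class"].iloc[0] == "unacceptable"
        assert not bool(flags["hi_flag"].iloc[0])

    def test_cr_bands(self):
        assert br.classify(self._table({"As": 0.5}, 1e-7))["cr_class"].iloc[0] \
            == "de_minimis"
        assert br.classify(self._table({"As": 0.5}, 1e-5))["cr_class"].iloc[0] \
            == "acceptable_range"

    def test_monotone_in_every_component(self, fitted):
        base = br.classify(fitted.risk_table)
        t = fitted.risk_table
        bigger = br.RiskTable.from_components(cdi=t.cdi, hq=t.hq * 3, cr=t.cr)
        raised = br.classify(bigger)
        hq_cols = [c for c in base.columns if c.startswith("hq_flag")]
        assert (base[hq_cols] <= raised[hq_cols]).all().all()
        assert (base["hi_flag"] <= raised["hi_flag"]).all()


class TestSummarize:
    def test_published_child_hi_mean(self, published_hi):
        child = published_hi.xs("child", level="cohort")
        assert child.mean() == pytest.approx(8.047, abs=5e-4)

    def test_published_adult_tcr_mean(self, published_cr):
        adult = published_cr.xs("adult", level="cohort")["tcr_printed"]
        assert adult.mean() == pytest.approx(4.42e-3, abs=5e-6)

    def test_single_region_equal_cohorts_gives_unit_ratio(self):
        idx = pd.MultiIndex.from_tuples(
            [("North", "adult"), ("North", "child")],
            names=["region", "cohort"])
        hq = pd.DataFrame({"As": [2.0, 2.0]}, index=idx)
        cr = pd.DataFrame({"As": [1e-3, 1e-3]}, index=idx)
        table = br.RiskTable.from_components(cdi=hq * 0.003, hq=hq, cr=cr)
        s = br.summarize(table)
        assert s.hi_ratio == {"North": pytest.approx(1.0)}
        assert s.hi_min["adult"] <= s.hi_mean["adult"] <= s.hi_max["adult"]


class TestComputeRiskTable:
    def test_hi_scales_with_ir_and_inversely_with_bw(self, study, defaults):
        base = br.compute_risk_table(study, {"adult": defaults.adult},
                                     br.builtin_defaults().tox)
        p = defaults.adult
        doubled_ir = br.ExposureParams("adult", IR=2 * p.IR, EF=p.EF,
                                       ED=p.ED, BW=p.BW, AT=p.AT)
        doubled_bw = br.ExposureParams("adult", IR=p.IR, EF=p.EF,
                                       ED=p.ED, BW=2 * p.BW, AT=p.AT)
        tox = br.builtin_defaults().tox
        hi_ir = br.compute_risk_table(study, {"adult": doubled_ir}, tox).hi
        hi_bw = br.compute_risk_table(study, {"adult": doubled_bw}, tox).hi
        np.testing.assert_allclose(hi_ir.to_numpy(), 2 * base.hi.to_numpy(),
                                   rtol=1e-12)
        np.testing.assert_allclose(hi_bw.to_numpy(), base.hi.to_numpy() / 2,
                                   rtol=1e-12)

    def test_element_without_rfd_is_skipped_with_warning(self, study, defaults,
                                                         caplog):
        tox = dict(br.builtin_defaults().tox)
        tox["Fe"] = br.ToxProfile("Fe", rfd=None, osf=0.01)
        with caplog.at_level("WARNING"):
            table = br.compute_risk_table(study, {"adult": defaults.adult}, tox)
        assert "Fe" not in table.hq.columns
        assert any("Fe" in m for m in caplog.messages)

    def test_fully_censored_elements_absent(self, fitted):
        assert {"Hg", "Pb"}.isdisjoint(fitted.risk_table.hq.columns)
        assert list(fitted.risk_table.cr.columns) == ["As", "Cd"]
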