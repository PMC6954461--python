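"""MIRD dose engine: absorbed doses, effective dose, scaling, cohorts."""

import numpy as np
import pandas as pd
import pytest

from petdose.dosimetry import (DoseReport, TissueWeights, absorbed_doses,
                               cohort_summary, effective_dose, exam_budget,
                               load_published_coefficients, load_tissue_weights,
                               make_report, pediatric_report, report_from_published,
                               scale_to_administered)
from petdose.kinetics import TIACSet
from petdose.nucdata_phantoms import Phantom, SMatrix, load_phantom
from conftest import make_toy_phantom


class TestAbsorbedDoses:
    def test_zero_tiacs_zero_doses(self, toy_phantom, ga68):
        tiacs = TIACSet({"organ_0": 0.0}, 0.0, ga68)
        assert all(v == 0.0 for v in absorbed_doses(tiacs, toy_phantom).values())

    def test_single_source_product(self, ga68):
        sm = SMatrix({("t", "s"): 0.9, ("s", "s"): 1.2, ("t", "total_body"): 0.1,
                      ("s", "total_body"): 0.1}, "x")
        ph = Phantom("toy", {"t": 100.0, "s": 200.0}, 5000.0, sm)
        doses = absorbed_doses(TIACSet({"s": 0.5}, 0.0, ga68), ph)
        assert doses["t"] == pytest.approx(0.45, rel=1e-12)

    def test_whole_body_split_equivalence(self, ga68):
        """Uniform distribution booked organ-by-organ + remainder equals the
        single total-body source, on 100 random toy phantoms."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            ph = make_toy_phantom(rng, n_organs=int(rng.integers(2, 6)))
            tau_total = float(rng.uniform(0.2, 1.5))
            organs = list(ph.organ_masses_g)
            organ_tiacs = {o: tau_total * ph.mass(o) / ph.total_body_mass_g for o in organs}
            m_rob = ph.total_body_mass_g - sum(ph.organ_masses_g.values())
            rem = tau_total * m_rob / ph.total_body_mass_g
            split = absorbed_doses(TIACSet(organ_tiacs, rem, ga68), ph)
            for target in split:
                direct = tau_total * ph.s_matrix.get(target, "total_body")
                assert split[target] == pytest.approx(direct, rel=1e-9)

    def test_linearity_in_tiacs(self, toy_phantom, ga68):
        t1 = TIACSet({"organ_0": 0.15, "organ_1": 0.05}, 0.25, ga68)
        t2 = TIACSet({"organ_0": 0.025, "organ_1": 0.2}, 0.1, ga68)
        combo = TIACSet({"organ_0": 2 * 0.15 + 0.025, "organ_1": 2 * 0.05 + 0.2},
                        2 * 0.25 + 0.1, ga68)
        d1 = absorbed_doses(t1, toy_phantom)
        d2 = absorbed_doses(t2, toy_phantom)
        dc = absorbed_doses(combo, toy_phantom)
        for target in dc:
            assert dc[target] == pytest.approx(2 * d1[target] + d2[target], rel=1e-9)

    def test_unknown_source_rejected(self, toy_phantom, ga68):
        with pytest.raises(ValueError, match="spleen"):
            absorbed_doses(TIACSet({"spleen": 0.1}, 0.0, ga68), toy_phantom)

    def test_missing_self_dose_entry_rejected(self, ga68):
        sm = SMatrix({("t", "s"): 0.9, ("t", "total_body"): 0.1}, "x")
        ph = Phantom("toy", {"t": 100.0, "s": 200.0}, 5000.0, sm)
        with pytest.raises(ValueError, match="self-dose"):
            absorbed_doses(TIACSet({"s": 0.5}, 0.0, ga68), ph)


class TestEffectiveDose:
    def test_uniform_doses_reproduce_dose(self, icrp60):
        ph = load_phantom("adult_female")
        doses = {o: 0.42 for o in set(ph.organ_masses_g) | {"total_body"}}
        assert effective_dose(doses, icrp60, ph) == pytest.approx(0.42, rel=1e-9)

    def test_zero_doses_zero_effective(self, icrp60):
        ph = load_phantom("adult_male")
        doses = {o: 0.0 for o in set(ph.organ_masses_g) | {"total_body"}}
        assert effective_dose(doses, icrp60, ph) == 0.0

    def test_matches_direct_weighted_sum(self, icrp60):
        """Brute-force oracle: resolve every weighted tissue by hand."""
        ph = load_phantom("adult_female")
        rng = np.random.default_rng(12)
        doses = {o: float(rng.uniform(0.001, 0.5))
                 for o in set(ph.organ_masses_g) | {"total_body"}}
        masses = ph.organ_masses_g
        colon = ((doses["upper_large_intestine_wall"] * masses["upper_large_intestine_wall"]
                  + doses["lower_large_intestine_wall"] * masses["lower_large_intestine_wall"])
                 / (masses["upper_large_intestine_wall"] + masses["lower_large_intestine_wall"]))
        rem_organs = [o for o in icrp60.remainder_tissues if o in masses]
        rem = (sum(doses[o] * masses[o] for o in rem_organs)
               / sum(masses[o] for o in rem_organs))
        expected = (0.20 * doses["ovaries"] + 0.12 * doses["red_marrow"] + 0.12 * colon
                    + 0.12 * doses["lungs"] + 0.12 * doses["stomach_wall"]
                    + 0.05 * doses["urinary_bladder_wall"] + 0.05 * doses["breasts"]
                    + 0.05 * doses["liver"] + 0.05 * doses["thymus"]
                    + 0.05 * doses["thyroid"] + 0.01 * doses["skin"]
                    + 0.01 * doses["osteogenic_cells"] + 0.05 * rem)
        assert effective_dose(doses, icrp60, ph) == pytest.approx(expected, rel=1e-12)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TissueWeights("bad", {"gonads": 0.5, "lungs": 0.4})

    def test_packaged_weights_normalized(self, icrp60):
        assert sum(icrp60.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unresolvable_tissue_rejected(self, icrp60):
        ph = load_phantom("adult_female")
        doses = {"kidneys": 0.4}  # almost everything missing
        with pytest.raises(ValueError):
            effective_dose(doses, icrp60, ph)


class TestScaling:
    def test_published_newborn_effective_at_20_mbq(self):
        report = report_from_published("newborn")
        scaled = scale_to_administered(report, 20.0)
        assert scaled.effective_dose_msv == pytest.approx(2.32, abs=1e-9)

    def test_published_adult_kidney_at_100_mbq(self):
        scaled = scale_to_administered(report_from_published("adult"), 100.0)
        assert scaled.organ_doses_mgy["kidneys"] == pytest.approx(47.2, abs=1e-9)

    def test_zero_activity_rejected(self):
        with pytest.raises(ValueError):
            scale_to_administered(report_from_published("adult"), 0.0)

    def test_scaling_is_exact_multiplication(self, toy_phantom, ga68, icrp60):
        # toy phantom lacks ICRP organs; build a minimal report directly
        report = DoseReport("toy", {"organ_0": 0.25, "organ_1": 0.01}, 0.02)
        scaled = scale_to_administered(report, 37.0)
        assert scaled.organ_doses_mgy["organ_0"] == pytest.approx(0.25 * 37.0, rel=1e-15)
        assert scaled.effective_dose_msv == pytest.approx(0.02 * 37.0, rel=1e-15)
        # per-MBq coefficients unchanged
        assert scaled.organ_doses_mgy_per_mbq == report.organ_doses_mgy_per_mbq


class TestExamBudget:
    def test_effective_dose_budget(self):
        assert exam_budget(0.71, 10.0) == 14

    def test_red_marrow_budget(self):
        assert exam_budget(0.6, 250.0) == 416

    def test_limit_equal_to_dose_gives_one(self):
        assert exam_budget(2.5, 2.5) == 1

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            exam_budget(0.0, 10.0)


class TestPediatric:
    def test_zero_tiacs_zero_doses(self, ga68, icrp60):
        ph = load_phantom("newborn")
        report = pediatric_report(TIACSet({"kidneys": 0.0}, 0.0, ga68), ph, icrp60)
        assert report.effective_dose_msv_per_mbq == 0.0
        assert all(v == 0.0 for v in report.organ_doses_mgy_per_mbq.values())

    def test_adult_phantom_rejected(self, ga68, icrp60):
        with pytest.raises(ValueError, match="pediatric"):
            pediatric_report(TIACSet({}, 0.0, ga68), load_phantom("adult_male"), icrp60)

    def test_np_only_self_dose_scales_with_inverse_mass(self, ga68, icrp60):
        """With self-dose-only S values and a pure kidney TIAC, the child/adult
        kidney dose ratio is the adult/child kidney mass ratio."""
        adult = load_phantom("adult_male", np_only=True, nuclide=ga68)
        newborn = load_phantom("newborn", np_only=True, nuclide=ga68)
        tiacs = TIACSet({"kidneys": 0.5}, 0.0, ga68)
        d_adult = absorbed_doses(tiacs, adult)["kidneys"]
        d_newborn = absorbed_doses(tiacs, newborn)["kidneys"]
        assert d_newborn / d_adult == pytest.approx(
            adult.mass("kidneys") / newborn.mass("kidneys"), rel=1e-9)

    def test_pancreas_dose_ordering_across_ages(self, ga68, icrp60):
        """Fixed TIACs give newborn > 1-y > 5-y > adult pancreas doses."""
        tiacs = TIACSet({"kidneys": 0.5, "pancreas": 0.0034}, 0.8, ga68)
        doses = {}
        for model in ("newborn", "one_year", "five_year", "adult_male"):
            doses[model] = absorbed_doses(tiacs, load_phantom(model))["pancreas"]
        assert doses["newborn"] > doses["one_year"] > doses["five_year"] > doses["adult_male"]


class TestCohortSummary:
    def _report(self, kidney, pancreas=0.02, effective=0.007):
        return DoseReport("adult_female", {"kidneys": kidney, "pancreas": pancreas},
                          effective)

    def test_identical_reports_zero_sd(self):
        summary = cohort_summary([self._report(0.5)] * 3)
        assert summary.loc["kidneys", "mean"] == pytest.approx(0.5)
        assert summary.loc["kidneys", "sd"] == pytest.approx(0.0, abs=1e-15)

    def test_two_reports_hand_arithmetic(self):
        summary = cohort_summary([self._report(0.4), self._report(0.6)])
        assert summary.loc["kidneys", "mean"] == pytest.approx(0.5)
        assert summary.loc["kidneys", "sd"] == pytest.approx(0.1414213562, rel=1e-8)

    def test_single_report_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohort_summary([self._report(0.4)])

    def test_heterogeneous_targets_rejected_unless_union(self):
        a = self._report(0.4)
        b = DoseReport("adult_male", {"kidneys": 0.6, "testes": 0.002}, 0.007)
        with pytest.raises(ValueError, match="heterogeneous"):
            cohort_summary([a, b])
        summary = cohort_summary([a, b], union=True)
        assert summary.loc["kidneys", "mean"] == pytest.approx(0.5)
        assert summary.loc["testes", "mean"] == pytest.approx(0.002)

    def test_report_order_follows_reporting_table(self):
        summary = cohort_summary([self._report(0.4), self._report(0.6)])
        assert list(summary.index) == ["kidneys", "pancreas", "effective_dose"]


class TestDoseReportInvariants:
    def test_effective_cannot_exceed_peak_organ_dose(self):
        with pytest.raises(ValueError, match="exceeds"):
            DoseReport("adult_male", {"kidneys": 0.01}, 0.5)

    def test_negative_doses_rejected(self):
        with pytest.raises(ValueError):
            DoseReport("adult_male", {"kidneys": -0.1}, 0.0)

    def test_full_report_from_phantom(self, ga68, icrp60):
        ph = load_phantom("adult_female")
        tiacs = TIACSet({"kidneys": 0.5, "pancreas": 0.0034, "duodenum": 0.003}, 0.8, ga68)
        report = make_report(tiacs, ph, icrp60)
        assert report.organ_doses_mgy_per_mbq["kidneys"] > report.organ_doses_mgy_per_mbq["pancreas"]
        assert 0 < report.effective_dose_msv_per_mbq < report.organ_doses_mgy_per_mbq["kidneys"]
        assert report.provenance["weights"] == "icrp60"


def test_published_coefficient_fixture_shapes():
    frame = load_published_coefficients()
    assert set(frame["model"]) == {"adult", "newborn", "one_year", "five_year"}
    adult = frame[frame["model"] == "adult"]
    assert len(adult) == 26  # 25 sites + effective dose
    assert (frame["mean"] > 0).all()
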