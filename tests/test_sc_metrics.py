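"""Stopping rule, SC mass/thickness, per-site drug amount and depth profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpkbe import (
    SiteRecord,
    StoppingRule,
    StudyDesign,
    TapeGroupRecord,
    check_stopping_rule,
    depth_profile,
    sc_mass_and_thickness,
    site_amount_q,
)
from dpkbe.diffusion import uptake_profile


def make_site(concs, masses=None, design=None, phase="uptake"):
    design = design or StudyDesign()
    masses = masses if masses is not None else [0.5] * len(concs)
    groups = [
        TapeGroupRecord("S01", "REF", phase, 1, i + 1, m, c)
        for i, (m, c) in enumerate(zip(masses, concs))
    ]
    return SiteRecord(design=design, groups=groups)


class TestStoppingRule:
    def test_absolute_limit_fires_first(self):
        d = check_stopping_rule(10.0, [61.0], 12)
        assert d.stop and d.criterion == "absolute_tewl"

    def test_continue_below_all_thresholds(self):
        d = check_stopping_rule(10.0, [30.0], 12)
        assert not d.stop and d.criterion is None

    def test_max_tapes_fires(self):
        d = check_stopping_rule(10.0, [20.0], 30)
        assert d.stop and d.criterion == "max_tapes"

    def test_baseline_multiple_fires(self):
        d = check_stopping_rule(5.0, [31.0], 10)
        assert d.stop and d.criterion == "baseline_multiple"

    def test_reporting_order_absolute_before_multiplier(self):
        # 70 trips both the ceiling and 6x baseline; the ceiling is reported
        d = check_stopping_rule(10.0, [70.0], 10)
        assert d.criterion == "absolute_tewl"

    def test_empty_series_continues_with_warning(self):
        d = check_stopping_rule(10.0, [], 5)
        assert not d.stop and d.warning is not None

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            check_stopping_rule(0.0, [10.0], 5)


class TestMassThickness:
    def test_reference_thickness_conversion(self):
        # 0.93 mg/cm^2 at density 1 g/cm^3 is 9.3 um of SC
        d = StudyDesign(area_cm2=1.0)
        site = make_site([0.1] * 3, masses=[0.31, 0.31, 0.31], design=d)
        mass, thick = sc_mass_and_thickness(site)
        assert mass == pytest.approx(0.93)
        assert thick == pytest.approx(9.3)

    def test_total_mass_over_template_area(self):
        # 4.2 mg over the 5 cm^2 template: 0.84 mg/cm^2 -> 8.4 um
        site = make_site([0.1] * 3, masses=[1.4, 1.4, 1.4])
        mass, thick = sc_mass_and_thickness(site)
        assert mass == pytest.approx(0.84)
        assert thick == pytest.approx(8.4)

    def test_zero_mass_gives_zero_thickness(self):
        site = make_site([0.1], masses=[0.0])
        assert sc_mass_and_thickness(site) == (0.0, 0.0)


class TestSiteAmount:
    def test_sum_of_quantifiable_groups(self):
        site = make_site([0.5, 0.2, 0.1])
        assert site_amount_q(site) == pytest.approx((0.8 * 3.6) / 5.0)

    def test_all_below_loq_gets_half_areal_loq(self):
        site = make_site([0.01, 0.02, 0.005])
        assert site_amount_q(site) == pytest.approx(0.038 * 3.6 / 5.0 / 2.0)
        assert site_amount_q(site) == pytest.approx(0.0137, abs=5e-5)

    def test_group_exactly_at_loq_is_included(self):
        site = make_site([0.038])
        assert site_amount_q(site) == pytest.approx(0.038 * 3.6 / 5.0)

    def test_partially_censored_site_drops_only_censored_groups(self):
        site = make_site([0.5, 0.01])
        assert site_amount_q(site) == pytest.approx(0.5 * 3.6 / 5.0)

    def test_regrouping_conservation(self):
        # pooling two quantifiable groups into one leaves Q unchanged
        fine = make_site([0.3, 0.5, 0.2])
        pooled = make_site([0.8, 0.2])  # concentrations add when extracts pool
        assert site_amount_q(fine) == pytest.approx(site_amount_q(pooled))

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity_above_loq(self, scale):
        base = [0.5, 0.2, 0.1]
        lo = StudyDesign(loq_ug_per_ml=1e-9)  # keep everything quantifiable
        q1 = site_amount_q(make_site(base, design=lo))
        q2 = site_amount_q(make_site([scale * c for c in base], design=lo))
        assert q2 == pytest.approx(scale * q1, rel=1e-12)


class TestDepthProfile:
    def test_widths_sum_to_one(self, sites):
        for site in sites[:10]:
            prof = depth_profile(site)
            assert prof.widths.sum() == pytest.approx(1.0, abs=1e-12)
            assert prof.depth_lower[0] == 0.0

    def test_equal_masses_two_to_one_drug_ratio(self):
        site = make_site([0.4, 0.2], masses=[0.5, 0.5])
        prof = depth_profile(site)
        np.testing.assert_allclose(prof.widths, [0.5, 0.5])
        assert prof.concentrations_ug_cm3[0] / prof.concentrations_ug_cm3[1] == pytest.approx(2.0)

    def test_uniform_drug_per_mass_is_flat(self):
        site = make_site([0.1, 0.2, 0.3], masses=[0.1, 0.2, 0.3])
        prof = depth_profile(site)
        assert np.ptp(prof.concentrations_ug_cm3) == pytest.approx(0.0, abs=1e-9)

    def test_zero_mass_group_flagged(self):
        site = make_site([0.1, 0.2], masses=[0.5, 0.0])
        prof = depth_profile(site)
        assert prof.undefined[1]
        assert prof.widths[1] == 0.0
        assert np.isnan(prof.concentrations_ug_cm3[1])

    def test_diffusion_uptake_profile_decreases_with_depth(self):
        # equal-mass groups carrying drug according to the membrane profile
        # at tau = 0.3 must produce monotonically decreasing concentrations
        edges = np.linspace(0.0, 1.0, 9)
        x = np.linspace(0.0, 1.0, 2001)
        c = uptake_profile(x, 0.3)
        cum = np.concatenate([[0.0], np.cumsum((c[1:] + c[:-1]) / 2 * np.diff(x))])
        drug = np.diff(np.interp(edges, x, cum))
        concs = drug / (3.6 / 1000.0)  # per-group extract concentration
        site = make_site(list(concs), masses=[0.5] * 8,
                         design=StudyDesign(loq_ug_per_ml=1e-12))
        prof = depth_profile(site)
        assert np.all(np.diff(prof.concentrations_ug_cm3) < 0)
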