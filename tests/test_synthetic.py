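"""Synthetic-study generator: determinism, ground-truth recovery, censoring."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dpkbe import (
    StudyDesign,
    fit_lag_time,
    read_study,
    site_amount_q,
    validate_design_balance,
)
from dpkbe.bioequivalence import abe, s_wr
from dpkbe.synthetic import (
    ProductSpec,
    SyntheticStudyConfig,
    generate_site_amounts,
    generate_tape_records,
    generate_tewl_series,
    true_retained_fraction,
)


class TestSiteAmounts:
    def test_noise_free_study_is_deterministic(self):
        cfg = SyntheticStudyConfig(
            sigma_s=0.0, sigma_w=0.0,
            products=(ProductSpec("REF", "reference", 1.0),),
        )
        df = generate_site_amounts(cfg, seed=0)
        up = df[df["phase"] == "uptake"]["q_ug_cm2"]
        cl = df[df["phase"] == "clearance"]["q_ug_cm2"]
        np.testing.assert_allclose(up, cfg.q_up_ref_ug_cm2, rtol=1e-12)
        np.testing.assert_allclose(
            cl, cfg.q_up_ref_ug_cm2 * true_retained_fraction(cfg), rtol=1e-12
        )

    def test_same_seed_identical_output(self):
        cfg = SyntheticStudyConfig()
        a = generate_site_amounts(cfg, seed=5)
        b = generate_site_amounts(cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_parameter_recovery_at_large_n(self):
        cfg = SyntheticStudyConfig(
            design=StudyDesign(n_subjects=500),
            products=(ProductSpec("REF", "reference", 1.0),
                      ProductSpec("TEST", "test", 0.9)),
            sigma_s=0.4, sigma_w=0.3,
        )
        df = generate_site_amounts(cfg, seed=17)
        up = df[df["phase"] == "uptake"]
        ref = up[up["product_code"] == "REF"].pivot(
            index="subject_id", columns="replicate_index", values="q_ug_cm2"
        ).to_numpy()
        assert s_wr(ref) == pytest.approx(0.3, rel=0.05)
        gm = up.groupby(["product_code", "subject_id"])["q_ug_cm2"].apply(
            lambda v: np.exp(np.mean(np.log(v))))
        d = np.log(gm["TEST"].to_numpy()) - np.log(gm["REF"].to_numpy())
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - np.log(0.9)) < 3 * se

    def test_lag_time_recovered_without_noise(self):
        cfg = SyntheticStudyConfig(
            sigma_s=0.0, sigma_w=0.0, true_t_lag_h=18.9,
            products=(ProductSpec("REF", "reference", 1.0),),
        )
        df = generate_site_amounts(cfg, seed=0)
        q_up = df[df["phase"] == "uptake"]["q_ug_cm2"].iloc[0]
        q_cl = df[df["phase"] == "clearance"]["q_ug_cm2"].iloc[0]
        fit = fit_lag_time(q_up, q_cl, cfg.design.t_up_h, cfg.design.delta_t_h)
        assert fit.t_lag_h == pytest.approx(18.9, rel=1e-6)

    def test_log_amounts_are_normal(self):
        cfg = SyntheticStudyConfig(
            design=StudyDesign(n_subjects=500),
            products=(ProductSpec("REF", "reference", 1.0),),
            sigma_s=0.3, sigma_w=0.3,
        )
        df = generate_site_amounts(cfg, seed=23)
        logs = np.log(df[df["phase"] == "uptake"]["q_ug_cm2"].to_numpy())
        # subsample within shapiro's validity range
        p = stats.shapiro(logs[:500]).pvalue
        assert p > 0.01


class TestTapeRecords:
    def test_drug_conservation_before_censoring(self, synth_config):
        tapes = generate_tape_records(synth_config, seed=11)
        amounts = generate_site_amounts(synth_config, seed=11)
        d = synth_config.design
        key = ["subject_id", "product_code", "phase", "replicate_index"]
        sums = (
            tapes.assign(drug=tapes["extract_concentration_ug_ml"] * d.extract_volume_ml)
            .groupby(key)["drug"].sum() / d.area_cm2
        )
        merged = amounts.set_index(key).join(sums.rename("q_regen"))
        np.testing.assert_allclose(merged["q_ug_cm2"], merged["q_regen"], rtol=1e-9)

    def test_same_seed_byte_identical_csv(self, synth_config):
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            generate_tape_records(synth_config, seed=4).to_csv(buf, index=False)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_generated_study_is_balanced(self, sites, design):
        assert validate_design_balance(sites, design).empty

    def test_tape_counts_and_group_sizes_within_protocol(self, sites):
        for site in sites:
            assert site.n_tapes <= 30
            assert all(1 <= g.n_tapes_in_group <= 8 for g in site.groups)

    def test_censoring_path_reduces_low_amount_sites(self):
        cfg = SyntheticStudyConfig(
            q_up_ref_ug_cm2=0.05,
            products=(ProductSpec("REF", "reference", 1.0),),
        )
        tapes = generate_tape_records(cfg, seed=2)
        d = cfg.design
        sites = read_study(io_path(tapes), d)
        any_censored = False
        half_loq = d.loq_areal_ug_per_cm2 / 2
        for site in sites:
            raw = sum(
                g.extract_concentration_ug_ml * d.extract_volume_ml for g in site.groups
            ) / d.area_cm2
            q = site_amount_q(site)
            censored = [
                0 < g.extract_concentration_ug_ml < d.loq_ug_per_ml for g in site.groups
            ]
            if all(censored):
                assert q == pytest.approx(half_loq)  # all-below-LOQ substitution
            else:
                assert q <= raw + 1e-12
                if any(censored):
                    any_censored = True
                    assert q < raw
        assert any_censored


def io_path(df: pd.DataFrame):
    """Write a frame to an in-memory CSV buffer readable by read_study."""
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf


class TestTewl:
    def test_series_is_increasing_on_average_and_seedable(self):
        b1, s1 = generate_tewl_series(20, seed=1)
        b2, s2 = generate_tewl_series(20, seed=1)
        assert (b1, s1) == (b2, s2)
        assert s1[-1] > s1[0] > b1 * 0.9
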