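"""ABE/SABE deciders, the within-subject SD estimator and the model surface."""

import numpy as np
import pandas as pd
import pytest

from dpkbe import (
    BioequivalenceModel,
    abe,
    classify_variability,
    s_wr,
    sabe,
)
from dpkbe.synthetic import ProductSpec, SyntheticStudyConfig, generate_site_amounts


class TestSwr:
    def test_equal_replicates_give_zero(self):
        assert s_wr([[0.5, 0.5], [1.2, 1.2]]) == 0.0

    def test_symmetric_log_spread_closed_form(self):
        # replicates (e^{+a}, e^{-a}) per subject: s_WR = a*sqrt(2), any n
        a = 0.1
        for n in (2, 5, 17):
            reps = np.tile([np.exp(a), np.exp(-a)], (n, 1))
            assert s_wr(reps) == pytest.approx(a * np.sqrt(2), rel=1e-12)

    def test_scale_invariance(self):
        reps = np.array([[0.3, 0.5], [0.8, 1.1], [0.2, 0.9]])
        assert s_wr(reps) == pytest.approx(s_wr(10.0 * reps), rel=1e-12)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            s_wr(np.array([[0.5], [0.7]]))


class TestVariabilityFlag:
    @pytest.mark.parametrize("value,expected", [(0.294, False), (0.599, True), (0.0, False)])
    def test_strict_threshold(self, value, expected):
        assert classify_variability(value).is_highly_variable is expected


class TestAbe:
    def test_identical_products_pass(self):
        q = np.array([0.4, 0.7, 1.1, 0.5])
        r = abe(q, q)
        assert r.gmr == pytest.approx(1.0)
        assert r.abe_pass

    def test_gmr_reciprocity(self):
        rng = np.random.default_rng(3)
        t, r = rng.lognormal(0, 0.4, 8), rng.lognormal(0, 0.4, 8)
        fwd, rev = abe(t, r), abe(r, t)
        assert fwd.gmr * rev.gmr == pytest.approx(1.0, rel=1e-12)
        assert fwd.ci_low == pytest.approx(1.0 / rev.ci_high, rel=1e-12)
        assert fwd.ci_high == pytest.approx(1.0 / rev.ci_low, rel=1e-12)

    def test_pass_fail_scale_invariant(self):
        rng = np.random.default_rng(4)
        t, r = rng.lognormal(0, 0.2, 10), rng.lognormal(0, 0.2, 10)
        base = abe(t, r)
        scaled = abe(1000 * t, 1000 * r)
        assert base.abe_pass == scaled.abe_pass
        assert base.gmr == pytest.approx(scaled.gmr, rel=1e-12)

    def test_pairing_identity_exact(self):
        # exp(mean log difference) equals the ratio of geometric means
        rng = np.random.default_rng(5)
        t, r = rng.lognormal(0, 0.5, 12), rng.lognormal(0, 0.5, 12)
        gm = lambda v: np.exp(np.mean(np.log(v)))
        assert abe(t, r).gmr == pytest.approx(gm(t) / gm(r), rel=1e-12)

    def test_consistency_on_synthetic_study(self):
        cfg = SyntheticStudyConfig(
            design=__import__("dpkbe").StudyDesign(n_subjects=1000),
            products=(ProductSpec("REF", "reference", 1.0), ProductSpec("TEST", "test", 0.9)),
            sigma_s=0.4, sigma_w=0.3,
        )
        df = generate_site_amounts(cfg, seed=9)
        up = df[df["phase"] == "uptake"]
        gms = up.groupby(["product_code", "subject_id"])["q_ug_cm2"].apply(
            lambda v: np.exp(np.mean(np.log(v)))
        )
        r = abe(gms["TEST"].to_numpy(), gms["REF"].to_numpy())
        assert r.gmr == pytest.approx(0.9, abs=0.02)
        assert r.ci_low <= 0.9 <= r.ci_high

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            abe([1.0, 1.1], [1.0, 0.9])


class TestSabe:
    def test_zero_difference_large_swr_passes(self):
        n = 8
        t = np.full(n, 0.6) * np.exp(np.random.default_rng(0).normal(0, 1e-4, n))
        r = np.full(n, 0.6)
        reps = np.array([[0.6 * np.e**0.5, 0.6 * np.e**-0.5]] * n)  # s_WR ~ 0.71
        res = sabe(t, r, reps)
        assert res.scl_ub < 0 and res.sabe_pass

    def test_gmr_constraint_binds(self):
        n = 8
        t = np.full(n, 0.9)
        r = np.full(n, 0.6)  # GMR = 1.5, outside [0.8, 1.25]
        reps = np.array([[0.6 * np.e**1.0, 0.6 * np.e**-1.0]] * n)  # huge s_WR
        res = sabe(t, r, reps)
        assert res.scl_ub < 0
        assert not res.sabe_pass

    def test_sabe_not_stricter_than_abe_at_unity_gmr(self):
        # with GMR = 1, growing reference variability can only move the
        # scaled decider from agreeing with ABE to being more permissive
        rng = np.random.default_rng(21)
        n, nr = 10, 2
        passes_abe = passes_sabe = 0
        for _ in range(400):
            s = rng.normal(0, 0.4, (n, 1))
            t = np.exp(s + rng.normal(0, 0.6, (n, nr)))
            r = np.exp(s + rng.normal(0, 0.6, (n, nr)))
            tg, rg = np.exp(np.log(t).mean(1)), np.exp(np.log(r).mean(1))
            passes_abe += abe(tg, rg).abe_pass
            passes_sabe += sabe(tg, rg, r).sabe_pass
        assert passes_sabe >= passes_abe


@pytest.fixture(scope="module")
def amounts():
    return generate_site_amounts(SyntheticStudyConfig(), seed=14)


class TestModelSurface:
    def test_auto_selects_sabe_for_high_variability(self, amounts):
        res = BioequivalenceModel(amounts, test="TEST", ref="REF", method="auto").fit()
        for phase in ("uptake", "clearance"):
            assert res[phase].s_wr is not None
            if res[phase].s_wr > 0.294:
                assert res[phase].sabe_pass is not None

    def test_frame_and_summary(self, amounts):
        res = BioequivalenceModel(amounts, test="CPLUS", ref="REF").fit()
        frame = res.to_frame()
        assert set(frame["endpoint"]) == {"uptake", "clearance"}
        assert "GMR" in res.summary()

    def test_margin_133_supported(self, amounts):
        res = BioequivalenceModel(amounts, test="CPLUS", ref="REF", margin=1.33).fit()
        assert res["uptake"].margin == 1.33
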