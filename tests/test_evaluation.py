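"""Correlation, SDPE, Steiger's Z, ICC, paired t, repeated splits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pvq
from pvq.errors import InputError
from pvq.evaluation import (EvalReport, icc, invert_sdpe, paired_t, pearson_r,
                            repeated_split_eval, report_from_scores, sdpe,
                            steiger_z)
from pvq.modeling import FeatureTable, RatingSet, VowelQualityModel, split_dataset


class TestPearson:
    def test_perfect_correlations(self):
        a = np.arange(10.0)
        assert pearson_r(a, a)[0] == pytest.approx(1.0)
        assert pearson_r(a, -a + 3)[0] == pytest.approx(-1.0)

    def test_independent_normals_near_zero(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(1000), rng.standard_normal(1000)
        rho, _ = pearson_r(a, b)
        assert abs(rho) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            pearson_r(np.ones(10), np.arange(10.0))


class TestSdpe:
    def test_limits(self):
        assert sdpe(18.0, 0.0) == 18.0
        assert sdpe(18.0, 1.0) == 0.0
        assert sdpe(18.0, -1.0) == 0.0

    def test_published_consistency(self):
        # sigma recovered from one (rho, SDPE) pair reproduces another row
        sigma = invert_sdpe(17.26, 0.28)
        assert sigma == pytest.approx(17.979, abs=5e-3)
        assert round(sdpe(sigma, 0.80), 2) == 10.79

    def test_invalid_rho_rejected(self):
        with pytest.raises(InputError):
            sdpe(10.0, 1.2)

    def test_report_invariant_enforced(self):
        with pytest.raises(InputError):
            EvalReport(rho=0.5, p_value=0.01, sigma_s=10.0, sdpe=9.99,
                       partition="train", n=50)


def _steiger_oracle(r1y, r2y, r12, n):
    """Independent step-by-step coding of the dependent-correlation Z test."""
    z1 = 0.5 * np.log((1 + r1y) / (1 - r1y))
    z2 = 0.5 * np.log((1 + r2y) / (1 - r2y))
    rm2 = ((r1y + r2y) / 2.0) ** 2
    cov = (r12 * (1 - 2 * rm2) - 0.5 * rm2 * (1 - 2 * rm2 - r12 * r12))
    s = cov / ((1 - rm2) * (1 - rm2))
    z = (z1 - z2) * np.sqrt((n - 3) / (2 * (1 - s)))
    p = 2 * (1 - stats.norm.cdf(abs(z)))
    return z, p


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_z(0.6, 0.6, 0.4, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, p1 = steiger_z(0.8, 0.65, 0.5, 113)
        z2, p2 = steiger_z(0.65, 0.8, 0.5, 113)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_agrees_with_independent_coding(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            r1, r2 = rng.uniform(-0.9, 0.9, 2)
            # sample r12 inside the realizable interval for (r1, r2)
            half_width = np.sqrt((1 - r1 ** 2) * (1 - r2 ** 2))
            r12 = r1 * r2 + 0.95 * half_width * rng.uniform(-1, 1)
            n = int(rng.integers(10, 500))
            z, p = steiger_z(r1, r2, r12, n)
            zo, po = _steiger_oracle(r1, r2, r12, n)
            assert z == pytest.approx(zo, abs=1e-8)
            assert p == pytest.approx(po, abs=1e-8)

    def test_degenerate_rejected(self):
        with pytest.raises(InputError):
            steiger_z(1.0, -1.0, 0.0, 50)
        with pytest.raises(InputError):
            steiger_z(0.5, 0.4, 0.3, 3)


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3))
        assert icc(x, "consistency_random") == pytest.approx(1.0)
        assert icc(x, "agreement_mixed") == pytest.approx(1.0)

    def test_constant_offsets_distinguish_flavors(self):
        base = np.arange(12.0)[:, None]
        x = np.hstack([base, base + 5, base + 10])
        assert icc(x, "consistency_random") == pytest.approx(1.0)
        assert icc(x, "agreement_mixed") < 1.0

    def test_matches_variance_component_closed_form(self):
        rng = np.random.default_rng(2)
        m, k = 400, 3
        sigma_t, sigma_e = 15.0, 6.0
        target = rng.normal(50, sigma_t, m)[:, None]
        x = target + rng.normal(0, sigma_e, (m, k))
        # average-measures consistency ICC approaches
        # sigma_t^2 / (sigma_t^2 + sigma_e^2 / k)
        expected = sigma_t ** 2 / (sigma_t ** 2 + sigma_e ** 2 / k)
        assert icc(x, "consistency_random") == pytest.approx(expected, abs=0.05)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(50, 10, (25, 4)) + rng.normal(0, 3, (25, 1))
        long = pd.DataFrame({
            "target": np.repeat(np.arange(25), 4),
            "rater": np.tile(np.arange(4), 25),
            "score": x.ravel()})
        ref = pingouin.intraclass_corr(long, targets="target", raters="rater",
                                       ratings="score").set_index("Type")
        assert icc(x, "agreement_mixed") == pytest.approx(
            ref.loc["ICC(A,k)", "ICC"], abs=1e-6)
        assert icc(x, "consistency_random") == pytest.approx(
            ref.loc["ICC(C,k)", "ICC"], abs=1e-6)

    def test_degenerate_rejected(self):
        with pytest.raises(InputError):
            icc(np.full((5, 3), 7.0), "consistency_random")
        with pytest.raises(InputError):
            icc(np.zeros((1, 3)), "consistency_random")


class TestPairedT:
    def test_identical_samples(self):
        x = np.arange(10.0)
        t, p = paired_t(x, x)
        assert t == 0.0 and p == 1.0

    def test_constant_shift_without_noise_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(InputError):
            paired_t(x, x + 3.0)

    def test_power_at_unit_effect_size(self):
        # shift delta = sigma_d with n = 51 should be detected almost always
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(200):
            d = rng.normal(1.0, 1.0, 51)
            _, p = paired_t(d, np.zeros(51))
            hits += p < 0.01
        assert hits >= 0.95 * 200

    def test_medication_style_paired_cohort(self):
        # improvement concentrated in the poor-quality half of the cohort
        rng = np.random.default_rng(5)
        off = rng.uniform(10, 90, 51)
        gain = np.where(off < 50, rng.uniform(5, 15, 51), rng.normal(0, 2, 51))
        on = off + gain
        poor = off < 50
        _, p_poor = paired_t(off[poor], on[poor])
        _, p_good = paired_t(off[~poor], on[~poor])
        assert p_poor < 0.01
        assert p_good > 0.05


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(6)
    m = 113
    X = rng.standard_normal((m, 4))
    y = 50 + 12 * X[:, 0] - 8 * X[:, 1] + 5 * X[:, 2]
    y += rng.normal(0, 0.3 * np.std(y), m)
    ids = [f"v{i:03d}" for i in range(m)]
    table = FeatureTable(pd.DataFrame(X, columns=list("abcd"), index=ids))
    ratings = RatingSet(pd.DataFrame(
        {"rater_1": y, "rater_2": y, "rater_3": y}, index=ids))
    return table, ratings


class TestRepeatedSplits:

    def test_single_repeat_equals_manual_split(self, planted):
        table, ratings = planted
        pipes = {"lr": {"columns": list("abcd"), "mapper": "lr",
                        "reduction": "none"}}
        res = repeated_split_eval(table, ratings, pipes, n_repeats=1,
                                  base_seed=3)
        (ftr, rtr), (fte, rte) = split_dataset(table, ratings, 0.2, seed=3)
        fit = VowelQualityModel(ftr, rtr).fit(seed=3)
        rep_tr = report_from_scores(fit.y_train, fit.fittedvalues)
        rep_te = report_from_scores(rte.y, fit.predict(fte.df))
        assert res.loc["lr", "train_r"] == pytest.approx(rep_tr.rho)
        assert res.loc["lr", "test_r"] == pytest.approx(rep_te.rho)

    def test_reproducible_given_base_seed(self, planted):
        table, ratings = planted
        pipes = {"lr": {"columns": list("abcd"), "mapper": "lr",
                        "reduction": "none"}}
        a = repeated_split_eval(table, ratings, pipes, n_repeats=3, base_seed=9)
        b = repeated_split_eval(table, ratings, pipes, n_repeats=3, base_seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_correct_model_does_not_overfit(self, planted):
        table, ratings = planted
        pipes = {"lr": {"columns": list("abcd"), "mapper": "lr",
                        "reduction": "none"}}
        res = repeated_split_eval(table, ratings, pipes, n_repeats=10,
                                  base_seed=0)
        assert abs(res.loc["lr", "train_r"] - res.loc["lr", "test_r"]) < 0.05
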