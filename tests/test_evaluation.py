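"""Reliability and diagnostic statistics against independent oracles."""
import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from dcepk.evaluation import (
    bland_altman,
    delong_paired_test,
    evaluate_cohort,
    icc,
    nrmse,
    roc_auc,
    ssim_map,
    subject_score,
)
from dcepk.phantom import generate_cohort
from dcepk.physics import PKMaps


def ssim_by_hand(a, b, data_range, sigma=1.5):
    """Direct Wang-formula SSIM with a Gaussian window, for small images."""
    from scipy.ndimage import gaussian_filter

    k1, k2 = 0.01, 0.03
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    opts = dict(sigma=sigma, truncate=3.5, mode="constant")
    mu_a = gaussian_filter(a, **opts)
    mu_b = gaussian_filter(b, **opts)
    va = gaussian_filter(a * a, **opts) - mu_a**2
    vb = gaussian_filter(b * b, **opts) - mu_b**2
    cab = gaussian_filter(a * b, **opts) - mu_a * mu_b
    s = ((2 * mu_a * mu_b + c1) * (2 * cab + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
    )
    return s


class TestSSIM:
    def test_identical_maps_score_one(self):
        a = np.random.default_rng(0).random((12, 12))
        assert ssim_map(a, a, data_range=1.0) == pytest.approx(1.0)

    def test_anticorrelated_maps_negative(self):
        a = np.random.default_rng(1).random((16, 16))
        b = -a + a.mean() * 2
        assert ssim_map(a, b, data_range=1.0) < 0

    def test_matches_direct_formula(self):
        """Interior pixels agree with a hand-written Wang-formula SSIM."""
        rng = np.random.default_rng(2)
        a = rng.random((24, 24))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        hand = ssim_by_hand(a, b, data_range=1.0)
        # compare interior means (edge handling differs at the border)
        interior = np.zeros(a.shape, bool)
        interior[6:-6, 6:-6] = True
        ours = ssim_map(a, b, mask=interior[..., None] * np.ones((1, 1, 1), bool),
                        data_range=1.0)
        assert ours == pytest.approx(hand[interior[:, :]].mean(), abs=1e-6)

    def test_constant_pair_rejected_without_range(self):
        with pytest.raises(ValueError):
            ssim_map(np.zeros((8, 8)), np.zeros((8, 8)), data_range=0.0)


class TestNRMSE:
    def test_equal_maps_zero(self):
        a = np.random.default_rng(0).random((10, 10))
        assert nrmse(a, a) == 0.0

    def test_constant_offset_closed_form(self):
        a = np.random.default_rng(1).random((10, 10))
        c = 0.17
        b = a + c * (a.max() - a.min())
        assert nrmse(a, b) == pytest.approx(100 * c, rel=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((9, 9)), rng.random((9, 9))
        m = rng.random((9, 9)) > 0.4
        hand = np.sqrt(np.mean((a[m] - b[m]) ** 2)) / (a[m].max() - a[m].min()) * 100
        assert nrmse(a, b, m) == pytest.approx(hand, abs=1e-12)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.ones((4, 4)), np.zeros((4, 4)))


class TestICC:
    def test_matches_anova_hand_formula(self):
        m = np.array([[9.0, 2.0], [1.0, 1.0], [8.0, 4.0], [2.0, 1.0], [10.0, 5.0], [3.0, 2.0]])
        n, k = m.shape
        grand = m.mean()
        msr = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
        sse = ((m - m.mean(1, keepdims=True) - m.mean(0, keepdims=True) + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        hand = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        est, ci, flagged = icc(m)
        assert est == pytest.approx(hand, abs=1e-12)
        assert ci[0] < est < ci[1] and not flagged

    def test_identical_raters_give_one(self):
        m = np.tile(np.arange(1.0, 7.0)[:, None], (1, 2))
        est, ci, flagged = icc(m)
        assert est == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        m = np.random.default_rng(5).normal(size=(200, 2))
        est, ci, _ = icc(m)
        assert ci[0] <= 0.0 <= ci[1]

    def test_zero_between_subject_variance_flagged(self):
        assert icc(np.ones((5, 2)))[2]

    def test_shared_affine_rescaling_invariance(self):
        m = np.random.default_rng(6).normal(size=(20, 3))
        a, _, _ = icc(m)
        b, _, _ = icc(3.5 * m - 1.2)
        assert a == pytest.approx(b, rel=1e-9)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc(np.ones((2, 2)))
        with pytest.raises(ValueError):
            icc(np.ones((5, 1)))


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.arange(5.0)
        assert bland_altman(x, x) == (0.0, (0.0, 0.0))

    def test_hand_arithmetic(self):
        md, (lo, hi) = bland_altman(np.array([0.0, 0.0]), np.array([1.0, -1.0]))
        assert md == 0.0
        assert hi == pytest.approx(1.96 * np.sqrt(2.0))

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        c = 0.7
        md0, loa0 = bland_altman(x, y)
        md1, loa1 = bland_altman(x, y + c)
        assert md1 == pytest.approx(md0 - c)
        assert loa1[0] == pytest.approx(loa0[0] - c)


class TestROC:
    def test_exhaustive_mann_whitney_small_n(self):
        """AUROC == pairwise Mann-Whitney for every labelling at n <= 8."""
        rng = np.random.default_rng(0)
        for n in (4, 6, 8):
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            for pos in itertools.combinations(range(n), n // 2):
                labels = np.zeros(n, int)
                labels[list(pos)] = 1
                auc, _ = roc_auc(scores, labels)
                p, q = scores[labels == 1], scores[labels == 0]
                brute = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                                 for a in p for b in q])
                assert auc == pytest.approx(brute, abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_perfect_separation_and_flip(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        assert roc_auc(scores, labels)[0] == 1.0
        assert roc_auc(scores, 1 - labels)[0] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4, int))


class TestDeLong:
    def test_identical_scores_null_result(self):
        s = np.random.default_rng(0).normal(size=30)
        l = (np.random.default_rng(1).random(30) < 0.5).astype(int)
        assert delong_paired_test(s, s, l) == (0.0, 0.0, 1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        l = (rng.random(40) < 0.5).astype(int)
        a, b = rng.normal(size=40) + l, rng.normal(size=40)
        d1, z1, p1 = delong_paired_test(a, b, l)
        d2, z2, p2 = delong_paired_test(b, a, l)
        assert d2 == pytest.approx(-d1) and p2 == pytest.approx(p1)

    def test_variance_matches_jackknife(self):
        """DeLong AUC variance within 10% of a leave-one-out estimate."""
        rng = np.random.default_rng(3)
        n = 100
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        scores = rng.normal(size=n) + labels
        from dcepk.evaluation import _delong_components

        auc, v10, v01 = _delong_components(scores, labels)
        var_delong = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
        loo = []
        for i in range(n):
            keep = np.ones(n, bool)
            keep[i] = False
            loo.append(roc_auc_score(labels[keep], scores[keep]))
        loo = np.asarray(loo)
        var_jack = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
        assert var_delong == pytest.approx(var_jack, rel=0.10)


@pytest.fixture(scope="module")
def tiny_cohort():
    subs, _ = generate_cohort(8, split=(0.0, 0.0, 1.0), seed=21, render=False)
    return subs


class TestCohortAssembly:
    def _fake_outputs(self, subs, rater_jitter=0.0, sample_jitter=0.0):
        """Pathway outputs derived from ground truth with controllable noise."""
        from dcepk.nets import PredictionSet

        conventional, predictions = {}, {}
        rng = np.random.default_rng(0)
        for s in subs:
            base = s.gt_maps.stack()[..., 0]
            raters = []
            for _ in range(2):
                pert = base * (1 + rater_jitter * rng.normal(size=3)[:, None, None])
                raters.append(PKMaps.from_stack(np.abs(pert)[..., None]))
            conventional[s.subject_id] = raters
            samples = np.stack([
                np.abs(base * (1 + sample_jitter * rng.normal(size=3)[:, None, None]))
                for _ in range(4)
            ])
            predictions[s.subject_id] = PredictionSet.from_samples(samples, (0, 1, 2, 3))
        return conventional, predictions

    def test_identical_samples_give_unit_synthetic_icc(self, tiny_cohort):
        conv, preds = self._fake_outputs(tiny_cohort, rater_jitter=0.1, sample_jitter=0.0)
        rep = evaluate_cohort(tiny_cohort, conv, preds)
        for p in ("ktrans", "ve", "vp"):
            assert rep.icc["synthetic"][p]["icc"] == pytest.approx(1.0)
            assert rep.icc["conventional"][p]["icc"] < 1.0

    def test_duplicated_raters_give_unit_conventional_icc(self, tiny_cohort):
        conv, preds = self._fake_outputs(tiny_cohort, rater_jitter=0.0, sample_jitter=0.05)
        rep = evaluate_cohort(tiny_cohort, conv, preds)
        for p in ("ktrans", "ve", "vp"):
            assert rep.icc["conventional"][p]["icc"] == pytest.approx(1.0)

    def test_missing_pathway_rejected(self, tiny_cohort):
        conv, preds = self._fake_outputs(tiny_cohort)
        preds.pop(tiny_cohort[0].subject_id)
        with pytest.raises(ValueError, match="missing"):
            evaluate_cohort(tiny_cohort, conv, preds)

    def test_report_serialises(self, tiny_cohort, tmp_path):
        conv, preds = self._fake_outputs(tiny_cohort, 0.05, 0.01)
        rep = evaluate_cohort(tiny_cohort, conv, preds)
        out = tmp_path / "report.json"
        rep.to_json(out)
        import json

        loaded = json.loads(out.read_text())
        assert set(loaded["icc"]) == {"conventional", "synthetic"}
        assert loaded["n_test"] == len(tiny_cohort)


class TestSubjectScore:
    def test_masked_means(self):
        maps = PKMaps(
            ktrans=np.array([[[0.1], [0.3]]]),
            ve=np.array([[[0.2], [0.4]]]),
            vp=np.array([[[0.0], [0.1]]]),
        )
        mask = np.array([[[True], [True]]])
        s = subject_score(maps, mask)
        assert s["ktrans"] == pytest.approx(0.2)
        assert s["ve"] == pytest.approx(0.3)

    def test_empty_mask_rejected(self):
        maps = PKMaps(*(np.zeros((2, 2, 1)),) * 3)
        with pytest.raises(ValueError):
            subject_score(maps, np.zeros((2, 2, 1), bool))
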