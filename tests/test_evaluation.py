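"""Metrics against closed forms and a brute-force oracle; folds; statistics."""

import numpy as np
import pytest

from synthct.evaluation import (PSNR_CAP_DB, MetricsRecord, aggregate_records,
                                compare_models, compute_mae_hu, compute_psnr,
                                compute_ssim, cross_validate, kruskal_wallis,
                                make_folds)
from synthct.phantom import generate_dataset, identity_model_ranges


def brute_force_ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Independent SSIM: explicit 11x11 Gaussian-weighted windows at every
    full-window position; no library filtering."""
    sigma, half = 1.5, 5
    x = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-x ** 2 / (2 * sigma ** 2))
    g1 /= g1.sum()
    w = np.outer(g1, g1)
    c1, c2 = 0.01 ** 2, 0.03 ** 2  # data range 1.0
    h, wd = a.shape
    vals = []
    for i in range(half, h - half):
        for j in range(half, wd - half):
            wa = a[i - half:i + half + 1, j - half:j + half + 1]
            wb = b[i - half:i + half + 1, j - half:j + half + 1]
            mu_a = (w * wa).sum()
            mu_b = (w * wb).sum()
            var_a = (w * (wa - mu_a) ** 2).sum()
            var_b = (w * (wb - mu_b) ** 2).sum()
            cov = (w * (wa - mu_a) * (wb - mu_b)).sum()
            vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                        / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))
    return float(np.mean(vals))


def brute_force_psnr(a: np.ndarray, b: np.ndarray) -> float:
    return float(10 * np.log10(1.0 / np.mean((a - b) ** 2)))


class TestMAE:
    def test_identical_zero(self):
        x = np.random.default_rng(0).random((8, 8))
        assert compute_mae_hu(x, x) == 0.0

    def test_constant_shift(self):
        x = np.zeros((8, 8))
        assert compute_mae_hu(x, x + 50.0) == pytest.approx(50.0)

    def test_normalized_difference_scales_to_hu(self):
        # 0.1 in normalized units corresponds to 422.4 HU
        from synthct.preprocess import denormalize
        a = denormalize(np.full((8, 8), 0.5))
        b = denormalize(np.full((8, 8), 0.6))
        assert compute_mae_hu(a, b) == pytest.approx(422.4, abs=1e-3)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            compute_mae_hu(np.zeros((4, 4)), np.zeros((4, 4)),
                           region=np.zeros((4, 4), bool))


class TestPSNR:
    def test_identical_hits_cap(self):
        x = np.random.default_rng(0).random((8, 8))
        assert compute_psnr(x, x) == PSNR_CAP_DB

    def test_constant_difference_closed_forms(self):
        a = np.zeros((8, 8))
        assert compute_psnr(a, a + 0.1) == pytest.approx(20.0, abs=1e-9)
        assert compute_psnr(a, a + 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_decreasing_in_mse(self):
        a = np.zeros((8, 8))
        assert compute_psnr(a, a + 0.05) > compute_psnr(a, a + 0.2)


class TestSSIM:
    def test_identical_images_one(self):
        x = np.random.default_rng(0).random((32, 32))
        assert compute_ssim(x, x) == pytest.approx(1.0)

    def test_inverted_halves_dissimilar(self):
        a = np.zeros((32, 32))
        a[:, 16:] = 1.0
        assert compute_ssim(a, 1.0 - a) < 0.1

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert compute_ssim(a, b) == pytest.approx(compute_ssim(b, a))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            compute_ssim(np.zeros((8, 8)), np.zeros((8, 8)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert compute_ssim(a, b) == pytest.approx(brute_force_ssim(a, b),
                                                   abs=1e-6)
        assert compute_psnr(a, b) == pytest.approx(brute_force_psnr(a, b),
                                                   abs=1e-9)


class TestFolds:
    def test_56_subjects_four_folds_of_14(self):
        ids = [f"p{i}" for i in range(56)]
        split = make_folds(ids, 4, seed=0)
        sizes = [len(split.subjects_in(f)) for f in range(4)]
        assert sizes == [14, 14, 14, 14]
        assert set().union(*[split.subjects_in(f) for f in range(4)]) == set(ids)

    def test_single_fold_contains_all(self):
        split = make_folds(["a", "b", "c"], 1, seed=0)
        assert split.subjects_in(0) == ["a", "b", "c"] or \
            set(split.subjects_in(0)) == {"a", "b", "c"}

    def test_no_subject_in_two_folds(self):
        split = make_folds([f"p{i}" for i in range(10)], 3, seed=2)
        seen = []
        for f in range(3):
            seen += split.subjects_in(f)
        assert len(seen) == len(set(seen)) == 10

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], 3)


class TestCrossValidate:
    def test_identity_plugin_matches_baseline(self):
        pairs = generate_dataset(4, 2, seed=0)
        records = cross_validate(pairs, mode="identity", k=2, seed=0)
        by = {}
        for r in records:
            by.setdefault(r.model_label, []).append(r)
        assert len(records) == len(pairs) * 2
        for rb, ri in zip(by["CBCT"], by["identity sCT"]):
            assert rb.mae == pytest.approx(ri.mae)
            assert rb.ssim == pytest.approx(ri.ssim)

    def test_no_subject_leakage(self):
        pairs = generate_dataset(6, 2, seed=1)
        records = cross_validate(pairs, mode="identity", k=3, seed=1)
        subj_fold = {}
        for r in records:
            subj = r.image_id.split("/")[0]
            subj_fold.setdefault(subj, set()).add(r.fold)
        for folds in subj_fold.values():
            assert len(folds) == 1

    def test_identity_dataset_perfect_metrics(self):
        pairs = generate_dataset(2, 2, model_ranges=identity_model_ranges(),
                                 seed=2)
        records = cross_validate(pairs, mode="identity", k=2, seed=0)
        for r in records:
            assert r.mae == pytest.approx(0.0, abs=1e-6)
            assert r.ssim == pytest.approx(1.0)


class TestCompareModels:
    def test_hand_ranked_kruskal_wallis(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5], [101, 102, 103, 104, 105],
                              [201, 202, 203, 204, 205])
        assert h == pytest.approx(12.5)
        assert p < 0.01

    def test_identical_groups_no_rejection(self):
        h, p = kruskal_wallis([1.0] * 5, [1.0] * 5)
        assert p == pytest.approx(1.0)

    def _records(self, maes, label):
        return [MetricsRecord(ssim=0.9, psnr=30.0, mae=m, model_label=label)
                for m in maes]

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(0)
        groups = {
            "a": self._records(rng.normal(100, 2, 20), "a"),
            "b": self._records(rng.normal(40, 2, 20), "b"),
        }
        report = compare_models(groups)
        assert report.kruskal_p["mae"] < 0.01
        assert report.posthoc["mae"][("a", "b")] is True
        # ssim identical across groups -> no rejection
        assert report.posthoc["ssim"][("a", "b")] is False
        assert report.medians["mae"]["a"] > report.medians["mae"]["b"]

    def test_small_groups_rejected(self):
        groups = {"a": self._records([1, 2], "a"),
                  "b": self._records([3, 4], "b")}
        with pytest.raises(ValueError):
            compare_models(groups)

    def test_aggregate_median_iqr_format(self):
        rng = np.random.default_rng(1)
        records = self._records(rng.normal(50, 5, 12), "m")
        df = aggregate_records(records)
        assert "mae_median" in df.columns
        assert "mae_iqr" in df.columns
        assert df.loc["m", "mae_median"] == pytest.approx(
            np.median([r.mae for r in records]))
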