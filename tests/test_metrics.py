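"""Metric battery: closed forms, invariances and degradation directions."""
import math

import numpy as np
import pytest

from catdeblur.cat import to_grayscale
from catdeblur.data import BlurSpec, FaceFixtureSpec, build_paired_corpus
from catdeblur.exceptions import CatDeblurError, ShapeError, SizeError
from catdeblur.metrics import (RandomProjectionExtractor, ae, brisque_features,
                               brisque_score, evaluate_corpus, fid, fid_from_features,
                               fit_brisque_model, fit_niqe_model, inception_score,
                               mscn_coefficients, niqe_score, psnr, ssim)


@pytest.fixture(scope="module")
def fixture_corpora():
    train = build_paired_corpus(FaceFixtureSpec(seed=0), 12, BlurSpec())
    held = build_paired_corpus(FaceFixtureSpec(seed=500), 8, BlurSpec())
    return train, held


@pytest.fixture(scope="module")
def iqa_models(fixture_corpora):
    train, _ = fixture_corpora
    grays = [to_grayscale(s.clean) for s in train]
    return fit_brisque_model(grays), fit_niqe_model(grays)


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.uniform(0, 255, size=(32, 32))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        x = rng.uniform(0, 255, size=(32, 32))
        y = rng.uniform(0, 255, size=(32, 32))
        assert ssim(x, y) == pytest.approx(ssim(y, x))

    def test_constant_images_closed_form(self):
        a, b = 100.0, 150.0
        c1 = (0.01 * 255) ** 2
        expected = (2 * a * b + c1) / (a ** 2 + b ** 2 + c1)
        got = ssim(np.full((24, 24), a), np.full((24, 24), b))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ssim(np.zeros((16, 16)), np.zeros((16, 17)))


class TestPSNR:
    def test_identical_images_flagged_infinite(self, rng):
        x = rng.uniform(0, 255, size=(16, 16))
        assert math.isinf(psnr(x, x))

    def test_full_range_offset_is_zero_db(self):
        assert psnr(np.zeros((8, 8)), np.full((8, 8), 255.0)) == pytest.approx(0.0)

    @pytest.mark.parametrize("delta", [4.0, 16.0, 51.0])
    def test_uniform_offset_closed_form(self, delta):
        x = np.full((16, 16), 100.0)
        assert psnr(x, x + delta) == pytest.approx(20 * math.log10(255 / delta))


class TestAE:
    def test_identical_is_zero_and_extremes_are_255(self, rng):
        x = rng.uniform(0, 255, size=(8, 8))
        assert ae(x, x) == 0.0
        assert ae(np.zeros((8, 8)), np.full((8, 8), 255.0)) == 255.0

    def test_inverted_checkerboard(self):
        board = np.indices((8, 8)).sum(0) % 2 * 255.0
        assert ae(board, 255.0 - board) == 255.0


class TestNoiseMonotonicity:
    def test_ae_up_ssim_down_with_growing_noise(self, rng):
        x = rng.uniform(40, 215, size=(48, 48))
        prev_ae, prev_ssim = -1.0, 2.0
        for sigma in (2.0, 8.0, 24.0):
            y = np.clip(x + rng.normal(scale=sigma, size=x.shape), 0, 255)
            cur_ae, cur_ssim = ae(x, y), ssim(x, y)
            assert cur_ae > prev_ae and cur_ssim < prev_ssim
            prev_ae, prev_ssim = cur_ae, cur_ssim


class TestFID:
    def test_identical_corpus_scores_zero(self, fixture_corpora):
        _, held = fixture_corpora
        imgs = [s.clean for s in held]
        assert fid(imgs, imgs) == pytest.approx(0.0, abs=1e-6)

    def test_symmetric(self, fixture_corpora):
        _, held = fixture_corpora
        clean = [s.clean for s in held]
        blur = [s.blurred for s in held]
        assert fid(clean, blur) == pytest.approx(fid(blur, clean), rel=1e-6)

    def test_two_gaussian_closed_form_at_n5000(self, rng):
        # equal covariances: FID reduces to the squared mean distance
        dim, n = 8, 5000
        cov_factor = rng.normal(size=(dim, dim)) * 0.3
        m = rng.normal(size=dim)
        z1 = rng.normal(size=(n, dim)) @ cov_factor
        z2 = rng.normal(size=(n, dim)) @ cov_factor + m
        got = fid_from_features(z1, z2)
        assert got == pytest.approx(float(m @ m), rel=0.05)

    def test_empty_corpus_rejected(self):
        with pytest.raises(CatDeblurError):
            fid([], [np.zeros((32, 32, 3))])


class _OneHot:
    """Deterministic K-class one-hot labeler cycling through classes."""

    def __init__(self, k):
        self.k = k
        self.i = -1

    def predict_proba(self, _img):
        self.i += 1
        p = np.zeros(self.k)
        p[self.i % self.k] = 1.0
        return p


class TestInceptionScore:
    def test_uniform_one_hot_labeler_scores_k(self):
        for k in (5, 10):
            res = inception_score(list(range(10 * k)), _OneHot(k), n_splits=10)
            assert res.mean == pytest.approx(k, rel=1e-9)
            assert res.sd == pytest.approx(0.0, abs=1e-9)

    def test_identical_distributions_score_one(self):
        class Flat:
            def predict_proba(self, _):
                return np.full(7, 1 / 7)

        res = inception_score(list(range(20)), Flat(), n_splits=4)
        assert res.mean == pytest.approx(1.0)

    def test_invariant_to_image_order(self, fixture_corpora):
        _, held = fixture_corpora
        imgs = [s.clean for s in held]
        fx = RandomProjectionExtractor()
        a = inception_score(imgs, fx, n_splits=1).mean
        b = inception_score(imgs[::-1], fx, n_splits=1).mean
        assert a == pytest.approx(b)

    def test_unnormalized_classifier_rejected(self):
        class Bad:
            def predict_proba(self, _):
                return np.array([0.5, 0.9])

        with pytest.raises(CatDeblurError):
            inception_score(list(range(4)), Bad(), n_splits=1)


class TestMSCN:
    def test_constant_image_gives_zeros(self):
        assert np.allclose(mscn_coefficients(np.full((16, 16), 120.0)), 0.0)

    def test_mean_near_zero_on_textured_fixture(self, fixture_corpora):
        _, held = fixture_corpora
        m = mscn_coefficients(to_grayscale(held[0].clean))
        assert abs(m.mean()) < 0.05

    def test_approximately_affine_invariant(self, fixture_corpora):
        _, held = fixture_corpora
        g = to_grayscale(held[0].clean)
        m1 = mscn_coefficients(g)
        m2 = mscn_coefficients(1.2 * g + 10.0)
        assert np.mean(np.abs(m1 - m2)) < 0.05

    def test_too_small_image_rejected(self):
        with pytest.raises(SizeError):
            mscn_coefficients(np.zeros((4, 4)))


class TestBrisque:
    def test_feature_vector_is_36_dimensional(self, fixture_corpora):
        _, held = fixture_corpora
        assert brisque_features(to_grayscale(held[0].clean)).shape == (36,)

    def test_deterministic(self, fixture_corpora, iqa_models):
        _, held = fixture_corpora
        bm, _ = iqa_models
        g = to_grayscale(held[0].clean)
        assert brisque_score(g, bm) == brisque_score(g, bm)

    def test_blur_degrades_score(self, fixture_corpora, iqa_models):
        _, held = fixture_corpora
        bm, _ = iqa_models
        for s in held:
            assert (brisque_score(to_grayscale(s.blurred), bm)
                    > brisque_score(to_grayscale(s.clean), bm))

    def test_missing_model_rejected(self):
        with pytest.raises(CatDeblurError):
            brisque_score(np.zeros((32, 32)), None)


class TestNiqe:
    def test_nonnegative_and_deterministic(self, fixture_corpora, iqa_models):
        _, held = fixture_corpora
        _, nm = iqa_models
        g = to_grayscale(held[0].clean)
        a, b = niqe_score(g, nm), niqe_score(g, nm)
        assert a == b >= 0.0

    def test_blur_degrades_score(self, fixture_corpora, iqa_models):
        _, held = fixture_corpora
        _, nm = iqa_models
        clean = np.mean([niqe_score(to_grayscale(s.clean), nm) for s in held])
        blur = np.mean([niqe_score(to_grayscale(s.blurred), nm) for s in held])
        assert blur > clean


class TestEvaluateCorpus:
    def test_identical_corpora_hit_metric_optima(self, fixture_corpora):
        _, held = fixture_corpora
        imgs = [s.clean for s in held]
        report = evaluate_corpus(imgs, imgs)
        assert np.allclose(report.per_image["ssim"], 1.0)
        assert np.allclose(report.per_image["ae"], 0.0)
        assert report.corpus_level["fid"] == pytest.approx(0.0, abs=1e-6)

    def test_rerun_is_identical_and_has_nine_table_rows(self, fixture_corpora, iqa_models):
        _, held = fixture_corpora
        bm, nm = iqa_models
        kw = dict(brisque_model=bm, niqe_model=nm)
        r1 = evaluate_corpus([s.blurred for s in held], [s.clean for s in held], **kw)
        r2 = evaluate_corpus([s.blurred for s in held], [s.clean for s in held], **kw)
        assert r1.per_image.equals(r2.per_image)
        assert r1.corpus_level == r2.corpus_level
        assert list(r1.summary().keys()) == ["niqe", "brisque", "diqa_srcc", "diqa_plcc",
                                             "ssim", "psnr", "ae", "fid", "is"]

    def test_report_serialization(self, fixture_corpora, tmp_path):
        _, held = fixture_corpora
        report = evaluate_corpus([s.blurred for s in held], [s.clean for s in held])
        report.to_json(tmp_path / "r.json")
        report.to_csv(tmp_path / "r.csv")
        assert (tmp_path / "r.json").stat().st_size > 0


class TestDegradationDirection:
    """Blur must move every implemented metric in its published direction."""

    def test_all_arrows_point_the_right_way(self, fixture_corpora, iqa_models):
        _, held = fixture_corpora
        bm, nm = iqa_models
        clean = [s.clean for s in held]
        blurred = [s.blurred for s in held]
        fx = RandomProjectionExtractor()
        kw = dict(extractor=fx, brisque_model=bm, niqe_model=nm)
        ref = evaluate_corpus(clean, clean, **kw).summary()
        deg = evaluate_corpus(blurred, clean, **kw).summary()
        assert ref["ssim"] > deg["ssim"]
        assert ref["psnr"] > deg["psnr"]
        assert ref["is"] > deg["is"]
        assert ref["ae"] < deg["ae"]
        assert ref["fid"] < deg["fid"]
        assert ref["brisque"] < deg["brisque"]
        assert ref["niqe"] < deg["niqe"]
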