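"""Generator contracts: closed forms, seed reproducibility, configured rates."""

import warnings

import numpy as np
import pytest
from scipy import stats

from phenomap.encoding import encode_weekly
from phenomap.synthetic import (
    AcquisitionProfile,
    PhenologyModel,
    SceneConfig,
    default_phenologies,
    simulate_acquisitions,
    simulate_landscape,
    simulate_phenology,
    simulate_reference_products,
)


def masked_nearest_centroid(Xtr, ytr, Xte):
    """Gap-aware nearest-centroid oracle on encoded 52x9 matrices.

    Centroids average only filled weeks; distances use only the test
    sample's observed weeks, so acquisition-gap patterns do not drown
    the class signal.
    """
    codes = np.array(sorted(set(ytr)))
    cents = []
    for c in codes:
        Xc = Xtr[ytr == c]
        filled = Xc.any(axis=2)
        cent = np.zeros(Xc.shape[1:])
        for w in range(Xc.shape[1]):
            if filled[:, w].any():
                cent[w] = Xc[filled[:, w], w].mean(axis=0)
        cents.append(cent)
    C = np.array(cents)
    pred = []
    for x in Xte:
        fw = x.any(axis=1)
        d = ((x[fw][None] - C[:, fw]) ** 2).sum(axis=(1, 2))
        pred.append(codes[d.argmin()])
    return np.array(pred)


class TestPhenology:
    def test_zero_noise_equals_closed_form(self):
        m = PhenologyModel(6, (0.1,) * 6, (0.3,) * 6, 120, 280, noise_sd=0.0)
        dates = [1, 60, 150, 200, 300, 365]
        s = simulate_phenology(m, dates, np.random.default_rng(0))
        t = np.asarray(dates, float)
        expected = 0.1 + 0.3 * (
            1 / (1 + np.exp(-0.10 * (t - 120))) + 1 / (1 + np.exp(0.08 * (t - 280))) - 1
        )
        np.testing.assert_allclose(s.values, np.tile(expected[:, None], (1, 6)))

    def test_zero_amplitude_is_constant(self):
        m = PhenologyModel(1, (0.25,) * 6, (0.0,) * 6, 100, 280, noise_sd=0.0)
        s = simulate_phenology(m, [10, 180, 360], np.random.default_rng(0))
        np.testing.assert_allclose(s.values, 0.25)

    def test_two_seeds_differ_same_dates(self):
        m = default_phenologies()[10]
        dates = [50, 150, 250]
        a = simulate_phenology(m, dates, np.random.default_rng(1))
        b = simulate_phenology(m, dates, np.random.default_rng(2))
        np.testing.assert_array_equal(a.doy, b.doy)
        assert not np.allclose(a.values, b.values)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PhenologyModel(1, (0.9,) * 6, (0.3,) * 6, 100, 280)  # base+amp > 1
        with pytest.raises(ValueError):
            PhenologyModel(1, (0.1,) * 6, (0.3,) * 6, 280, 100)  # greenup after


class TestAcquisitions:
    def test_tiny_rate_usually_empty(self):
        prof = AcquisitionProfile(2018, 0.001)
        rng = np.random.default_rng(0)
        counts = [len(simulate_acquisitions(prof, rng)) for _ in range(200)]
        assert np.mean(counts) < 0.05

    def test_mean_count_matches_rate(self):
        prof = AcquisitionProfile(2018, 12.0)
        rng = np.random.default_rng(42)
        counts = [len(simulate_acquisitions(prof, rng)) for _ in range(1000)]
        assert np.mean(counts) == pytest.approx(12.0, rel=0.05)

    def test_uniform_weights_give_uniform_weeks(self):
        prof = AcquisitionProfile(2018, 10.0, week_weights=(1.0,) * 52)
        rng = np.random.default_rng(7)
        weeks = []
        while len(weeks) < 10_000:
            d = simulate_acquisitions(prof, rng)
            weeks.extend(((d - 1) // 7).clip(max=51).tolist())
        observed = np.bincount(np.asarray(weeks[:10_000]), minlength=52)
        # week 51 holds 9 days (359..366 folded), weeks 0..50 hold 7
        probs = np.full(52, 7 / 365.0)
        probs[51] = 9 / 365.0
        chi2 = ((observed - 10_000 * probs) ** 2 / (10_000 * probs)).sum()
        assert chi2 < stats.chi2.ppf(0.999, 51)

    def test_all_dates_clear_and_sorted(self):
        prof = AcquisitionProfile(2018, 25.0)
        d = simulate_acquisitions(prof, np.random.default_rng(3))
        assert (np.diff(d) > 0).all() and d.min() >= 1 and d.max() <= 365


class TestLandscape:
    def test_identity_rotation_keeps_crops(self):
        from phenomap.legend import CROP_CODES

        rot = {c: {c: 1.0} for c in CROP_CODES}
        cfg = SceneConfig(shape=(12, 12), years=[2016, 2017, 2018], n_patches=16,
                          rotation=rot, peat_expansion_rate=0, seed=5)
        scene = simulate_landscape(cfg)
        d = scene.truth.data
        np.testing.assert_array_equal(d[0], d[1])
        np.testing.assert_array_equal(d[0], d[2])

    def test_zero_expansion_keeps_exploited_area_constant(self):
        cfg = SceneConfig(shape=(12, 12), years=[2016, 2017, 2018], n_patches=16,
                          peat_expansion_rate=0, seed=5)
        scene = simulate_landscape(cfg)
        areas = [(g == 8).sum() for g in scene.truth.data]
        assert len(set(areas)) == 1

    def test_positive_expansion_is_monotone_and_capped(self):
        cfg = SceneConfig(shape=(10, 10), years=list(range(2016, 2022)),
                          n_patches=9, classes=(8, 9, 3), peat_expansion_rate=30,
                          seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scene = simulate_landscape(cfg)
        areas = [(g == 8).sum() for g in scene.truth.data]
        assert all(b >= a for a, b in zip(areas, areas[1:]))
        total_bog = ((scene.truth.data[0] == 8) | (scene.truth.data[0] == 9)).sum()
        assert areas[-1] <= total_bog

    def test_rotation_frequencies_match_matrix(self):
        # two-crop world with stay probability 0.7; patches rotate as units
        rot = {10: {10: 0.7, 11: 0.3}, 11: {10: 0.3, 11: 0.7}}
        cfg = SceneConfig(shape=(30, 30), years=list(range(2016, 2022)),
                          n_patches=100, classes=(10, 11), rotation=rot,
                          peat_expansion_rate=0, seed=9)
        scene = simulate_landscape(cfg)
        # count per-patch transitions (patches are the independent units)
        stays = trials = 0
        for t in range(1, len(scene.truth.years)):
            for p in np.unique(scene.patch_id):
                m = scene.patch_id == p
                prev = scene.truth.data[t - 1][m][0]
                cur = scene.truth.data[t][m][0]
                trials += 1
                stays += prev == cur
        phat = stays / trials
        se = np.sqrt(0.7 * 0.3 / trials)
        assert abs(phat - 0.7) < 2 * se

    def test_bit_exact_reproducibility(self):
        cfg = SceneConfig(shape=(8, 8), years=[2016, 2017], n_patches=10, seed=21)
        a = simulate_landscape(cfg)
        b = simulate_landscape(cfg)
        np.testing.assert_array_equal(a.truth.data, b.truth.data)
        sa = a.series[(3, 3)][2016]
        sb = b.series[(3, 3)][2016]
        np.testing.assert_array_equal(sa.doy, sb.doy)
        np.testing.assert_array_equal(sa.values, sb.values)


class TestReferenceProducts:
    def test_zero_contamination_builtup_imperviousness(self, small_scene):
        rng = np.random.default_rng(0)
        stack = simulate_reference_products(small_scene.truth, rng)
        builtup = small_scene.truth.data[0] == 1
        for year in (2006, 2009, 2012, 2015, 2018):
            imperv = stack.get("imperviousness", year)
            assert (imperv[builtup] >= 51).all()
            assert (imperv[~builtup] == 0).all()

    def test_zero_disagreement_is_relabeled_truth(self, small_scene):
        from phenomap.synthetic import CLC_CODES

        rng = np.random.default_rng(0)
        stack = simulate_reference_products(small_scene.truth, rng)
        clc = stack.get("clc_code", 2012)
        water = small_scene.truth.data[0] == 3
        assert (clc[water] == CLC_CODES["water"]).all()

    def test_disagreement_rate_binomial(self):
        cfg = SceneConfig(shape=(100, 100), years=[2018], n_patches=25, seed=4)
        scene = simulate_landscape(cfg)
        rng = np.random.default_rng(1)
        clean = simulate_reference_products(scene.truth, np.random.default_rng(1))
        noisy = simulate_reference_products(scene.truth, rng, disagreement=0.1)
        frac = (noisy.get("clc_code", 2012) != clean.get("clc_code", 2012)).mean()
        assert frac == pytest.approx(0.1, abs=0.01)


class TestSeparability:
    def test_nearest_centroid_oracle_recovers_classes(self):
        """Default phenologies are separable at >= 20 clear obs/year."""
        rng = np.random.default_rng(42)
        phen = default_phenologies()
        prof = AcquisitionProfile(2018, 20.0)

        def make(n):
            X, y = [], []
            for code, m in phen.items():
                for _ in range(n):
                    d = simulate_acquisitions(prof, rng)
                    s = simulate_phenology(m, d, rng)
                    X.append(encode_weekly(s).matrix)
                    y.append(code)
            return np.array(X), np.array(y)

        Xtr, ytr = make(25)
        Xte, yte = make(25)
        pred = masked_nearest_centroid(Xtr, ytr, Xte)
        assert (pred == yte).mean() >= 0.95
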