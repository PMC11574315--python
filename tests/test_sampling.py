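"""Spectral-temporal metrics, the rule engine, sampling caps and parcels."""

import numpy as np
import pytest

from phenomap.encoding import ObservationSeries
from phenomap.geoio import GeoTransform
from phenomap.sampling import (
    Condition,
    RuleSpec,
    builtin_rules,
    compute_stm,
    evaluate_rule,
    rasterize_crop_parcels,
    sample_points,
    CropParcel,
    INVARIANT_CLASS_CAP,
    CROP_CLASS_CAP,
)
from phenomap.synthetic import (
    CLC_CODES,
    N2K_CODES,
    ReferenceStack,
    simulate_reference_products,
)


def series_with_ndvi(values, year=2018):
    """Series whose NDVI equals `values` exactly (red=0, nir=v scaled)."""
    values = np.asarray(values, float)
    doy = np.arange(1, len(values) + 1)
    bands = np.zeros((len(values), 6))
    bands[:, 3] = values  # nir=v, red=0 -> ndvi = v/v = 1... need care
    # use red such that (nir-red)/(nir+red) = v with nir+red = 0.5
    bands[:, 3] = 0.25 * (1 + values)
    bands[:, 0] = 0.25 * (1 - values)
    return ObservationSeries(year, doy, bands, np.ones(len(values), bool))


class TestSTM:
    def test_constant_series_any_percentile(self):
        smap = {(0, 0): {2018: series_with_ndvi([0.4, 0.4, 0.4])}}
        for pct in (10, 50, 90):
            out = compute_stm(smap, (1, 1), "ndvi", pct)
            assert out[0, 0] == pytest.approx(0.4)

    def test_linear_interpolation_percentile(self):
        smap = {(0, 0): {2018: series_with_ndvi([0.1, 0.2, 0.3, 0.4])}}
        assert compute_stm(smap, (1, 1), "ndvi", 90)[0, 0] == pytest.approx(0.37)

    def test_p10_below_p90_everywhere(self, rng):
        smap = {}
        for i in range(5):
            vals = rng.uniform(-0.5, 0.9, 12)
            smap[(0, i)] = {2018: series_with_ndvi(vals)}
        p10 = compute_stm(smap, (1, 5), "ndvi", 10)
        p90 = compute_stm(smap, (1, 5), "ndvi", 90)
        assert (p10 <= p90 + 1e-12).all()

    def test_no_observations_is_nodata(self):
        empty = ObservationSeries(2018, np.zeros(0, int), np.zeros((0, 6)),
                                  np.zeros(0, bool))
        out = compute_stm({(0, 0): {2018: empty}}, (1, 1), "ndvi", 50)
        assert np.isnan(out[0, 0])


def brute_force_eligibility(stack, rule, shape):
    """Exhaustive per-pixel, per-condition oracle (plain Python loops)."""
    rows, cols = shape
    ops = {">": lambda a, b: a > b, "<": lambda a, b: a < b,
           "==": lambda a, b: a == b, ">=": lambda a, b: a >= b,
           "<=": lambda a, b: a <= b}
    out = np.zeros(shape, bool)
    for r in range(rows):
        for c in range(cols):
            ok = True
            for cond in rule.conditions:
                if cond.window == 5:
                    if not (2 <= r < rows - 2 and 2 <= c < cols - 2):
                        ok = False
                        break
                    cells = [(rr, cc) for rr in range(r - 2, r + 3)
                             for cc in range(c - 2, c + 3)]
                    if cond.quantifier == "ring":
                        cells = [p for p in cells if p != (r, c)]
                else:
                    cells = [(r, c)]
                for year in cond.years:
                    for rr, cc in cells:
                        if cond.kind == "cmp":
                            v = stack.get(cond.product, year)[rr, cc]
                            if np.isnan(float(v)) or not ops[cond.op](v, cond.threshold):
                                ok = False
                        elif cond.kind == "in_set":
                            v = stack.get(cond.product, year)[rr, cc]
                            if v not in cond.codes:
                                ok = False
                        else:
                            a = stack.get(cond.product[0], year)[rr, cc]
                            b = stack.get(cond.product[1], year)[rr, cc]
                            if not any(a == x and b == y for x, y in cond.pairs):
                                ok = False
                if not ok:
                    break
            out[r, c] = ok
    return out


class TestRuleEngine:
    def _random_stack(self, rng, shape=(12, 12)):
        stack = ReferenceStack(products={})
        for year in (2006, 2009, 2012, 2015, 2018):
            stack.add("imperviousness", year,
                      rng.choice([0, 0, 10, 30, 60, 90], size=shape).astype(float))
        for year in (2012, 2015, 2018):
            stack.add("tree_density", year,
                      rng.choice([0, 0, 20, 50, 80, 95], size=shape).astype(float))
        for year in (2006, 2012, 2015, 2018):
            stack.add("forest_type", year, rng.choice([0, 1, 2], size=shape))
        clc = list(CLC_CODES.values())
        n2k = list(N2K_CODES.values())
        for year in (2006, 2012, 2018):
            stack.add("clc_code", year, rng.choice(clc, size=shape))
            stack.add("n2k_code", year, rng.choice(n2k, size=shape))
        stack.add("ndvi_p90", None, rng.uniform(-1, 1, shape))
        stack.add("ndwi_p90", None, rng.uniform(-1, 1, shape))
        stack.add("ndwi_p10", None, rng.uniform(-1, 1, shape))
        return stack

    def test_rule_count_is_ten(self):
        assert len(builtin_rules()) == 10

    def test_builtup_center_threshold_is_strict(self):
        rule = next(r for r in builtin_rules() if r.name == "Built-up")
        center = [c for c in rule.conditions if c.quantifier == "center"][0]
        assert center.op == ">" and center.threshold == 50.0
        ring = [c for c in rule.conditions if c.quantifier == "ring"][0]
        assert ring.op == ">" and ring.threshold == 20.0

    def test_exploited_bog_rule_years(self):
        rule = next(r for r in builtin_rules() if r.name == "Exploited peat bog")
        for cond in rule.conditions:
            assert cond.years == (2006, 2012, 2018)
        n2k = [c for c in rule.conditions if c.product == "n2k_code"][0]
        assert n2k.codes == (N2K_CODES["exploited_peat"],)

    def test_water_rule_worked_example(self):
        shape = (5, 5)
        stack = ReferenceStack(products={})
        for year in (2006, 2009, 2012, 2015, 2018):
            stack.add("imperviousness", year, np.zeros(shape))
        stack.add("ndwi_p10", None, np.full(shape, 0.4))
        stack.add("ndvi_p90", None, np.full(shape, 0.1))
        rule = next(r for r in builtin_rules() if r.name == "Water")
        assert evaluate_rule(stack, rule).all()
        # one imperviousness violation in one year makes the pixel ineligible
        stack.products["imperviousness"][2012][2, 2] = 5.0
        mask = evaluate_rule(stack, rule)
        assert not mask[2, 2] and mask.sum() == 24

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_rules_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        stack = self._random_stack(rng)
        for rule in builtin_rules():
            got = evaluate_rule(stack, rule)
            want = brute_force_eligibility(stack, rule, (12, 12))
            np.testing.assert_array_equal(got, want, err_msg=rule.name)

    def test_adding_condition_never_adds_pixels(self, rng):
        stack = self._random_stack(rng)
        base = RuleSpec("t", 2, 2, (
            Condition("cmp", "ndvi_p90", (None,), "<", 0.3),
        ))
        extended = RuleSpec("t", 2, 2, base.conditions + (
            Condition("cmp", "imperviousness", (2006,), "==", 0.0),
        ))
        m1 = evaluate_rule(stack, base)
        m2 = evaluate_rule(stack, extended)
        assert not (m2 & ~m1).any()

    def test_missing_product_named_in_error(self):
        stack = ReferenceStack(products={})
        rule = builtin_rules()[0]
        with pytest.raises(KeyError, match="imperviousness"):
            evaluate_rule(stack, rule)

    def test_sampled_points_have_rule_class_on_clean_scene(self, small_scene):
        from phenomap.sampling import add_stm_products

        rng = np.random.default_rng(0)
        stack = simulate_reference_products(small_scene.truth, rng)
        add_stm_products(stack, small_scene.series, small_scene.truth.shape)
        base = small_scene.truth.data[0]
        for rule in builtin_rules():
            mask = evaluate_rule(stack, rule)
            pts = np.argwhere(mask)
            for r, c in pts:
                if rule.target_level == 2:
                    assert base[r, c] == rule.target_code, rule.name
                else:
                    assert base[r, c] >= 10 or base[r, c] == 18, rule.name


class TestSamplePoints:
    def test_cap_semantics(self, rng):
        mask = np.ones((150, 100), bool)  # 15,000 eligible
        pts = sample_points(mask, 10_000, rng)
        assert len(pts) == 10_000
        assert INVARIANT_CLASS_CAP == 10_000 and CROP_CLASS_CAP == 50_000

    def test_fewer_eligible_than_cap(self, rng):
        mask = np.zeros((50, 50), bool)
        mask[:10, :20] = True
        pts = sample_points(mask, 10_000, rng)
        assert len(pts) == 200

    def test_seed_contract(self):
        mask = np.ones((60, 60), bool)
        a = sample_points(mask, 100, np.random.default_rng(5))
        b = sample_points(mask, 100, np.random.default_rng(5))
        c = sample_points(mask, 100, np.random.default_rng(6))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            pts = sample_points(np.zeros((5, 5), bool), 10, np.random.default_rng(0))
        assert len(pts) == 0


class TestCropParcels:
    transform = GeoTransform(0.0, 3000.0, 30.0)

    def test_aligned_square_parcel_labels_nine_pixels(self):
        from shapely.geometry import box

        parcel = CropParcel(box(300, 3000 - 390, 390, 3000 - 300), 2019, 10)
        out = rasterize_crop_parcels([parcel], self.transform, (20, 20))
        assert (out[2019] == 10).sum() == 9

    def test_overlapping_parcels_become_nodata(self):
        from shapely.geometry import box

        g = box(300, 3000 - 390, 390, 3000 - 300)
        out = rasterize_crop_parcels(
            [CropParcel(g, 2019, 10), CropParcel(g, 2019, 11)],
            self.transform, (20, 20),
        )
        assert (out[2019] != 0).sum() == 0

    def test_empty_parcel_set(self):
        assert rasterize_crop_parcels([], self.transform, (10, 10)) == {}

    def test_unknown_label_rejected(self):
        from shapely.geometry import box

        with pytest.raises(ValueError, match="7"):
            rasterize_crop_parcels(
                [CropParcel(box(0, 0, 30, 30), 2019, 7)], self.transform, (10, 10)
            )
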