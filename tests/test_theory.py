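"""Solids-of-revolution theory: closed forms, Pappus quadrature, bounds."""

import math

import numpy as np
import pytest

from spindleasym.theory import (
    InvalidShapeError,
    ShapeFunction,
    SolidOfRevolutionPole,
    SpindleModel,
    bounds_eq6,
    cone_closed_form,
    delta_2d_from_model,
    delta_v_from_model,
    epsilon_delta,
    pappus_volume,
    random_shape_function,
    random_spindle_model,
    spheroid_closed_form,
    voxel_volume_oracle,
)


class TestClosedForms:
    def test_spheroid_printed_formulas(self):
        v, a = spheroid_closed_form(2, 3)
        assert v == pytest.approx(8 * math.pi)
        assert a == pytest.approx(3 * math.pi)
        v11, _ = spheroid_closed_form(1, 1)
        assert v11 == pytest.approx(2 * math.pi / 3)

    def test_spheroid_volume_area_proportionality(self, rng):
        # V = 4 A d / 3 for every spheroid pole
        for d, w in rng.uniform(0.2, 5.0, size=(20, 2)):
            v, a = spheroid_closed_form(d, w)
            assert v / (a * d) == pytest.approx(4 / 3)

    def test_cone_printed_formulas(self):
        assert cone_closed_form(2, 3) == pytest.approx((math.pi, 3.0))
        assert cone_closed_form(1, 1) == pytest.approx((math.pi / 12, 0.5))

    def test_cone_proportionality_shape_independent(self, rng):
        consts = set()
        for d, w in rng.uniform(0.2, 5.0, size=(10, 2)):
            v, a = cone_closed_form(d, w)
            consts.add(round(v / (a * d), 12))
        assert len(consts) == 1

    @pytest.mark.parametrize("fn", [spheroid_closed_form, cone_closed_form])
    def test_nonpositive_dimensions_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0, 1)


class TestPappus:
    def test_spheroid_matches_closed_form(self):
        # the classical half-spheroid formulas use the equatorial radius,
        # so the equivalent revolution region has diameter 2 d
        v_cf, a_cf = spheroid_closed_form(2, 3)
        pole = SolidOfRevolutionPole(ShapeFunction.spheroid(), diameter=4, width=3)
        q = pappus_volume(pole)
        assert q.volume == pytest.approx(v_cf, rel=1e-6)
        assert 2 * q.area_AD == pytest.approx(a_cf, rel=1e-4)

    def test_cone_matches_closed_form(self):
        pole = SolidOfRevolutionPole(ShapeFunction.cone(), diameter=2, width=3)
        q = pappus_volume(pole)
        assert q.volume == pytest.approx(math.pi, rel=1e-6)
        # A(D) is the half cross-section: for f(u)=1-u, A(D) = d w / 4
        assert q.area_AD == pytest.approx(2 * 3 / 4)

    def test_pappus_identity_v_equals_2pi_a_rbar(self, rng):
        for _ in range(10):
            pole = random_spindle_model(rng).left
            q = pappus_volume(pole)
            assert q.volume == pytest.approx(2 * math.pi * q.area_AD * q.centroid_rbar)

    def test_invalid_shape_rejected(self):
        with pytest.raises(InvalidShapeError):
            ShapeFunction(lambda u: 0.5 + 0 * u)  # f(0) != 1

    def test_quadrature_floor(self):
        pole = SolidOfRevolutionPole(ShapeFunction.cone(), 1, 1)
        with pytest.raises(ValueError):
            pappus_volume(pole, n_quad=8)


class TestVoxelOracle:
    @pytest.mark.parametrize(
        "shape, d, w, expected",
        [
            ("spheroid", 2.0, 2.0, None),  # hemisphere-like, vs Pappus
            ("cone", 2.0, 3.0, math.pi),
        ],
    )
    def test_matches_closed_form_within_1pct(self, shape, d, w, expected):
        sf = ShapeFunction.spheroid() if shape == "spheroid" else ShapeFunction.cone()
        pole = SolidOfRevolutionPole(sf, d, w)
        target = expected if expected is not None else pappus_volume(pole).volume
        assert voxel_volume_oracle(pole, 0.02) == pytest.approx(target, rel=0.01)

    def test_refinement_reduces_error(self):
        pole = SolidOfRevolutionPole(ShapeFunction.spheroid(), 2, 2)
        truth = pappus_volume(pole).volume
        coarse = abs(voxel_volume_oracle(pole, 0.04) - truth)
        fine = abs(voxel_volume_oracle(pole, 0.01) - truth)
        assert fine < coarse

    def test_coarse_grid_warns(self):
        pole = SolidOfRevolutionPole(ShapeFunction.cone(), 1, 1)
        with pytest.warns(UserWarning):
            voxel_volume_oracle(pole, 0.2)


class TestModelDeltas:
    def test_equal_diameters_make_2d_and_3d_identical(self, rng):
        for _ in range(10):
            model = random_spindle_model(rng, diameter_ratio=1.0)
            assert delta_v_from_model(model) == pytest.approx(
                delta_2d_from_model(model), abs=1e-9
            )

    def test_spheroid_width_ratio_case(self):
        # equal diameters, w_L = 1.5 w_R: areas scale with w, so both
        # differences equal (1.5 - 1)/(1.5 + 1) * 100 = 20
        shape = ShapeFunction.spheroid()
        model = SpindleModel(
            left=SolidOfRevolutionPole(shape, 2.0, 3.0),
            right=SolidOfRevolutionPole(shape, 2.0, 2.0),
        )
        assert delta_2d_from_model(model) == pytest.approx(20.0, abs=1e-9)
        assert delta_v_from_model(model) == pytest.approx(20.0, abs=1e-9)

    def test_delta_v_equals_weighted_area_formula(self, rng):
        # two independent code paths: Pappus volumes vs the
        # diameter-weighted area combination
        for _ in range(10):
            model = random_spindle_model(rng, diameter_ratio=1.2)
            a_l = model.left.cross_section_area()
            a_r = model.right.cross_section_area()
            expected = (1.2 * a_l - a_r) / (1.2 * a_l + a_r) * 100.0
            assert delta_v_from_model(model) == pytest.approx(expected, abs=1e-6)

    def test_centroid_ratio_equals_diameter_ratio(self, rng):
        for _ in range(50):
            model = random_spindle_model(rng, monotone=bool(rng.integers(2)))
            rho = (
                pappus_volume(model.left).centroid_rbar
                / pappus_volume(model.right).centroid_rbar
            )
            assert rho == pytest.approx(model.diameter_ratio, abs=1e-9)


class TestBounds:
    def test_equal_diameters_collapse_to_delta(self):
        assert bounds_eq6(20.0, 1.0) == pytest.approx((20.0, 20.0))

    def test_zero_delta_collapses_to_epsilon(self):
        lo, hi = bounds_eq6(0.0, 2.0)
        assert lo == pytest.approx(100 / 3)
        assert hi == pytest.approx(100 / 3)

    def test_near_unity_ratio_bounds(self):
        # delta = 20 at the typical diameter ratio 1.09
        eps = (1.09 - 1) / (1.09 + 1) * 100
        lo, hi = bounds_eq6(20.0, 1.09)
        assert hi == pytest.approx(1.09 * 20 + eps)
        assert lo == pytest.approx(20 / 1.09 + eps)
        assert lo < hi

    def test_exact_relation_lies_within_bounds_everywhere(self):
        # the exact map Delta_V(Delta) for fixed delta must be enveloped
        for ratio in (0.7, 0.9, 1.09, 1.3, 1.8):
            e = epsilon_delta(ratio) / 100
            for d in np.linspace(0, 99, 150):
                x = d / 100
                dv = (x + e) / (1 + e * x) * 100
                lo, hi = bounds_eq6(d, ratio)
                assert lo - 1e-9 <= dv <= hi + 1e-9

    def test_containment_on_random_models(self, rng):
        for _ in range(200):
            model = random_spindle_model(rng).canonicalized()
            d2 = delta_2d_from_model(model)
            dv = delta_v_from_model(model)
            lo, hi = bounds_eq6(d2, model.diameter_ratio)
            assert lo - 1e-9 <= dv <= hi + 1e-9


class TestShapeFunctions:
    def test_random_shapes_hit_endpoints(self, rng):
        for monotone in (True, False):
            f = random_shape_function(rng, monotone=monotone)
            assert float(f(0.0)) == pytest.approx(1.0, abs=1e-9)
            assert float(f(1.0)) == pytest.approx(0.0, abs=1e-9)
            assert np.all(f(np.linspace(0, 1, 500)) >= -1e-12)

    def test_json_round_trip(self, tmp_path):
        model = SpindleModel(
            left=SolidOfRevolutionPole(ShapeFunction.cone(), 2.4, 1.5),
            right=SolidOfRevolutionPole(ShapeFunction.cone(), 2.0, 1.8),
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SpindleModel.from_json(path)
        assert back.diameter_ratio == pytest.approx(1.2)
        assert delta_v_from_model(back) == pytest.approx(delta_v_from_model(model))

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            SpindleModel(
                left=SolidOfRevolutionPole(ShapeFunction.cone(), 2, 1),
                right=SolidOfRevolutionPole(ShapeFunction.spheroid(), 2, 1),
            )
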