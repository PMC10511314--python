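"""Aitchison-geometry primitives: worked examples, round trips, invariants.

Closure, clr and perturbation are cross-checked against scikit-bio's
implementations; pivot coordinates are cross-checked against a direct
evaluation of the defining log-ratio formula.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coda24 import (
    ALL_BASES,
    PARTS,
    Composition,
    CompositionError,
    PivotBasis,
    closure,
    clr,
    clr_inverse,
    compositional_mean,
    first_pivot_all_parts,
    inverse_pivot,
    perturb,
    perturbation_difference,
    pivot_coordinates,
)
from conftest import random_compositions

positive_parts = st.lists(
    st.floats(min_value=1e-3, max_value=1e3), min_size=4, max_size=4
)


class TestClosure:
    def test_minutes_example(self):
        c = closure([497, 584, 282, 77])
        np.testing.assert_allclose(
            c.values,
            [0.345138888889, 0.405555555556, 0.195833333333, 0.053472222222],
            atol=1e-10,
        )
        np.testing.assert_allclose(c.minutes, [497, 584, 282, 77], atol=1e-9)

    def test_already_closed_is_identity(self):
        c = closure([0.25, 0.25, 0.25, 0.25])
        np.testing.assert_allclose(c.values, 0.25)

    def test_zero_part_errors_with_behavior_name(self):
        with pytest.raises(CompositionError, match="lpa"):
            closure([1, 1, 0, 1])
        with pytest.raises(CompositionError, match="mvpa"):
            closure([1, 1, 1, -2])

    @given(positive_parts, st.floats(min_value=0.1, max_value=100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariant_and_idempotent(self, raw, c):
        base = closure(raw)
        np.testing.assert_allclose(closure(np.array(raw) * c).values, base.values,
                                   atol=1e-12)
        np.testing.assert_allclose(closure(base.values).values, base.values,
                                   atol=1e-12)

    def test_matches_skbio(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        raw = rng.uniform(0.5, 100, size=(20, 4))
        ours = np.stack([closure(r).values for r in raw])
        np.testing.assert_allclose(ours, skbio_comp.closure(raw), atol=1e-12)

    def test_zero_replacement_option(self):
        c = closure([1, 1, 1, 0], zero_replacement=1e-5)
        assert c.values[3] == pytest.approx(1e-5)
        assert c.values.sum() == pytest.approx(1.0)


class TestPerturbation:
    def test_change_example(self):
        post = Composition.from_minutes([520, 572, 272, 76])
        pre = Composition.from_minutes([497, 584, 282, 77])
        diff = perturbation_difference(post, pre)
        np.testing.assert_allclose(
            diff.values,
            [0.263063504422, 0.246261674431, 0.242512116625, 0.248162704522],
            atol=1e-10,
        )

    def test_no_change_is_neutral_element(self):
        x = Composition.from_minutes([480, 600, 280, 80])
        np.testing.assert_allclose(
            perturbation_difference(x, x).values, 0.25, atol=1e-12
        )

    def test_round_trip_pre_plus_diff_recovers_post(self, rng):
        for pre, post in zip(random_compositions(rng, 1000),
                             random_compositions(rng, 1000)):
            diff = perturbation_difference(post, pre)
            np.testing.assert_allclose(
                perturb(pre, diff).values, post.values, atol=1e-10
            )

    def test_matches_skbio_perturb(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        x, y = random_compositions(rng, 2)
        np.testing.assert_allclose(
            perturb(x, y).values, skbio_comp.perturb(x.values, y.values), atol=1e-12
        )


class TestCompositionalMean:
    def test_constant_sample_is_idempotent(self):
        x = Composition.from_minutes([497, 584, 282, 77])
        np.testing.assert_allclose(
            compositional_mean([x, x, x]).values, x.values, atol=1e-12
        )

    def test_two_point_hand_computation(self):
        # closure of part-wise geometric means of the two compositions
        m = compositional_mean(
            [Composition((0.4, 0.3, 0.2, 0.1)), Composition((0.1, 0.2, 0.3, 0.4))]
        )
        np.testing.assert_allclose(
            m.values,
            [0.224744871392, 0.275255128608, 0.275255128608, 0.224744871392],
            atol=1e-10,
        )

    def test_equals_inverse_ilr_of_mean_ilr(self, rng):
        sample = random_compositions(rng, 50)
        basis = ALL_BASES["sleep"]
        z_mean = np.mean([pivot_coordinates(x, basis) for x in sample], axis=0)
        np.testing.assert_allclose(
            compositional_mean(sample).values,
            inverse_pivot(z_mean, basis).values,
            atol=1e-12,
        )

    def test_empty_sample_errors(self):
        with pytest.raises(CompositionError):
            compositional_mean([])


class TestClr:
    def test_reference_example(self):
        x = Composition.from_minutes([497, 584, 282, 77])
        np.testing.assert_allclose(
            clr(x),
            [0.5675391506675, 0.7288501073991, 0.0008561955090, -1.2972454535750],
            atol=1e-10,
        )

    def test_equal_composition_maps_to_zero(self):
        np.testing.assert_allclose(clr(Composition((0.25,) * 4)), 0.0, atol=1e-12)

    def test_zero_sum_and_linearity_under_perturbation(self, rng):
        for x, y in zip(random_compositions(rng, 200), random_compositions(rng, 200)):
            cx, cy, cxy = clr(x), clr(y), clr(perturb(x, y))
            assert abs(cx.sum()) < 1e-12
            np.testing.assert_allclose(cxy, cx + cy, atol=1e-10)

    def test_matches_skbio_clr(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        x = random_compositions(rng, 1)[0]
        np.testing.assert_allclose(clr(x), skbio_comp.clr(x.values), atol=1e-12)

    def test_clr_inverse_round_trip(self, rng):
        x = random_compositions(rng, 1)[0]
        np.testing.assert_allclose(clr_inverse(clr(x)).values, x.values, atol=1e-12)


class TestPivotBasis:
    @pytest.mark.parametrize("part", PARTS)
    def test_orthonormal_zero_sum_columns(self, part):
        V = ALL_BASES[part].contrast_matrix
        np.testing.assert_allclose(V.T @ V, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(V.sum(axis=0), 0.0, atol=1e-12)

    @pytest.mark.parametrize("part", PARTS)
    def test_order_puts_pivot_first_rest_canonical(self, part):
        basis = ALL_BASES[part]
        assert basis.order[0] == part
        assert basis.order[1:] == tuple(p for p in PARTS if p != part)

    def test_unknown_behavior_rejected(self):
        with pytest.raises(CompositionError):
            PivotBasis("napping")


class TestPivotCoordinates:
    def test_reference_example_sleep_first(self):
        x = Composition.from_minutes([497, 584, 282, 77])
        np.testing.assert_allclose(
            pivot_coordinates(x, ALL_BASES["sleep"]),
            [0.6553377628270, 1.1243523190815, 0.9178964787370],
            atol=1e-10,
        )

    def test_equal_composition_maps_to_origin(self):
        z = pivot_coordinates(Composition((0.25,) * 4), ALL_BASES["lpa"])
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    @pytest.mark.parametrize("part", PARTS)
    def test_matches_direct_log_ratio_formula(self, part, rng):
        # independent evaluation of z_k = sqrt((D-k)/(D-k+1)) ln(x_k/gm(rest))
        basis = ALL_BASES[part]
        for x in random_compositions(rng, 20):
            v = np.array([x[p] for p in basis.order])
            expected = [
                np.sqrt((4 - k) / (4 - k + 1))
                * np.log(v[k - 1] / np.exp(np.mean(np.log(v[k:]))))
                for k in (1, 2, 3)
            ]
            np.testing.assert_allclose(
                pivot_coordinates(x, basis), expected, atol=1e-10
            )

    def test_ilr_linearity_on_perturbations(self, rng):
        basis = ALL_BASES["sed"]
        for x, y in zip(random_compositions(rng, 200), random_compositions(rng, 200)):
            np.testing.assert_allclose(
                pivot_coordinates(perturb(x, y), basis),
                pivot_coordinates(x, basis) + pivot_coordinates(y, basis),
                atol=1e-10,
            )

    def test_round_trips_both_ways(self, rng):
        basis = ALL_BASES["mvpa"]
        for x in random_compositions(rng, 1000):
            z = pivot_coordinates(x, basis)
            np.testing.assert_allclose(
                inverse_pivot(z, basis).values, x.values, atol=1e-10
            )
        for z in rng.normal(0, 1.5, size=(200, 3)):
            np.testing.assert_allclose(
                pivot_coordinates(inverse_pivot(z, basis), basis), z, atol=1e-10
            )

    def test_inverse_of_origin_is_equal_composition(self):
        np.testing.assert_allclose(
            inverse_pivot([0, 0, 0], ALL_BASES["sleep"]).values, 0.25, atol=1e-12
        )

    def test_inverse_reference_example(self):
        c = inverse_pivot(
            [0.6553377628270, 1.1243523190815, 0.9178964787370], ALL_BASES["sleep"]
        )
        np.testing.assert_allclose(
            c.values,
            [0.345138888889, 0.405555555556, 0.195833333333, 0.053472222222],
            atol=1e-10,
        )

    def test_inverse_rejects_non_finite(self):
        with pytest.raises(CompositionError):
            inverse_pivot([np.nan, 0, 0], ALL_BASES["sleep"])


class TestFirstPivotAllParts:
    def test_reference_example(self):
        x = Composition.from_minutes([497, 584, 282, 77])
        np.testing.assert_allclose(
            first_pivot_all_parts(x),
            [0.6553377628270, 0.8416036114115, 0.0009886494151, -1.4979300236536],
            atol=1e-10,
        )

    def test_zero_sum_and_clr_identity(self, rng):
        for x in random_compositions(rng, 200):
            fp = first_pivot_all_parts(x)
            assert abs(fp.sum()) < 1e-10
            np.testing.assert_allclose(fp, np.sqrt(4 / 3) * clr(x), atol=1e-12)

    def test_matches_first_coordinate_of_each_basis(self, rng):
        for x in random_compositions(rng, 20):
            fp = first_pivot_all_parts(x)
            for j, part in enumerate(PARTS):
                assert fp[j] == pytest.approx(
                    pivot_coordinates(x, ALL_BASES[part])[0], abs=1e-12
                )


class TestCompositionType:
    def test_minutes_view_sums_to_day(self):
        c = Composition.from_minutes([480, 600, 280, 80])
        assert c.minutes.sum() == pytest.approx(1440.0, abs=1e-9)
        assert c.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_part_lookup_and_dict(self):
        c = Composition.from_minutes([480, 600, 280, 80])
        assert c["sed"] == pytest.approx(600 / 1440)
        assert c.as_dict(minutes=True)["mvpa"] == pytest.approx(80)

    def test_wrong_length_rejected(self):
        with pytest.raises(CompositionError):
            Composition((0.5, 0.5))
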