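"""The four channel representations and the physical factor."""

import datetime as dt
import math

import numpy as np
import pytest

from eupkit.data_io import CaseDayRecord
from eupkit.environment import EnvironmentItem, EnvironmentWindow
from eupkit.eup_features import (
    FeatureBundle,
    PhysicalUncertainty,
    Projector,
    cosine_similarity,
    env_feature,
    environment_representation,
    framing_feature,
    physical_factor,
    physical_feature,
    similarity_representation,
    uncertainty_representation,
)


def make_env(items, kind="macro"):
    return EnvironmentWindow(post_id="p", kind=kind, items=items, T=3)


def item(doc_id, emb, sim, unc, t=0.0):
    return EnvironmentItem(doc_id, np.asarray(emb, dtype=float), sim, unc, t)


class TestCosine:
    def test_examples(self):
        v = np.array([1.0, 2.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([-1.0, 0.0])) == pytest.approx(-1.0)

    def test_zero_vector_convention(self):
        assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0


class TestRepresentations:
    def test_single_identical_item(self):
        p = np.array([0.6, 0.8])
        env = make_env([item("e", p, 1.0, 0.3)])
        assert np.allclose(similarity_representation(p, env), p * p)

    def test_empty_environment_is_zero(self):
        p = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(similarity_representation(p, make_env([])), np.zeros(3))
        assert np.array_equal(uncertainty_representation(make_env([]), dim=3), np.zeros(3))

    def test_three_item_hand_computation(self):
        p = np.array([1.0, 2.0])
        env = make_env(
            [
                item("a", [1.0, 0.0], 0.5, 0.2),
                item("b", [0.0, 1.0], -0.5, 0.4),
                item("c", [2.0, 2.0], 1.0, 1.0),
            ]
        )
        # S = mean_i s_i * (p ⊙ e_i), computed coordinate by coordinate
        expected_S = (
            0.5 * np.array([1.0 * 1.0, 2.0 * 0.0])
            + -0.5 * np.array([1.0 * 0.0, 2.0 * 1.0])
            + 1.0 * np.array([1.0 * 2.0, 2.0 * 2.0])
        ) / 3.0
        assert np.allclose(similarity_representation(p, env), expected_S, atol=1e-12)
        expected_U = (
            0.2 * np.array([1.0, 0.0]) + 0.4 * np.array([0.0, 1.0]) + 1.0 * np.array([2.0, 2.0])
        ) / 3.0
        assert np.allclose(uncertainty_representation(env), expected_U, atol=1e-12)

    def test_uncertainty_weights(self):
        emb = np.array([3.0, -1.0])
        assert np.allclose(uncertainty_representation(make_env([item("a", emb, 0.1, 1.0)])), emb)
        zeros = make_env([item("a", emb, 0.1, 0.0), item("b", emb, 0.2, 0.0)])
        assert np.array_equal(uncertainty_representation(zeros), np.zeros(2))

    def test_dimension_mismatch_rejected(self):
        env = make_env([item("a", [1.0, 2.0, 3.0], 0.5, 0.1)])
        with pytest.raises(ValueError, match="dimension"):
            similarity_representation(np.array([1.0, 2.0]), env)


class TestProjectors:
    def test_identity_projector_preserves_concatenation(self):
        p = np.array([1.0, -1.0])
        env = make_env([item("a", [0.5, 0.25], 1.0, 0.8)])
        rep = environment_representation(p, env)
        out = env_feature(rep, Projector.identity(4))
        assert np.allclose(out, np.concatenate([rep.S, rep.U]))

    def test_zero_input_gives_bias(self):
        proj = Projector(np.zeros((4, 2)), b=np.array([0.7, -0.3]))
        rep = environment_representation(np.array([1.0, 1.0]), make_env([]))
        assert np.allclose(env_feature(rep, proj), [0.7, -0.3])

    def test_projector_rejects_wrong_dimension(self):
        with pytest.raises(ValueError, match="dimension"):
            Projector.identity(3)(np.ones(4))

    def test_random_projector_reproducible(self):
        x = np.arange(6.0)
        assert np.allclose(Projector.random(6, 3, seed=9)(x), Projector.random(6, 3, seed=9)(x))


class TestFraming:
    def test_scaling_endpoints(self):
        p = np.array([2.0, -4.0])
        proj = Projector.identity(2)
        assert np.allclose(framing_feature(p, 0.0, proj), np.zeros(2))
        assert np.allclose(framing_feature(p, 1.0, proj), p)

    def test_linear_in_uncertainty(self):
        p = np.array([2.0, -4.0, 1.0])
        proj = Projector(np.eye(3))  # linear, no bias
        assert np.allclose(2 * framing_feature(p, 0.5, proj), framing_feature(p, 1.0, proj))

    def test_out_of_range_uncertainty_rejected(self):
        with pytest.raises(ValueError):
            framing_feature(np.ones(2), 1.5, Projector.identity(2))


def series_from_counts(cases, news):
    start = dt.date(2020, 3, 1)
    return [
        CaseDayRecord(start + dt.timedelta(days=i), c, m)
        for i, (c, m) in enumerate(zip(cases, news))
    ]


class TestPhysicalFactor:
    def test_zero_case_change_annihilates(self):
        series = series_from_counts([10, 10, 14], [5, 9, 11])
        phys = PhysicalUncertainty(series)
        assert phys.raw_factor(series[1].date) == 0.0  # ln 1 = 0

    def test_hand_computed_raw_value(self):
        series = series_from_counts([10, 11, 11], [5, 7, 7])
        phys = PhysicalUncertainty(series)
        assert phys.raw_factor(series[1].date) == pytest.approx(math.log(2) * math.log(3), abs=1e-12)

    def test_normalization_maps_min_to_zero_max_to_one(self):
        series = series_from_counts([10, 10, 50, 51], [5, 9, 30, 40])
        phys = PhysicalUncertainty(series).fit()
        values = [phys.factor(rec.date) for rec in series[1:]]
        assert min(values) == 0.0
        assert max(values) == 1.0
        assert all(0.0 <= v <= 1.0 for v in values)

    def test_train_only_bounds_clip_outside_dates(self):
        series = series_from_counts([10, 12, 20, 200], [5, 7, 9, 90])
        train_dates = [series[1].date, series[2].date]
        phys = PhysicalUncertainty(series).fit(train_dates)
        assert phys.factor(series[3].date) == 1.0  # above the training max, clipped

    def test_missing_dates_error(self):
        series = series_from_counts([10, 12], [5, 7])
        phys = PhysicalUncertainty(series).fit()
        with pytest.raises(KeyError):
            phys.factor(dt.date(2021, 1, 1))
        with pytest.raises(KeyError):
            phys.factor(series[0].date)  # first day has no predecessor

    def test_series_gap_rejected(self):
        series = series_from_counts([10, 12], [5, 7])
        series[1] = CaseDayRecord(series[1].date + dt.timedelta(days=5), 12, 7)
        with pytest.raises(ValueError, match="gap"):
            PhysicalUncertainty(series)

    def test_monotone_in_case_change(self):
        values = []
        for delta in range(0, 40, 4):
            series = series_from_counts([100, 100 + delta], [50, 60])
            values.append(PhysicalUncertainty(series).raw_factor(series[1].date))
        assert values == sorted(values)

    def test_one_shot_wrapper(self):
        series = series_from_counts([10, 10, 50], [5, 9, 30])
        assert physical_factor(series, series[1].date) == 0.0


class TestPhysicalFeature:
    def test_zero_factor_annihilates(self):
        proj = Projector(np.zeros((6, 2)), b=np.array([0.1, 0.2]))
        out = physical_feature(0.0, np.ones(2), np.ones(2), np.ones(2), proj)
        assert np.allclose(out, [0.1, 0.2])

    def test_identity_recovers_scaled_concatenation(self):
        proj = Projector.identity(6)
        I_M, I_C, I_F = np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])
        out = physical_feature(0.5, I_M, I_C, I_F, proj)
        assert np.allclose(out, 0.5 * np.concatenate([I_M, I_C, I_F]))

    def test_homogeneous_in_factor(self):
        proj = Projector(np.eye(6)[:, :2])  # linear, no bias
        args = (np.ones(2), 2 * np.ones(2), 3 * np.ones(2))
        assert np.allclose(2 * physical_feature(0.4, *args, proj), physical_feature(0.8, *args, proj))


class TestFeatureBundle:
    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            FeatureBundle(np.ones(2), np.ones(2), np.ones(3), np.ones(2), 0.5)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            FeatureBundle(np.array([np.nan, 1.0]), np.ones(2), np.ones(2), np.ones(2), 0.5)
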