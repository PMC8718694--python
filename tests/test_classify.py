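"""Per-reaction classifier training, tuning, filtering and profiling."""
import numpy as np
import pytest

from wcflux.classify import (
    ClassifierRecord,
    ClassifierSpec,
    cross_validate,
    filter_classifiers,
    full_grid,
    grid_search,
    make_flux_profile,
    prepare_classifier_input,
    train_reaction_classifier,
)
from wcflux.errors import (
    DegenerateInputError,
    DegenerateLabelError,
    InvalidArgumentError,
    MissingSeriesError,
)
from wcflux.types import FluxSeries, SimulationRecord


def _separable_data(rng, n=60, dim=20):
    """Two well-separated input shapes with consistent labels."""
    half = n // 2
    X0 = np.tile(np.linspace(0, 1, dim), (half, 1)) + rng.normal(
        0, 0.02, (half, dim)
    )
    X1 = np.tile(np.linspace(1, 0, dim), (n - half, 1)) + rng.normal(
        0, 0.02, (n - half, dim)
    )
    X = np.vstack([X0, X1])
    y = np.array([0] * half + [1] * (n - half))
    return X, y


SMALL = dict(width=16, epochs=15, batch_size=8)


class TestPrepareClassifierInput:
    def test_uniform_grid_preserved_up_to_scaling(self):
        t = np.linspace(0, 100, 50)
        y = np.sin(t / 10) + 2
        out = prepare_classifier_input(FluxSeries(t, y), target_length=50)
        rescaled = (y - y.min()) / (y.max() - y.min())
        assert np.allclose(out, rescaled, atol=1e-12)

    def test_constant_series_maps_to_zeros(self):
        out = prepare_classifier_input(
            FluxSeries(np.arange(10.0), np.full(10, 3.3)), 25
        )
        assert out.shape == (25,) and not out.any()

    def test_downsampled_line_matches_analytic_interpolation(self):
        t = np.linspace(0, 499, 500)
        out = prepare_classifier_input(FluxSeries(t, t.copy()), 100)
        assert np.allclose(out, np.linspace(0, 1, 100), atol=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            prepare_classifier_input(
                FluxSeries(np.array([]), np.array([])), 10
            )


class TestTrainReactionClassifier:
    def test_separable_inputs_reach_high_holdout_accuracy(self, rng):
        X, y = _separable_data(rng)
        clf = train_reaction_classifier(
            X, y, ClassifierSpec(seed=3, **SMALL)
        )
        assert clf.holdout_accuracy >= 0.95

    def test_permuted_labels_give_chance_level(self, rng):
        X, _ = _separable_data(rng, n=80)
        y = rng.permutation([0] * 40 + [1] * 40)
        clf = train_reaction_classifier(
            X, y, ClassifierSpec(seed=5, **SMALL)
        )
        assert abs(clf.holdout_accuracy - 0.5) <= 0.15

    def test_same_seed_and_data_reproduce_accuracy(self, rng):
        X, y = _separable_data(rng, n=40)
        spec = ClassifierSpec(seed=11, **SMALL)
        a = train_reaction_classifier(X, y, spec).holdout_accuracy
        b = train_reaction_classifier(X, y, spec).holdout_accuracy
        assert a == b

    def test_single_class_labels_rejected(self, rng):
        X, _ = _separable_data(rng, n=20)
        with pytest.raises(DegenerateLabelError):
            train_reaction_classifier(
                X, np.zeros(20, dtype=int), ClassifierSpec(**SMALL)
            )

    def test_five_hidden_layers_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ClassifierSpec(hidden_layers=5)


class TestGridSearch:
    def test_singleton_grid_returns_that_spec(self, rng):
        X, y = _separable_data(rng, n=40)
        spec = ClassifierSpec(seed=2, **SMALL)
        clf, rec = grid_search(X, y, [spec])
        assert rec.spec == spec

    def test_clean_labels_beat_corrupted_on_planted_winner(self, rng):
        X, y = _separable_data(rng, n=60)
        y_bad = y.copy()
        flip = rng.choice(len(y), size=len(y) // 2, replace=False)
        y_bad[flip] = 1 - y_bad[flip]
        spec = ClassifierSpec(seed=4, **SMALL)
        acc_clean = train_reaction_classifier(X, y, spec).holdout_accuracy
        acc_bad = train_reaction_classifier(X, y_bad, spec).holdout_accuracy
        assert acc_clean > acc_bad

    def test_grid_winner_attains_max_of_individual_fits(self, rng):
        X, y = _separable_data(rng, n=40)
        grid = [
            ClassifierSpec(width=8, epochs=e, batch_size=8, seed=6)
            for e in (2, 15)
        ]
        clf, rec = grid_search(X, y, grid)
        individual = [
            train_reaction_classifier(X, y, s).holdout_accuracy for s in grid
        ]
        assert rec.holdout_accuracy == pytest.approx(max(individual))

    def test_full_grid_has_27_points(self):
        grid = full_grid()
        assert len(grid) == 27
        assert len({(s.epochs, s.batch_size, s.width) for s in grid}) == 27


class TestCrossValidate:
    def test_k_below_two_rejected(self, rng):
        X, y = _separable_data(rng, n=20)
        with pytest.raises(InvalidArgumentError):
            cross_validate(X, y, ClassifierSpec(**SMALL), k=1)

    def test_k_above_n_rejected(self, rng):
        X, y = _separable_data(rng, n=10)
        with pytest.raises(InvalidArgumentError):
            cross_validate(X, y, ClassifierSpec(**SMALL), k=11)

    def test_fold_accuracies_stable_on_separable_fixture(self, rng):
        X, y = _separable_data(rng, n=50)
        spec = ClassifierSpec(seed=8, **SMALL)
        folds = cross_validate(X, y, spec, k=5)
        assert len(folds) == 5
        holdout = train_reaction_classifier(X, y, spec).holdout_accuracy
        assert abs(np.mean(folds) - holdout) <= 0.1


class TestFilterClassifiers:
    @staticmethod
    def _rec(rid, acc):
        return ClassifierRecord(
            reaction_id=rid, spec=ClassifierSpec(), holdout_accuracy=acc
        )

    def test_threshold_edge_keeps_exactly_seventy_percent(self):
        recs = [
            self._rec("a", 0.69),
            self._rec("b", 0.70),
            self._rec("c", 0.95),
        ]
        kept = filter_classifiers(recs)
        assert [r.reaction_id for r in kept] == ["b", "c"]
        assert all(r.retained for r in kept)

    def test_empty_input_gives_empty_output(self):
        assert filter_classifiers([]) == []

    def test_zero_threshold_retains_all(self):
        recs = [self._rec("a", 0.0), self._rec("b", 0.3)]
        assert len(filter_classifiers(recs, min_accuracy=0)) == 2


class TestMakeFluxProfile:
    @pytest.fixture
    def trained_pair(self, rng):
        X, y = _separable_data(rng, n=40, dim=30)
        spec = ClassifierSpec(seed=9, **SMALL)
        return {
            "R_A": train_reaction_classifier(X, y, spec, "R_A"),
            "R_B": train_reaction_classifier(X, y, spec, "R_B"),
        }

    def test_profile_length_equals_retained_count(self, trained_pair):
        t = np.linspace(0, 1, 30)
        sim = SimulationRecord(
            "S1",
            "ko",
            {
                "R_A": FluxSeries(t, np.linspace(0, 1, 30)),
                "R_B": FluxSeries(t, np.linspace(1, 0, 30)),
            },
        )
        profile = make_flux_profile(sim, trained_pair)
        assert profile.bits.shape == (2,)
        assert profile.reaction_ids == ("R_A", "R_B")
        # increasing shape was class 0, decreasing class 1
        assert profile.bits.tolist() == [0, 1]

    def test_missing_series_rejected(self, trained_pair):
        sim = SimulationRecord(
            "S2",
            "ko",
            {"R_A": FluxSeries(np.arange(30.0), np.linspace(0, 1, 30))},
        )
        with pytest.raises(MissingSeriesError):
            make_flux_profile(sim, trained_pair)
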