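"""Phenotype classification, phi association, profile PCA, separability."""
import math

import numpy as np
import pytest

from wcflux.errors import (
    DegenerateFitWarning,
    DegenerateLabelError,
    UnclassifiedPhenotypeError,
    UndefinedStatisticError,
)
from wcflux.markers import (
    ContingencyTable2x2,
    classify_phenotype,
    contingency_from_labels,
    flags_for_class,
    marker_report,
    phi_coefficient,
    reduce_profiles,
    svm_separability,
)
from wcflux.network import DriverSet
from wcflux.types import PhenotypeClass, PhenotypeFlags


class TestPhiCoefficient:
    def test_perfect_association(self):
        assert phi_coefficient(ContingencyTable2x2(10, 0, 0, 10)) == 1.0

    def test_independence(self):
        assert phi_coefficient(ContingencyTable2x2(5, 5, 5, 5)) == 0.0

    def test_direct_formula_example(self):
        # ad - bc = 20*65 - 5*10 = 1250; denominator sqrt(3_937_500)
        phi = phi_coefficient(ContingencyTable2x2(20, 5, 10, 65))
        assert phi == pytest.approx(1250 / math.sqrt(3_937_500), rel=1e-12)

    def test_matches_pearson_correlation_of_binary_vectors(self, rng):
        for _ in range(100):
            x = rng.integers(0, 2, 40)
            y = rng.integers(0, 2, 40)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            # abnormal = (x == 0), so the table's "normal" rows count x == 1
            table = contingency_from_labels(x == 0, y == 1)
            a = int(((x == 1) & (y == 1)).sum())
            b = int(((x == 1) & (y == 0)).sum())
            c = int(((x == 0) & (y == 1)).sum())
            d = int(((x == 0) & (y == 0)).sum())
            assert (table.a, table.b, table.c, table.d) == (a, b, c, d)
            # phi is the Pearson correlation of the normal and in-class
            # indicators
            oracle = np.corrcoef(x, y)[0, 1]
            assert phi_coefficient(table) == pytest.approx(
                oracle, rel=1e-10, abs=1e-10
            )

    def test_swapping_both_labellings_preserves_phi(self):
        t = ContingencyTable2x2(20, 5, 10, 65)
        swapped = ContingencyTable2x2(65, 10, 5, 20)
        assert phi_coefficient(t) == pytest.approx(phi_coefficient(swapped))

    def test_swapping_one_labelling_flips_sign(self):
        t = ContingencyTable2x2(20, 5, 10, 65)
        rows_swapped = ContingencyTable2x2(10, 65, 20, 5)
        assert phi_coefficient(rows_swapped) == pytest.approx(
            -phi_coefficient(t)
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            phi_coefficient(ContingencyTable2x2(0, 0, 5, 5))


class TestClassifyPhenotype:
    TABLE = [
        ((0, 0, 0, 0, 0, 0), PhenotypeClass.METABOLIC),
        ((1, 0, 0, 0, 0, 0), PhenotypeClass.RNA),
        ((1, 1, 0, 0, 0, 0), PhenotypeClass.PROTEIN),
        ((0, 1, 1, 1, 0, 0), PhenotypeClass.DNA),
        ((1, 1, 1, 1, 0, 1), PhenotypeClass.SLOW_GROWING),
        ((1, 1, 1, 1, 0, 0), PhenotypeClass.SEPTUM),
        ((1, 1, 1, 1, 1, 1), PhenotypeClass.NON_ESSENTIAL),
    ]

    @pytest.mark.parametrize("flags,expected", TABLE)
    def test_printed_rows_classify_as_printed(self, flags, expected):
        f = PhenotypeFlags(*(bool(v) for v in flags))
        assert classify_phenotype(f) is expected

    def test_unlisted_combination_raises(self):
        with pytest.raises(UnclassifiedPhenotypeError):
            classify_phenotype(
                PhenotypeFlags(
                    dna=False,
                    rna=False,
                    protein=True,
                    growth=False,
                    division=False,
                )
            )

    @pytest.mark.parametrize("cls", list(PhenotypeClass))
    def test_flags_for_class_round_trips(self, cls):
        assert classify_phenotype(flags_for_class(cls)) is cls

    def test_completed_division_implies_initiated(self):
        f = PhenotypeFlags(True, True, True, True, True, False)
        assert f.division_initiated


class TestReduceProfiles:
    def test_identical_profiles_warn_and_return_zero_scores(self):
        P = np.ones((5, 4))
        with pytest.warns(DegenerateFitWarning):
            red = reduce_profiles(P)
        assert not red.scores.any()
        assert red.explained_variance_fraction == 0.0

    def test_two_opposite_clusters_separate_on_pc1(self):
        P = np.vstack([np.zeros((10, 6)), np.ones((10, 6))])
        red = reduce_profiles(P)
        assert red.explained_variance_fraction == pytest.approx(1.0)
        pc1 = red.scores[:, 0]
        assert (pc1[:10].max() < pc1[10:].min()) or (
            pc1[:10].min() > pc1[10:].max()
        )

    def test_scores_reproducible(self, rng):
        P = rng.integers(0, 2, size=(20, 8)).astype(float)
        a = reduce_profiles(P).scores
        b = reduce_profiles(P).scores
        assert np.array_equal(a, b)

    def test_single_simulation_rejected(self):
        with pytest.raises(Exception):
            reduce_profiles(np.ones((1, 4)))


class TestSvmSeparability:
    def test_wide_margin_clusters_pass(self, rng):
        scores = np.vstack(
            [
                rng.normal(0, 0.1, (30, 2)),
                rng.normal(5, 0.1, (30, 2)),
            ]
        )
        y = np.array([0] * 30 + [1] * 30)
        res = svm_separability(scores, y, "R_X")
        assert res.accuracy == pytest.approx(1.0) and res.passes

    def test_random_labels_on_single_blob_fail(self, rng):
        scores = rng.normal(0, 1, (500, 2))
        y = rng.integers(0, 2, 500)
        res = svm_separability(scores, y)
        assert res.accuracy < 0.95 and not res.passes

    def test_reported_accuracy_matches_hyperplane_reclassification(self, rng):
        scores = rng.normal(0, 1, (100, 2))
        y = (scores @ [1.0, 2.0] > 0.3).astype(int)
        res = svm_separability(scores, y)
        margin = scores @ res.weights + res.offset
        classes = np.unique(y)
        predicted = np.where(margin > 0, classes[1], classes[0])
        assert res.accuracy == pytest.approx((predicted == y).mean())

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateLabelError):
            svm_separability(rng.normal(size=(10, 2)), np.zeros(10))


class TestMarkerReport:
    def test_no_drivers_gives_empty_table(self):
        table = marker_report(DriverSet((), (), "maximum"), {}, {})
        assert len(table) == 0

    def test_one_row_per_driver(self):
        drivers = DriverSet(("R1", "R2", "TX_3"), (), "maximum")
        table = marker_report(drivers, {}, {})
        assert len(table) == 3
        assert list(table.reaction_id) == ["R1", "R2", "TX_3"]

    def test_best_class_maximises_absolute_phi(self):
        drivers = DriverSet(("R1",), (), "maximum")
        phis = {
            "R1": {
                PhenotypeClass.METABOLIC: -0.97,
                PhenotypeClass.RNA: 0.20,
            }
        }
        table = marker_report(drivers, {}, phis)
        assert table.best_class[0] == "metabolic"
        assert table.best_phi[0] == pytest.approx(-0.97)
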