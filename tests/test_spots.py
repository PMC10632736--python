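import numpy as np
import pandas as pd
import pytest

from neighborex.io import ExpressionMatrix, MarkerSet, log_normalize
from neighborex.spots import (
    classify_spots,
    doublet_weights,
    make_artificial_spots,
    validate_by_correlation,
    validate_by_markers,
)


def deconv_frame(rows):
    return pd.DataFrame(
        rows, columns=["spot_id", "first_type", "second_type", "first_prop", "spot_class"]
    )


class TestClassifySpots:
    def test_singlet_goes_homotypic(self):
        d = deconv_frame([("s1", "A", "", 1.0, "singlet")] * 1)
        cats = classify_spots(d, min_members=1)
        assert [c.label for c in cats] == ["A/A"]

    def test_reversed_doublets_share_category(self):
        d = deconv_frame(
            [("s1", "A", "B", 0.6, "doublet"), ("s2", "B", "A", 0.3, "doublet")]
        )
        cats = classify_spots(d, min_members=1)
        assert [c.label for c in cats] == ["A+B"]
        assert len(cats[0]) == 2

    def test_manual_tally(self):
        rows = (
            [(f"a{i}", "A", "", 1.0, "singlet") for i in range(5)]
            + [(f"b{i}", "B", "", 1.0, "singlet") for i in range(4)]
            + [(f"d{i}", "A", "B", 0.5, "doublet") for i in range(3)]
        )
        cats = {c.label: len(c) for c in classify_spots(deconv_frame(rows), min_members=1)}
        assert cats == {"A/A": 5, "B/B": 4, "A+B": 3}

    def test_weights_follow_canonical_order(self):
        d = deconv_frame(
            [("s1", "B", "A", 0.3, "doublet"), ("s2", "A", "B", 0.8, "doublet")]
        )
        w = doublet_weights(d)
        # weight is the proportion of the lexicographically first type (A)
        assert w == {"s1": pytest.approx(0.7), "s2": pytest.approx(0.8)}


class TestArtificialSpots:
    def test_midpoint_mix(self):
        a = np.array([[2.0, 0.0]])
        b = np.array([[0.0, 2.0]])
        s = make_artificial_spots("s", 0.5, ("A", "B"), a, b, n_reps=3, seed=0)
        assert np.allclose(s.replicates, [[1.0, 1.0]] * 3)

    def test_boundary_weight_returns_first_pool(self):
        a = np.array([[3.0, 1.0]])
        b = np.array([[9.0, 9.0]])
        s = make_artificial_spots("s", 1.0, ("A", "B"), a, b, n_reps=2, seed=0)
        assert np.allclose(s.replicates, [[3.0, 1.0]] * 2)

    def test_singleton_pools_match_formula(self, rng):
        a = rng.uniform(0, 5, size=(1, 7))
        b = rng.uniform(0, 5, size=(1, 7))
        w = 0.37
        s = make_artificial_spots("s", w, ("A", "B"), a, b, n_reps=100, seed=1)
        assert np.allclose(s.replicates, w * a + (1 - w) * b, atol=1e-12)

    def test_replicates_conserve_weighted_mix(self, rng):
        # every replicate must be exactly w*a + (1-w)*b for some pool rows
        a = rng.uniform(0, 5, size=(4, 6))
        b = rng.uniform(0, 5, size=(5, 6))
        w = 0.25
        s = make_artificial_spots("s", w, ("A", "B"), a, b, n_reps=50, seed=2)
        mixes = (w * a[:, None, :] + (1 - w) * b[None, :, :]).reshape(-1, 6)
        for rep in s.replicates:
            assert np.min(np.abs(mixes - rep).max(axis=1)) < 1e-12

    def test_reproducible_under_seed(self, rng):
        a, b = rng.uniform(size=(3, 4)), rng.uniform(size=(2, 4))
        s1 = make_artificial_spots("s", 0.4, ("A", "B"), a, b, seed=9)
        s2 = make_artificial_spots("s", 0.4, ("A", "B"), a, b, seed=9)
        assert np.array_equal(s1.replicates, s2.replicates)

    def test_empty_pool_names_missing_type(self):
        with pytest.raises(ValueError, match="second"):
            make_artificial_spots("s", 0.5, ("A", "B"), np.ones((1, 2)), np.ones((0, 2)))


class TestCorrelationValidation:
    def test_recovers_annotation_on_ngs_dataset(self, ngs_dataset):
        expr, deconv, _, _ = ngs_dataset
        cats = classify_spots(deconv)
        val = validate_by_correlation(expr, deconv, cats, n_reps=20, seed=3)
        w = deconv.set_index("spot_id")["first_prop"]
        minor = val["spot_id"].map(w).apply(lambda x: min(x, 1 - x))
        well_mixed = val[minor >= 0.2]
        assert well_mixed["valid"].mean() >= 0.9

    def test_mislabeled_pure_spot_flagged(self, ngs_dataset):
        expr, deconv, _, _ = ngs_dataset
        cats = classify_spots(deconv)
        # relabel a pure T4 singlet as an A+B doublet: argmax should disagree
        t4 = next(c for c in cats if c.label == "T4/T4").members[0]
        fake = deconv.copy()
        i = fake.index[fake["spot_id"] == t4][0]
        fake.loc[i, ["first_type", "second_type", "first_prop", "spot_class"]] = (
            "T1", "T2", 0.5, "doublet",
        )
        from neighborex.graph import NeighborCategory

        cats2 = [
            c
            if t4 not in c.members
            else NeighborCategory(
                c.center_type, c.partner_type, tuple(m for m in c.members if m != t4)
            )
            for c in cats
        ] + [NeighborCategory("T1", "T2", (t4,))]
        val = validate_by_correlation(expr, fake, cats2, n_reps=20, seed=3)
        row = val[val["spot_id"] == t4].iloc[0]
        assert not row["valid"]

    def test_constant_spot_flagged_with_reason(self):
        counts = np.array([[4, 4, 0, 5], [0, 5, 4, 4], [2, 2, 2, 3]])
        expr = log_normalize(
            ExpressionMatrix(["g1", "g2", "g3"], ["a1", "b1", "d1", "d2"], counts)
        )
        expr.normalized[:, 2] = 1.0  # constant expression vector
        d = deconv_frame(
            [
                ("a1", "A", "", 1.0, "singlet"),
                ("b1", "B", "", 1.0, "singlet"),
                ("d1", "A", "B", 0.5, "doublet"),
                ("d2", "A", "B", 0.5, "doublet"),
            ]
        )
        cats = classify_spots(d, min_members=1)
        val = validate_by_correlation(expr, d, cats, n_reps=5, seed=0)
        assert (val.set_index("spot_id").loc["d1", "reason"]) == "constant_expression"


class TestMarkerValidation:
    @pytest.fixture
    def marked_world(self):
        # gene0 marks A, gene1 marks B; d1 expresses both, d2 lacks B's marker
        counts = np.array(
            [
                [5, 0, 3, 4],
                [0, 5, 2, 0],
                [1, 1, 1, 1],
            ]
        )
        expr = log_normalize(
            ExpressionMatrix(["mA", "mB", "g"], ["a1", "b1", "d1", "d2"], counts)
        )
        d = deconv_frame(
            [
                ("a1", "A", "", 1.0, "singlet"),
                ("b1", "B", "", 1.0, "singlet"),
                ("d1", "A", "B", 0.5, "doublet"),
                ("d2", "A", "B", 0.5, "doublet"),
            ]
        )
        markers = [MarkerSet("A", ("mA",)), MarkerSet("B", ("mB",))]
        return expr, classify_spots(d, min_members=1), markers

    def test_spot_and_category_rules(self, marked_world):
        expr, cats, markers = marked_world
        out = validate_by_markers(expr, cats, markers, min_fraction=0.5)
        row = out.iloc[0]
        assert row["pair"] == "A+B"
        assert row["n_valid"] == 1  # d1 yes, d2 missing mB
        assert row["fraction_valid"] == pytest.approx(0.5)
        assert bool(row["passes"])

    def test_missing_marker_set_warns_and_skips(self, marked_world):
        expr, cats, markers = marked_world
        with pytest.warns(UserWarning, match="missing marker set"):
            out = validate_by_markers(expr, cats, markers[:1])
        assert out.empty
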