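"""VOC feature-table pipeline, presence calls and overlap counting."""

import numpy as np
import pandas as pd
import pytest

from thawflux import synthetic as syn
from thawflux import voc


def small_table(areas: dict, conditions: dict, roles: dict) -> voc.VOCFeatureTable:
    frame = pd.DataFrame(areas)
    frame.index = [f"F{i}" for i in range(len(frame))]
    frame.index.name = "feature_id"
    features = pd.DataFrame(
        {
            "mean_rt1": np.arange(len(frame), dtype=float),
            "mean_rt2": np.zeros(len(frame)),
            "compound": frame.index,
            "kegg_id": [None] * len(frame),
            "superclass": [None] * len(frame),
        },
        index=frame.index,
    )
    samples = pd.DataFrame(
        {"condition": conditions, "role": roles}
    )
    samples.index.name = "sample"
    return voc.VOCFeatureTable(frame, features, samples)


@pytest.fixture
def replicate_table():
    return small_table(
        areas={
            "s1": [10.0, 100.0], "s2": [20.0, 100.0], "s3": [30.0, 100.0],
            "ib": [40.0, 0.0], "mb": [20.0, 0.0],
            "c1": [0.0, 0.0],
        },
        conditions={"s1": "A", "s2": "A", "s3": "A", "ib": "blank",
                    "mb": "blank", "c1": "A"},
        roles={"s1": "live", "s2": "live", "s3": "live",
               "ib": "instrument_blank", "mb": "media_blank", "c1": "autoclaved"},
    )


class TestAverageReplicates:
    def test_triplicate_mean(self, replicate_table):
        means = voc.average_replicates(replicate_table)
        assert means.values.loc["F0", "A"] == pytest.approx(20.0)
        assert means.replicate_counts["A"] == 3

    def test_single_replicate_is_identity(self):
        table = small_table(
            {"s1": [5.0], "ib": [1.0]},
            {"s1": "A", "ib": "blank"},
            {"s1": "live", "ib": "instrument_blank"},
        )
        assert voc.average_replicates(table).values.loc["F0", "A"] == 5.0

    def test_matches_brute_force_group_means(self):
        rng = np.random.default_rng(0)
        n, reps = 12, 3
        conds = ["A", "B"]
        areas, cond_map, role_map = {}, {}, {}
        for c in conds:
            for r in range(reps):
                sid = f"{c}{r}"
                areas[sid] = rng.uniform(0, 100, n)
                cond_map[sid] = c
                role_map[sid] = "live"
        areas["ib"] = rng.uniform(0, 5, n)
        cond_map["ib"] = "blank"
        role_map["ib"] = "instrument_blank"
        table = small_table(areas, cond_map, role_map)
        means = voc.average_replicates(table)
        for c in conds:
            expected = np.mean([areas[f"{c}{r}"] for r in range(reps)], axis=0)
            assert np.allclose(means.values[c], expected)

    def test_unknown_role_rejected(self, replicate_table):
        with pytest.raises(ValueError):
            voc.average_replicates(replicate_table, role="no-such-role")


class TestSubtractBackground:
    def test_mean_of_blank_means(self, replicate_table):
        means = voc.average_replicates(replicate_table)
        corrected = voc.subtract_background(means)
        # instrument blank 40, media blank 20 → subtract 30 from live mean 20 → floored
        assert corrected.values.loc["F0", "A"] == 0.0
        assert corrected.values.loc["F1", "A"] == pytest.approx(100.0)

    def test_signal_minus_mean_blank(self):
        table = small_table(
            {"s1": [100.0], "ib": [40.0], "mb": [20.0]},
            {"s1": "A", "ib": "blank", "mb": "blank"},
            {"s1": "live", "ib": "instrument_blank", "mb": "media_blank"},
        )
        corrected = voc.subtract_background(voc.average_replicates(table))
        assert corrected.values.loc["F0", "A"] == pytest.approx(70.0)

    def test_zero_blanks_are_identity(self):
        table = small_table(
            {"s1": [33.0], "ib": [0.0], "mb": [0.0]},
            {"s1": "A", "ib": "blank", "mb": "blank"},
            {"s1": "live", "ib": "instrument_blank", "mb": "media_blank"},
        )
        corrected = voc.subtract_background(voc.average_replicates(table))
        assert corrected.values.loc["F0", "A"] == 33.0

    def test_missing_blank_role_rejected(self):
        table = small_table(
            {"s1": [1.0], "ib": [0.5]},
            {"s1": "A", "ib": "blank"},
            {"s1": "live", "ib": "instrument_blank"},
        )
        with pytest.raises(ValueError):
            voc.subtract_background(
                voc.average_replicates(table), blank_roles=("media_blank",)
            )


class TestSubtractControl:
    def _pair(self, live_vals, control_vals):
        table = small_table(
            {
                "s1": live_vals, "c1": control_vals,
                "ib": [0.0] * len(live_vals), "mb": [0.0] * len(live_vals),
            },
            {"s1": "A", "c1": "A", "ib": "blank", "mb": "blank"},
            {"s1": "live", "c1": "autoclaved",
             "ib": "instrument_blank", "mb": "media_blank"},
        )
        live = voc.subtract_background(voc.average_replicates(table, "live"))
        control = voc.subtract_background(voc.average_replicates(table, "autoclaved"))
        return live, control

    def test_zero_control_is_identity(self):
        live, control = self._pair([10.0, 20.0], [0.0, 0.0])
        out = voc.subtract_control(live, control)
        assert np.allclose(out.values["A"], [10.0, 20.0])

    def test_equal_live_and_control_zero_out(self):
        live, control = self._pair([10.0, 20.0], [10.0, 20.0])
        assert (voc.subtract_control(live, control).values["A"] == 0).all()

    def test_matches_floored_elementwise_difference(self):
        rng = np.random.default_rng(5)
        lv, cv = rng.uniform(0, 50, 8), rng.uniform(0, 50, 8)
        live, control = self._pair(list(lv), list(cv))
        out = voc.subtract_control(live, control)
        assert np.allclose(out.values["A"], np.maximum(lv - cv, 0.0))

    def test_control_subtraction_before_blank_subtraction_rejected(self):
        table = small_table(
            {"s1": [10.0], "c1": [5.0], "ib": [1.0]},
            {"s1": "A", "c1": "A", "ib": "blank"},
            {"s1": "live", "c1": "autoclaved", "ib": "instrument_blank"},
        )
        live = voc.average_replicates(table, "live")
        control = voc.subtract_background(
            voc.average_replicates(table, "autoclaved"), ("instrument_blank",)
        )
        with pytest.raises(voc.PipelineOrderError):
            voc.subtract_control(live, control)


class TestDropZeroRows:
    def _means(self, matrix):
        frame = pd.DataFrame(matrix, columns=["A", "B"])
        frame.index = [f"F{i}" for i in range(len(frame))]
        means = voc.ConditionMeans(
            frame, frame.copy(), pd.Series({"A": 1, "B": 1}),
            pd.DataFrame(index=frame.index),
            applied=("average", "subtract_background", "subtract_control"),
        )
        return means

    def test_no_zeros_is_identity(self):
        out = voc.drop_zero_rows(self._means([[1.0, 2.0], [3.0, 4.0]]))
        assert len(out.values) == 2

    def test_single_zero_cell_removes_whole_row(self):
        out = voc.drop_zero_rows(self._means([[1.0, 0.0], [3.0, 4.0]]))
        assert list(out.values.index) == ["F1"]
        assert out.removal_log == [("F0", ["B"])]

    def test_all_zero_table_empties(self):
        out = voc.drop_zero_rows(self._means([[0.0, 0.0], [0.0, 0.0]]))
        assert len(out.values) == 0


class TestBinFeaturesByMax:
    def test_single_condition_takes_everything(self):
        frame = pd.DataFrame({"A": [1.0, 2.0]}, index=["F0", "F1"])
        assignments, ties = voc.bin_features_by_max(frame)
        assert (assignments == "A").all() and not ties

    def test_argmax_assignment(self):
        frame = pd.DataFrame(
            {"A": [5.0], "B": [9.0], "C": [2.0]}, index=["F0"]
        )
        assignments, _ = voc.bin_features_by_max(frame)
        assert assignments["F0"] == "B"

    def test_matches_brute_force_argmax_and_conserves_features(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame(
            rng.uniform(0, 10, (20, 4)), columns=list("ABCD"),
            index=[f"F{i}" for i in range(20)],
        )
        assignments, _ = voc.bin_features_by_max(frame)
        assert len(assignments) == 20  # every feature in exactly one bin
        for fid in frame.index:
            assert assignments[fid] == frame.loc[fid].idxmax()

    def test_ties_go_to_first_condition_in_canonical_order_and_are_flagged(self):
        frame = pd.DataFrame({"A": [3.0], "B": [3.0]}, index=["F0"])
        assignments, ties = voc.bin_features_by_max(frame, tie_order=["B", "A"])
        assert assignments["F0"] == "B"
        assert ties == ["F0"]


class TestSuperclassCounts:
    def test_single_feature_single_count(self):
        counts = voc.superclass_counts(
            pd.Series({"F0": "A"}), {"F0": "Benzenoids"}
        )
        assert counts.loc["A", "Benzenoids"] == 1

    def test_missing_annotation_counted_as_unclassified(self):
        counts = voc.superclass_counts(pd.Series({"F0": "A"}), {})
        assert counts.loc["A", "unclassified"] == 1

    def test_matches_brute_force_cross_tabulation(self):
        rng = np.random.default_rng(2)
        features = [f"F{i}" for i in range(30)]
        assignments = pd.Series(rng.choice(["A", "B"], 30), index=features)
        classes = ["Benzenoids", "Hydrocarbons", "Lipids"]
        ann = {f: rng.choice(classes) for f in features}
        counts = voc.superclass_counts(assignments, ann)
        for cond in ("A", "B"):
            for cls in classes:
                expected = sum(
                    1 for f in features if assignments[f] == cond and ann[f] == cls
                )
                got = counts.loc[cond, cls] if cls in counts.columns else 0
                assert got == expected
        assert counts.sum(axis=1).to_dict() == assignments.value_counts().to_dict()


class TestPresenceAndOverlap:
    def test_packaged_table_reproduces_reported_overlap_counts(self):
        matrix = voc.load_shared_compound_table()
        count_37, _ = voc.overlap_count(
            matrix, voc.OverlapQuery(voc.BTL_200_CONDITIONS, ("MaC2A (37 °C)",))
        )
        count_2, _ = voc.overlap_count(
            matrix, voc.OverlapQuery(voc.BTL_200_CONDITIONS, ("MaC2A (2 °C)",))
        )
        count_m4, _ = voc.overlap_count(
            matrix,
            voc.OverlapQuery(("BTL 200 cm (-4 °C)",), voc.CULTURE_CONDITIONS),
        )
        assert (count_37, count_2, count_m4) == (13, 10, 6)

    def test_packaged_table_satisfies_its_defining_filter(self):
        """Every row is present in ≥1 soil and ≥1 culture condition."""
        matrix = voc.load_shared_compound_table()
        assert len(matrix.compounds) == 16
        soil = matrix.frame[list(voc.BTL_CONDITIONS)]
        culture = matrix.frame[list(voc.CULTURE_CONDITIONS)]
        assert soil.any(axis=1).all()
        assert culture.any(axis=1).all()

    def test_empty_matrix_counts_zero(self):
        matrix = voc.PresenceMatrix(
            pd.DataFrame(columns=["A", "B"], dtype=bool)
        )
        count, compounds = voc.overlap_count(
            matrix, voc.OverlapQuery(("A",), ("B",))
        )
        assert count == 0 and compounds == []

    def test_unknown_label_rejected(self):
        matrix = voc.load_shared_compound_table()
        with pytest.raises(KeyError):
            voc.overlap_count(
                matrix, voc.OverlapQuery(("no such condition",), ("MaC2A (2 °C)",))
            )

    def test_enlarging_any_set_is_monotone(self):
        matrix = voc.load_shared_compound_table()
        small, _ = voc.overlap_count(
            matrix,
            voc.OverlapQuery(("BTL 200 cm (5 °C)",), ("MaC2A (37 °C)",)),
        )
        union, _ = voc.overlap_count(
            matrix, voc.OverlapQuery(voc.BTL_200_CONDITIONS, ("MaC2A (37 °C)",))
        )
        assert union >= small

    def test_all_combinator_requires_every_condition(self):
        matrix = voc.load_shared_compound_table()
        count, compounds = voc.overlap_count(
            matrix,
            voc.OverlapQuery(
                voc.BTL_200_CONDITIONS, voc.CULTURE_CONDITIONS,
                combine_a="all", combine_b="all",
            ),
        )
        # only benzaldehyde and o-xylene are present in every column involved
        assert compounds == ["Benzaldehyde", "o-Xylene"]
        assert count == 2

    def test_presence_requires_background_corrected_table(self):
        table, _ = syn.gen_voc_table(syn.VOCGenSpec(seed=0))
        means = voc.average_replicates(table)
        with pytest.raises(voc.PipelineOrderError):
            voc.presence_matrix(means)


class TestPresenceMatrixIO:
    @pytest.mark.parametrize("dialect", ["+-", "01"])
    def test_round_trip(self, tmp_path, dialect):
        matrix = voc.load_shared_compound_table()
        path = tmp_path / "presence.tsv"
        matrix.to_csv(path, dialect=dialect)
        back = voc.PresenceMatrix.from_csv(path)
        pd.testing.assert_frame_equal(back.frame, matrix.frame)


def test_pipeline_round_trip_recovers_planted_truth_in_noiseless_limit():
    rng = np.random.default_rng(21)
    conds = ("A", "B", "C")
    planted = {c: tuple(rng.choice(20, size=6, replace=False)) for c in conds}
    spec = syn.VOCGenSpec(
        n_features=20, conditions=conds, planted_signatures=planted,
        blank_level=0.0, replicate_cv=0.0, seed=3,
    )
    table, truth = syn.gen_voc_table(spec)
    presence = voc.run_standard_pipeline(table)["presence"]
    pd.testing.assert_frame_equal(presence.frame, truth.frame)


def test_superclass_annotations_cover_packaged_compounds():
    ann = voc.load_shared_compound_annotations()
    matrix = voc.load_shared_compound_table()
    assert list(ann.index) == matrix.compounds
    assert ann["superclass"].notna().all()
    assert ann.loc["Benzaldehyde", "kegg_id"] == "C00261"
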