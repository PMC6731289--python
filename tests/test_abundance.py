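import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from biogasnet.abundance import (
    PrevalenceFilter,
    RelativeAbundanceNormalizer,
    ReplicatePresenceFilter,
    aggregate,
    filter_replicate_presence,
    normalize_relative,
    plant_means,
    read_abundance_table,
    write_abundance,
    write_annotation,
)
from conftest import make_frame


def _write_fixture(tmp_path, abundance_text, annotation_text):
    ab = tmp_path / "abundance.tsv"
    an = tmp_path / "annotation.tsv"
    ab.write_text(abundance_text)
    an.write_text(annotation_text)
    return ab, an


ANN3 = (
    "feature_id\tspecies_id\tspecies_name\tfamily\tko_ids\tec_ids\n"
    "PG1\tS0001\tBug one\tFam\tK00001;K00002\t1.1.1.1\n"
    "PG2\tS0001\tBug one\tFam\tK00001\t\n"
    "PG3\tS0002\tBug two\tFam2\t\t\n"
)


class TestIO:
    def test_round_trip_identity(self, tmp_path):
        ab, an = _write_fixture(
            tmp_path,
            "feature_id\tA:1\tA:2\nPG1\t1.5\t2\nPG2\t0\t3\nPG3\t4\t0.25\n",
            ANN3,
        )
        X, ann = read_abundance_table(ab, an)
        assert X.shape == (2, 3)
        assert X.loc[("A", 1), "PG1"] == 1.5
        assert X.loc[("A", 2), "PG3"] == 0.25
        assert ann.loc["PG1", "ko_ids"] == frozenset({"K00001", "K00002"})
        # round trip through the writers
        out = tmp_path / "out.tsv"
        write_abundance(X, out)
        write_annotation(ann, tmp_path / "ann_out.tsv")
        X2, _ = read_abundance_table(out, tmp_path / "ann_out.tsv")
        pd.testing.assert_frame_equal(X, X2)

    def test_negative_value_rejected(self, tmp_path):
        ab, an = _write_fixture(
            tmp_path,
            "feature_id\tA:1\tA:2\nPG1\t1\t-2\nPG2\t0\t3\nPG3\t4\t1\n",
            ANN3,
        )
        with pytest.raises(ValueError, match="negative"):
            read_abundance_table(ab, an)

    def test_duplicate_feature_rejected(self, tmp_path):
        ab, an = _write_fixture(
            tmp_path,
            "feature_id\tA:1\nPG1\t1\nPG1\t2\n",
            ANN3,
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_abundance_table(ab, an)

    def test_unannotated_feature_kept_with_warning(self, tmp_path, caplog):
        ab, an = _write_fixture(
            tmp_path,
            "feature_id\tA:1\nPG1\t1\nPG2\t2\nPG3\t3\nPG9\t4\n",
            ANN3,
        )
        with caplog.at_level("WARNING"):
            X, ann = read_abundance_table(ab, an)
        assert "PG9" in X.columns
        assert ann.loc["PG9", "species_id"] == ""
        assert ann.loc["PG9", "ko_ids"] == frozenset()
        assert any("lack annotation" in r.message for r in caplog.records)


class TestReplicatePresence:
    def _two_plant_frame(self, feat_a, feat_b):
        vals = np.column_stack([feat_a, feat_b])
        return make_frame(vals, plants=["A"] * 5 + ["B"] * 5, features=["fa", "fb"])

    def test_three_of_five_kept_globally(self):
        X = self._two_plant_frame(
            [1, 2, 3, 0, 0, 0, 0, 0, 0, 0],  # 3/5 in plant A only
            [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        )
        out = filter_replicate_presence(X, min_present=3)
        assert list(out.columns) == ["fa", "fb"]

    def test_two_of_five_everywhere_removed(self):
        X = self._two_plant_frame(
            [1, 2, 0, 0, 0, 3, 4, 0, 0, 0],  # 2/5 in both plants
            [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        )
        out = filter_replicate_presence(X, min_present=3)
        assert list(out.columns) == ["fb"]

    def test_all_zero_removed(self):
        X = self._two_plant_frame([0] * 10, [1] * 10)
        assert list(filter_replicate_presence(X).columns) == ["fb"]

    def test_per_plant_mode_masks_failing_plant(self):
        X = self._two_plant_frame(
            [1, 2, 3, 0, 0, 5, 0, 0, 0, 0],
            [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        )
        out = filter_replicate_presence(X, min_present=3, per_plant=True)
        assert out.loc["A", "fa"].sum() > 0
        assert out.loc["B", "fa"].sum() == 0

    @given(st.integers(min_value=1, max_value=5))
    def test_raising_threshold_is_monotone(self, min_present):
        rng = np.random.default_rng(0)
        X = make_frame(rng.integers(0, 2, (10, 6)) * rng.random((10, 6)),
                       plants=["A"] * 5 + ["B"] * 5)
        lo = set(filter_replicate_presence(X, min_present).columns)
        hi = set(filter_replicate_presence(X, min(min_present + 1, 5)).columns)
        assert hi <= lo


class TestNormalize:
    def test_proportions(self):
        X = make_frame([[1, 1, 2]])
        out = normalize_relative(X)
        assert np.allclose(out.to_numpy(), [[25, 25, 50]])

    def test_zero_column_error(self):
        X = make_frame([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="zero total"):
            normalize_relative(X)

    @given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=2, max_size=8))
    def test_idempotent(self, row):
        X = make_frame([row])
        once = normalize_relative(X)
        twice = normalize_relative(once)
        pd.testing.assert_frame_equal(once, twice)
        assert np.allclose(once.sum(axis=1), 100.0, atol=1e-9)


class TestAggregate:
    def _ann(self):
        return pd.DataFrame(
            {
                "species_id": ["S0001", "S0001", "S0002"],
                "species_name": ["one", "one", "two"],
                "family": ["F1", "F1", ""],
                "ko_ids": [frozenset({"K00001", "K00002"}), frozenset({"K00001"}),
                           frozenset()],
                "ec_ids": [frozenset()] * 3,
            },
            index=pd.Index(["PG1", "PG2", "PG3"], name="feature_id"),
        )

    def test_species_additivity(self):
        X = make_frame([[2, 3, 7]], features=["PG1", "PG2", "PG3"])
        out = aggregate(X, self._ann(), "species")
        assert out.loc[("P1", 1), "S0001"] == 5
        assert out.loc[("P1", 1), "S0002"] == 7

    def test_multi_ko_full_contribution(self):
        X = make_frame([[4, 0, 0]], features=["PG1", "PG2", "PG3"])
        out = aggregate(X, self._ann(), "ko")
        assert out.loc[("P1", 1), "K00001"] == 4
        assert out.loc[("P1", 1), "K00002"] == 4

    def test_multi_ko_split_mode(self):
        X = make_frame([[4, 0, 0]], features=["PG1", "PG2", "PG3"])
        out = aggregate(X, self._ann(), "ko", multi_ko="split")
        assert out.loc[("P1", 1), "K00001"] == 2
        assert out.loc[("P1", 1), "K00002"] == 2

    def test_species_level_conserves_totals(self, rng):
        X = make_frame(rng.random((3, 3)), plants=["A", "A", "B"],
                       features=["PG1", "PG2", "PG3"])
        for level in ("species", "family"):
            out = aggregate(X, self._ann(), level)
            assert np.allclose(out.sum(axis=1), X.sum(axis=1))

    def test_unassigned_row_collects_unkeyed(self):
        X = make_frame([[1, 2, 3]], features=["PG1", "PG2", "PG3"])
        out = aggregate(X, self._ann(), "ko")
        assert out.loc[("P1", 1), "unassigned"] == 3
        fam = aggregate(X, self._ann(), "family")
        assert fam.loc[("P1", 1), "unassigned"] == 3


class TestPlantMeans:
    def test_mean_then_renormalize(self):
        X = make_frame([[10, 30], [20, 40]], plants=["A", "A"])
        raw = plant_means(X, renormalize=False)
        assert np.allclose(raw.loc["A"], [15, 35])
        norm = plant_means(X, renormalize=True)
        assert np.allclose(norm.loc["A"], [30, 70])

    def test_single_replicate_unchanged(self):
        X = make_frame([[40, 60]], plants=["A"])
        out = plant_means(X)
        assert np.allclose(out.loc["A"], [40, 60])

    def test_identical_replicates_idempotent(self):
        X = make_frame([[40, 60], [40, 60], [40, 60]], plants=["A"] * 3)
        assert np.allclose(plant_means(X).loc["A"], [40, 60])


class TestTransformers:
    def test_replicate_presence_transformer(self):
        X = make_frame(
            [[1, 1], [2, 1], [3, 1], [0, 1], [0, 1]], plants=["A"] * 5,
            features=["fa", "fb"],
        )
        t = ReplicatePresenceFilter(min_present=4).fit(X)
        assert list(t.kept_features_) == ["fb"]
        assert list(t.transform(X).columns) == ["fb"]
        assert t.get_params()["min_present"] == 4

    def test_normalizer_pipeline_compatible(self):
        from sklearn.pipeline import Pipeline

        X = make_frame([[1, 1, 2], [2, 2, 4]], plants=["A", "A"])
        pipe = Pipeline([
            ("presence", ReplicatePresenceFilter(min_present=1)),
            ("normalize", RelativeAbundanceNormalizer()),
        ])
        out = pipe.fit_transform(X)
        assert np.allclose(out.sum(axis=1), 100.0)

    @pytest.mark.parametrize(
        "n_samples,n_present,kept",
        [(40, 24, True), (15, 9, True), (15, 8, False)],
    )
    def test_prevalence_threshold(self, n_samples, n_present, kept):
        col = np.zeros(n_samples)
        col[:n_present] = 1.0
        X = make_frame(np.column_stack([col, np.ones(n_samples)]),
                       features=["fa", "fb"])
        t = PrevalenceFilter(min_fraction=0.6).fit(X)
        assert ("fa" in t.kept_features_) is kept
        assert "fb" in t.kept_features_
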