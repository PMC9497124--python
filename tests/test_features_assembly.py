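import numpy as np
import pandas as pd
import pytest

from cogniscreen.features_assembly import (
    FeatureTable,
    VIEWS,
    assemble,
    clean_ntb,
    fit_apply_normalization,
    group_statistics,
)


@pytest.fixture
def demo_frame(rng):
    n = 20
    groups = ["NC"] * 10 + ["MCI"] * 10
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:02d}" for i in range(n)],
            "group": groups,
            "age": rng.normal(71, 4, n),
            "gender": rng.choice(["male", "female"], n),
            "education_years": rng.integers(3, 16, n),
            "moca_b": rng.normal(26, 2, n),
            "ace_r": rng.normal(70, 8, n),
        }
    )


class TestCleanNTB:
    RANGES = {"moca": (0.0, 30.0), "sub1": (0.0, 10.0)}

    def test_out_of_range_cell_set_missing(self):
        df = pd.DataFrame({"subject_id": ["a", "b"], "moca": [35.0, 20.0], "sub1": [5.0, 5.0]})
        out, logbook = clean_ntb(df, self.RANGES)
        assert np.isnan(out.loc[0, "moca"])
        assert out.loc[1, "moca"] == 20.0
        assert any("moca=35" in line for line in logbook)

    def test_all_valid_unchanged(self):
        df = pd.DataFrame({"subject_id": ["a"], "moca": [25.0], "sub1": [3.0]})
        out, logbook = clean_ntb(df, self.RANGES)
        pd.testing.assert_frame_equal(out, df)
        assert logbook == []

    def test_mostly_missing_subject_dropped(self):
        ranges = {f"s{i}": (0.0, 10.0) for i in range(20)}
        row_ok = {f"s{i}": 5.0 for i in range(20)}
        row_bad = {f"s{i}": (np.nan if i < 11 else 5.0) for i in range(20)}
        df = pd.DataFrame([{"subject_id": "ok", **row_ok}, {"subject_id": "bad", **row_bad}])
        out, logbook = clean_ntb(df, ranges)
        assert list(out["subject_id"]) == ["ok"]
        assert any("dropped" in line for line in logbook)

    def test_no_ranges_rejected(self):
        with pytest.raises(ValueError):
            clean_ntb(pd.DataFrame({"a": [1]}), {})


class TestNormalization:
    def test_minmax_then_z(self):
        train = pd.DataFrame({"s": [10.0, 30.0, 20.0]})
        tr, _, params = fit_apply_normalization(train, minmax_cols=["s"])
        assert params.minmax["s"] == (10.0, 30.0)
        # value 20 -> 0.5 before the z-step
        mid = (0.5 - params.mean["s"]) / params.sd["s"]
        assert tr["s"].iloc[2] == pytest.approx(mid)

    def test_train_columns_standardized(self, rng):
        train = pd.DataFrame(rng.normal(5, 3, size=(50, 4)), columns=list("abcd"))
        tr, _, _ = fit_apply_normalization(train)
        assert np.allclose(tr.mean(), 0.0, atol=1e-9)
        assert np.allclose(tr.std(ddof=0), 1.0, atol=1e-9)

    def test_heldout_transformed_with_training_params_only(self, rng):
        train = pd.DataFrame({"a": rng.normal(0, 1, 40)})
        test = pd.DataFrame({"a": rng.normal(3, 1, 40)})  # shifted population
        _, te, _ = fit_apply_normalization(train, test)
        assert abs(te["a"].mean()) > 1.0  # no leakage: test mean is not re-centered

    def test_constant_column_dropped_with_warning(self, rng):
        train = pd.DataFrame({"a": rng.normal(0, 1, 10), "c": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            tr, _, params = fit_apply_normalization(train)
        assert "c" not in tr.columns and params.dropped == ["c"]

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            fit_apply_normalization(pd.DataFrame())

    def test_params_invariant_to_test_rows(self, rng):
        train = pd.DataFrame({"a": rng.normal(0, 1, 30)})
        test1 = pd.DataFrame({"a": rng.normal(0, 1, 10)})
        test2 = test1 * 100.0
        _, _, p1 = fit_apply_normalization(train, test1)
        _, _, p2 = fit_apply_normalization(train, test2)
        assert p1.mean == p2.mean and p1.sd == p2.sd and p1.medians == p2.medians


class TestAssemble:
    def _tables(self, demo_frame, rng):
        sids = demo_frame["subject_id"]
        ntb = pd.DataFrame({"subject_id": sids, "sub1": rng.normal(5, 1, len(sids))})
        eeg = pd.DataFrame({"subject_id": sids, "apen": rng.normal(1, 0.1, len(sids))})
        et = pd.DataFrame({"subject_id": sids, "fix": rng.normal(0.3, 0.05, len(sids))})
        return ntb, eeg, et

    def test_views_select_expected_modalities(self, demo_frame, rng):
        ntb, eeg, et = self._tables(demo_frame, rng)
        table = assemble(demo_frame, ntb, eeg, et, view="all")
        physio = table.view("physio_only")
        assert all(c.startswith(("eeg.", "et.")) for c in physio.data.columns)
        assert set(physio.data.columns) == {"eeg.apen", "et.fix"}
        clinical = table.view("clinical")
        assert set(clinical.data.columns) == {
            "clinical.age",
            "clinical.gender_male",
            "clinical.education_years",
            "clinical.moca_b",
            "clinical.ace_r",
        }

    def test_views_are_nested_in_all(self, demo_frame, rng):
        table = assemble(demo_frame, *self._tables(demo_frame, rng), view="all")
        all_cols = set(table.data.columns)
        for name in ("clinical", "ntb_only", "physio_only"):
            assert set(table.view(name).data.columns) <= all_cols
        blocks = sum(len(table.view(v).data.columns) for v in ("clinical", "ntb_only", "physio_only"))
        assert len(all_cols) == blocks

    def test_subject_missing_one_modality_excluded(self, demo_frame, rng):
        ntb, eeg, et = self._tables(demo_frame, rng)
        et = et.iloc[1:]  # first subject has no ET data
        table = assemble(demo_frame, ntb, eeg, et, view="all")
        assert "S00" not in table.data.index
        assert len(table) == len(demo_frame) - 1

    def test_labels_follow_group(self, demo_frame, rng):
        table = assemble(demo_frame, *self._tables(demo_frame, rng))
        assert (table.labels[demo_frame.set_index("subject_id")["group"] == "MCI"] == 1).all()
        assert (table.labels[demo_frame.set_index("subject_id")["group"] == "NC"] == -1).all()

    def test_duplicate_subject_rejected(self, demo_frame, rng):
        dup = pd.concat([demo_frame, demo_frame.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            assemble(dup, *self._tables(demo_frame, rng))

    def test_empty_join_rejected(self, demo_frame, rng):
        ntb, eeg, et = self._tables(demo_frame, rng)
        ntb["subject_id"] = "X" + ntb["subject_id"]
        with pytest.raises(ValueError, match="empty join"):
            assemble(demo_frame, ntb, eeg, et)


class TestGroupStatistics:
    def test_identical_groups_give_zero_t(self, demo_frame):
        df = demo_frame.copy()
        df.loc[df["group"] == "MCI", ["age", "moca_b", "ace_r"]] = (
            df.loc[df["group"] == "NC", ["age", "moca_b", "ace_r"]].to_numpy()
        )
        report = group_statistics(df)
        assert report["age"]["stat"] == pytest.approx(0.0, abs=1e-12)

    def test_chi_square_matches_direct_formula(self):
        # contingency [[30, 18], [28, 16]] by direct computation
        rows = []
        for group, male, female in (("NC", 30, 18), ("MCI", 28, 16)):
            rows += [{"group": group, "gender": "male"} for _ in range(male)]
            rows += [{"group": group, "gender": "female"} for _ in range(female)]
        df = pd.DataFrame(rows)
        df["age"] = 70.0 + np.arange(len(df)) * 0.01
        df["moca_b"] = 25.0 + np.arange(len(df)) * 0.01
        df["ace_r"] = 70.0 + np.arange(len(df)) * 0.01
        df["education_years"] = 9
        obs = np.array([[30.0, 18.0], [28.0, 16.0]])
        expected = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        chi2_hand = ((obs - expected) ** 2 / expected).sum()
        report = group_statistics(df)
        assert report["gender"]["stat"] == pytest.approx(chi2_hand, abs=1e-12)

    def test_wilcoxon_null_on_identical_samples(self, demo_frame):
        df = demo_frame.copy()
        df["education_years"] = 9
        report = group_statistics(df)
        assert report["education_years"]["stat"] == pytest.approx(0.0, abs=1e-12)

    def test_single_subject_group_rejected(self, demo_frame):
        df = demo_frame[demo_frame["subject_id"] != "S00"].copy()
        df = df[(df["group"] == "NC") | (df["subject_id"] == "S10")]
        with pytest.raises(ValueError):
            group_statistics(df)


def test_feature_table_requires_modality_tags(rng):
    df = pd.DataFrame({"untagged": rng.normal(0, 1, 4)}, index=list("abcd"))
    labels = pd.Series([1, -1, 1, -1], index=df.index)
    with pytest.raises(ValueError, match="modality"):
        FeatureTable(data=df, labels=labels)
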