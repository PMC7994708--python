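import numpy as np
import pandas as pd
import pytest

import symptomnet as sn
from symptomnet.panel import PanelSchemaError, PanelValidationError


def tiny_panel():
    rng = np.random.default_rng(3)
    scores = rng.integers(0, 5, size=(5, 3, 11)).astype(float)
    return sn.SymptomPanel(scores, [f"s{i}" for i in range(5)])


class TestReadWrite:
    @pytest.mark.parametrize("dialect", ["long", "wide"])
    def test_round_trip_identity(self, tmp_path, dialect):
        panel = tiny_panel()
        path = tmp_path / f"panel_{dialect}.csv"
        sn.write_panel(panel, path, dialect)
        back = sn.read_panel(path, dialect)
        np.testing.assert_array_equal(back.scores, panel.scores)
        assert back.subject_ids == panel.subject_ids
        assert back.wave_labels == panel.wave_labels
        assert back.symptom_names == panel.symptom_names

    def test_long_and_wide_give_same_panel(self, tmp_path):
        panel = tiny_panel()
        sn.write_panel(panel, tmp_path / "l.csv", "long")
        sn.write_panel(panel, tmp_path / "w.csv", "wide")
        pl = sn.read_panel(tmp_path / "l.csv", "long")
        pw = sn.read_panel(tmp_path / "w.csv", "wide")
        np.testing.assert_array_equal(pl.scores, pw.scores)
        assert pl.symptom_names == pw.symptom_names

    def test_shape_bookkeeping(self, tmp_path):
        rows = []
        for s in ("a", "b"):
            for w in ("t0", "t1", "t2"):
                rows.append({"subject": s, "wave": w,
                             **{sym: 1 for sym in sn.DEFAULT_SYMPTOMS}})
        pd.DataFrame(rows).to_csv(tmp_path / "p.csv", index=False)
        panel = sn.read_panel(tmp_path / "p.csv", "long")
        assert panel.scores.shape == (2, 3, 11)

    def test_out_of_range_score_names_the_cell(self):
        scores = np.ones((2, 3, 11))
        scores[1, 2, 4] = 7
        with pytest.raises(PanelValidationError, match=r"s1.*t2.*Irritable.*7"):
            sn.SymptomPanel(scores, ["s0", "s1"])

    def test_non_integer_score_rejected(self):
        scores = np.ones((2, 3, 11))
        scores[0, 0, 0] = 1.5
        with pytest.raises(PanelValidationError):
            sn.SymptomPanel(scores, ["s0", "s1"])

    def test_missing_columns_schema_error(self, tmp_path):
        pd.DataFrame({"subject": ["a"], "Mood": [1]}).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(PanelSchemaError):
            sn.read_panel(tmp_path / "bad.csv", "long")

    def test_duplicate_subject_wave_rejected(self, tmp_path):
        rows = [{"subject": "a", "wave": "t0", **{s: 1 for s in sn.DEFAULT_SYMPTOMS}}] * 2
        pd.DataFrame(rows).to_csv(tmp_path / "dup.csv", index=False)
        with pytest.raises(PanelValidationError):
            sn.read_panel(tmp_path / "dup.csv", "long")


class TestSummarize:
    def test_constant_column(self):
        scores = np.tile(np.arange(11.0) % 4, (4, 3, 1))
        scores[:, :, 0] = 3.0
        panel = sn.SymptomPanel(scores, list("abcd"))
        table = sn.summarize(panel, "t0")
        assert table.loc["Mood", "mean"] == 3
        assert table.loc["Mood", "sd"] == 0
        assert table.loc["Mood", "min"] == table.loc["Mood", "max"] == 3

    def test_two_point_sd_uses_n_minus_one(self):
        scores = np.ones((2, 3, 11))
        scores[0, 0, 0], scores[1, 0, 0] = 0, 4
        panel = sn.SymptomPanel(scores, ["a", "b"])
        table = sn.summarize(panel, "t0")
        assert table.loc["Mood", "mean"] == 2
        assert table.loc["Mood", "sd"] == pytest.approx(2.8284271, abs=1e-6)
        assert table.loc["Mood", "min"] == 0 and table.loc["Mood", "max"] == 4

    def test_schema_one_row_per_symptom(self, study_panel):
        table = sn.summarize(study_panel, "t1")
        assert list(table.index) == list(study_panel.symptom_names)
        assert list(table.columns) == ["mean", "sd", "min", "max"]

    def test_invariant_to_subject_order(self, study_panel):
        perm = np.random.default_rng(0).permutation(study_panel.n_subjects)
        shuffled = sn.SymptomPanel(study_panel.scores[perm],
                                   [study_panel.subject_ids[i] for i in perm],
                                   study_panel.wave_labels, study_panel.symptom_names)
        pd.testing.assert_frame_equal(sn.summarize(study_panel, "t0"),
                                      sn.summarize(shuffled, "t0"))

    def test_unknown_wave_raises(self, study_panel):
        with pytest.raises(KeyError):
            sn.summarize(study_panel, "t9")


class TestWaveMatrix:
    def test_complete_panel_keeps_all_rows(self, study_panel):
        X = sn.wave_matrix(study_panel, "t0")
        assert X.n == study_panel.n_subjects
        assert X.p == 11

    def test_listwise_drops_incomplete_subject(self, study_panel):
        scores = study_panel.scores.copy()
        scores[3, 1, 5] = np.nan
        panel = sn.SymptomPanel(scores, study_panel.subject_ids,
                                study_panel.wave_labels, study_panel.symptom_names)
        assert sn.wave_matrix(panel, "t1").n == study_panel.n_subjects - 1
        assert sn.wave_matrix(panel, "t0").n == study_panel.n_subjects

    def test_too_few_complete_subjects_raises(self):
        scores = np.full((5, 3, 11), np.nan)
        panel = sn.SymptomPanel(scores, [f"s{i}" for i in range(5)])
        with pytest.raises(ValueError):
            sn.wave_matrix(panel, "t0")

    def test_rows_sorted_by_subject_id(self, study_panel):
        X = sn.wave_matrix(study_panel, "t0")
        assert X.subject_ids == sorted(X.subject_ids, key=str)
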