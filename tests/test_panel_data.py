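import pandas as pd
import pytest

from phylotaste.errors import (
    IntegrityError,
    MappingError,
    RangeError,
    SchemaError,
    VocabularyError,
)
from phylotaste.panel_data import (
    QualityVocabulary,
    load_drug_table,
    load_trials,
    load_use_matrix,
    validate_dataset,
    write_drug_table,
    write_trials,
    write_use_matrix,
)
from phylotaste.metrics import trial_metrics


def test_vocabulary_is_22_unique_labels():
    v = QualityVocabulary()
    assert len(v) == 22
    with pytest.raises(VocabularyError):
        QualityVocabulary(qualities=("bitter",) * 22)
    with pytest.raises(VocabularyError):
        QualityVocabulary(qualities=tuple(f"q{i}" for i in range(21)))


class TestDrugTable:
    def test_genus_parsed_from_binomial(self, tmp_path):
        p = tmp_path / "drugs.csv"
        p.write_text(
            "drug_id,taxon_name,plant_part\nd001, Cinnamomum verum, bark\n"
        )
        df = load_drug_table(p)
        assert df.loc[0, "genus"] == "Cinnamomum"
        assert df.loc[0, "plant_part"] == "bark"

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "drugs.csv"
        p.write_text("drug_id,taxon_name\nd1,Genus sp\n")
        with pytest.raises(SchemaError, match="plant_part"):
            load_drug_table(p)

    def test_duplicate_drug_id_rejected(self, tmp_path):
        p = tmp_path / "drugs.csv"
        p.write_text(
            "drug_id,taxon_name,plant_part\nd1,Genus a,root\nd1,Genus b,bark\n"
        )
        with pytest.raises(IntegrityError):
            load_drug_table(p)


class TestTrials:
    def test_wide_blanks_fill_as_zero(self, tmp_path, vocab):
        p = tmp_path / "trials.csv"
        p.write_text(
            "trial_id,drug_id,panellist_id,days_since_collection,bitter,sweet\n"
            "t1,d1,p1,3,2,1\n"
        )
        df = load_trials(p, vocab)
        assert df.loc[0, "bitter"] == 2 and df.loc[0, "sweet"] == 1
        assert df[list(vocab.qualities)].iloc[0].sum() == 3  # 20 zeros

    def test_long_layout(self, tmp_path, vocab):
        p = tmp_path / "trials.csv"
        p.write_text(
            "trial_id,drug_id,panellist_id,quality,score\n"
            "t1,d1,p1,bitter,2\nt1,d1,p1,sour,3\n"
        )
        df = load_trials(p, vocab, layout="long")
        assert df.loc[0, "bitter"] == 2 and df.loc[0, "sour"] == 3

    def test_score_out_of_range(self, tmp_path, vocab):
        p = tmp_path / "trials.csv"
        p.write_text("trial_id,drug_id,panellist_id,bitter\nt1,d1,p1,4\n")
        with pytest.raises(RangeError):
            load_trials(p, vocab)

    def test_unknown_quality_label(self, tmp_path, vocab):
        p = tmp_path / "trials.csv"
        p.write_text("trial_id,drug_id,panellist_id,minty\nt1,d1,p1,1\n")
        with pytest.raises(VocabularyError):
            load_trials(p, vocab)


class TestUseMatrix:
    def test_all_zero_matrix_is_valid(self, tmp_path):
        (tmp_path / "m.csv").write_text("drug_id,u1,u2\nd1,0,0\nd2,0,0\n")
        (tmp_path / "c.csv").write_text("use_id,category_id\nu1,a\nu2,a\n")
        um = load_use_matrix(tmp_path / "m.csv", tmp_path / "c.csv")
        assert um.indicators.sum().sum() == 0

    def test_non_binary_cell(self, tmp_path):
        (tmp_path / "m.csv").write_text("drug_id,u1\nd1,2\n")
        (tmp_path / "c.csv").write_text("use_id,category_id\nu1,a\n")
        with pytest.raises(RangeError):
            load_use_matrix(tmp_path / "m.csv", tmp_path / "c.csv")

    def test_use_without_category(self, tmp_path):
        (tmp_path / "m.csv").write_text("drug_id,u1,u2\nd1,1,0\n")
        (tmp_path / "c.csv").write_text("use_id,category_id\nu1,a\n")
        with pytest.raises(MappingError, match="u2"):
            load_use_matrix(tmp_path / "m.csv", tmp_path / "c.csv")


class TestValidation:
    def test_counts_and_cross_references(self, tiny_dataset):
        report = validate_dataset(
            tiny_dataset.drugs, tiny_dataset.trials, tiny_dataset.uses
        )
        assert report.ok
        assert report.counts["trials"] == 3
        assert report.counts["drugs"] == 2
        assert report.counts["panellists"] == 2
        # perception reports = non-zero (trial, quality) scores
        assert report.counts["perception_reports"] == 3

    def test_perception_reports_equal_total_complexity(self, small_sim):
        ds = small_sim[0]
        report = validate_dataset(ds.drugs, ds.trials, ds.uses, ds.vocab)
        tm = trial_metrics(ds.trials, ds.vocab)
        assert report.counts["perception_reports"] == tm["complexity"].sum()

    def test_unknown_drug_reference_is_error(self, tiny_dataset):
        trials = tiny_dataset.trials.copy()
        trials.loc[0, "drug_id"] = "ghost"
        report = validate_dataset(tiny_dataset.drugs, trials, tiny_dataset.uses)
        assert not report.ok
        assert any("ghost" in msg for _, msg, _ in report.errors)

    def test_empty_trials_warns(self, tiny_dataset):
        empty = tiny_dataset.trials.iloc[0:0]
        report = validate_dataset(tiny_dataset.drugs, empty, tiny_dataset.uses)
        assert report.ok  # warnings only
        assert report.counts["trials"] == 0


def test_round_trip_preserves_tables(tmp_path, tiny_dataset, vocab):
    write_drug_table(tiny_dataset.drugs, tmp_path / "drugs.csv")
    write_trials(tiny_dataset.trials, tmp_path / "trials.csv")
    write_use_matrix(tiny_dataset.uses, tmp_path / "m.csv", tmp_path / "c.csv")
    drugs = load_drug_table(tmp_path / "drugs.csv")
    trials = load_trials(tmp_path / "trials.csv", vocab)
    uses = load_use_matrix(tmp_path / "m.csv", tmp_path / "c.csv")
    pd.testing.assert_frame_equal(drugs, tiny_dataset.drugs)
    pd.testing.assert_frame_equal(trials, tiny_dataset.trials)
    pd.testing.assert_frame_equal(uses.indicators, tiny_dataset.uses.indicators)
    assert uses.category_map == tiny_dataset.uses.category_map
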