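import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylotaste.metrics import (
    descriptive_summary,
    drug_versatility,
    format_pct,
    pooled_drug_qualities,
    render_report,
    trial_complexity,
    trial_intensity,
    trial_metrics,
)
from phylotaste.errors import IntegrityError
from phylotaste.panel_data import UseMatrix
from conftest import make_trials

score_vectors = st.lists(
    st.integers(min_value=0, max_value=3), min_size=22, max_size=22
)


@pytest.mark.parametrize(
    "scores,intensity,complexity",
    [
        ({"bitter": 2, "sweet": 1}, 3, 2),
        ({}, 0, 0),
        ({q: 3 for q in ("bitter",)}, 3, 1),
    ],
)
def test_intensity_and_complexity_examples(vocab, scores, intensity, complexity):
    vec = [scores.get(q, 0) for q in vocab.qualities]
    assert trial_intensity(vec) == intensity
    assert trial_complexity(vec) == complexity


def test_maximum_intensity_is_66():
    assert trial_intensity([3] * 22) == 66
    assert trial_complexity([3] * 22) == 22


@settings(derandomize=True, max_examples=50)
@given(score_vectors)
def test_intensity_complexity_inequalities(vec):
    i, c = trial_intensity(vec), trial_complexity(vec)
    assert c <= i <= 3 * c or (i == 0 and c == 0)
    assert c <= 22


def test_trial_metrics_matches_scalar_definitions(small_sim):
    ds = small_sim[0]
    tm = trial_metrics(ds.trials, ds.vocab)
    row = ds.trials.iloc[7]
    vec = [row[q] for q in ds.vocab.qualities]
    assert tm.loc[7, "intensity"] == trial_intensity(vec)
    assert tm.loc[7, "complexity"] == trial_complexity(vec)


class TestVersatility:
    def make_uses(self, rows, cmap):
        ind = pd.DataFrame(
            rows, index=pd.Index([f"d{i}" for i in range(len(rows))],
                                 name="drug_id"),
            columns=list(cmap),
        )
        return UseMatrix(indicators=ind, category_map=cmap)

    def test_counts_uses_and_distinct_categories(self):
        uses = self.make_uses(
            [[1, 1, 1]], {"u1": "A", "u2": "A", "u3": "B"}
        )
        v = drug_versatility(uses)
        assert v.loc[0, "n_uses"] == 3
        assert v.loc[0, "n_categories"] == 2

    def test_all_zero_row(self):
        uses = self.make_uses([[0, 0]], {"u1": "A", "u2": "B"})
        v = drug_versatility(uses)
        assert (v[["n_uses", "n_categories"]].to_numpy() == 0).all()

    def test_unknown_drug_lookup(self):
        uses = self.make_uses([[1]], {"u1": "A"})
        with pytest.raises(IntegrityError):
            drug_versatility(uses, drug_id="nope")

    def test_column_permutation_invariance(self):
        cmap = {"u1": "A", "u2": "B", "u3": "C"}
        uses = self.make_uses([[1, 0, 1], [0, 1, 1]], cmap)
        permuted = UseMatrix(
            indicators=uses.indicators[["u3", "u1", "u2"]],
            category_map=cmap,
        )
        pd.testing.assert_frame_equal(
            drug_versatility(uses), drug_versatility(permuted)
        )

    def test_monotone_under_flip_to_one(self):
        cmap = {"u1": "A", "u2": "B", "u3": "C"}
        base = self.make_uses([[1, 0, 0]], cmap)
        flipped = self.make_uses([[1, 1, 0]], cmap)
        v0, v1 = drug_versatility(base), drug_versatility(flipped)
        assert v1.loc[0, "n_uses"] >= v0.loc[0, "n_uses"]
        assert v1.loc[0, "n_categories"] >= v0.loc[0, "n_categories"]


class TestDescriptives:
    def test_one_of_two_trials_bitter(self, vocab):
        trials = make_trials(
            vocab,
            [
                ("t1", "d1", "p1", 0, {"bitter": 1}),
                ("t2", "d1", "p2", 0, {}),
            ],
        )
        uses = UseMatrix(
            indicators=pd.DataFrame(
                [[0]], index=pd.Index(["d1"], name="drug_id"), columns=["u1"]
            ),
            category_map={"u1": "A"},
        )
        stats = descriptive_summary(trials, uses, vocab)
        bitter = stats.per_quality.set_index("quality").loc["bitter"]
        assert bitter["reports"] == 1
        assert bitter["pct_of_trials"] == pytest.approx(50.0)
        weak = stats.intensity_levels.set_index("level").loc["weak"]
        assert weak["reports"] == 1
        assert weak["pct_of_reports"] == pytest.approx(100.0)

    def test_level_counts_sum_to_perception_reports(self, small_sim):
        ds = small_sim[0]
        stats = descriptive_summary(ds.trials, ds.uses, ds.vocab)
        assert (
            stats.intensity_levels["reports"].sum() == stats.n_perception_reports
        )
        # sum of per-quality reports equals total perception reports
        assert stats.per_quality["reports"].sum() == stats.n_perception_reports

    def test_pooled_qualities_are_union_over_trials(self, vocab):
        trials = make_trials(
            vocab,
            [
                ("t1", "d1", "p1", 0, {"bitter": 1}),
                ("t2", "d1", "p2", 0, {"sweet": 2}),
            ],
        )
        pooled = pooled_drug_qualities(trials, vocab)
        assert pooled["d1"] == 2

    def test_report_renders(self, small_sim):
        ds = small_sim[0]
        stats = descriptive_summary(ds.trials, ds.uses, ds.vocab)
        text = render_report(stats)
        assert "perception reports" in text.lower()


@pytest.mark.parametrize(
    "value,expected", [(39.16, "39"), (50.1, "50"), (3.22, "3.2"), (9.96, "10.0")]
)
def test_percentage_rounding_rule(value, expected):
    assert format_pct(value) == expected
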