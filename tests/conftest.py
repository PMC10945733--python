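import numpy as np
import pandas as pd
import pytest

from phylotaste.panel_data import (
    PanelDataset,
    QualityVocabulary,
    UseMatrix,
)
from phylotaste.simulate import SimulationScenario, simulate_dataset


@pytest.fixture(scope="session")
def vocab() -> QualityVocabulary:
    return QualityVocabulary()


def make_trials(vocab, rows):
    """Build a trial table from (trial_id, drug_id, panellist, days, scores)."""
    data = []
    for trial_id, drug_id, panellist, days, scores in rows:
        rec = {
            "trial_id": trial_id,
            "drug_id": drug_id,
            "panellist_id": panellist,
            "days_since_collection": days,
        }
        for q in vocab.qualities:
            rec[q] = scores.get(q, 0)
        data.append(rec)
    return pd.DataFrame(data)


@pytest.fixture
def tiny_dataset(vocab) -> PanelDataset:
    """Two drugs, three trials, three uses over two categories."""
    drugs = pd.DataFrame(
        {
            "drug_id": ["d1", "d2"],
            "taxon_name": ["Cinnamomum verum", "Anemone coronaria"],
            "genus": ["Cinnamomum", "Anemone"],
            "family": ["Lauraceae", "Ranunculaceae"],
            "plant_part": ["bark", "root"],
        }
    )
    trials = make_trials(
        vocab,
        [
            ("t1", "d1", "p1", 10, {"bitter": 2, "sweet": 1}),
            ("t2", "d1", "p2", 12, {"bitter": 1}),
            ("t3", "d2", "p1", 5, {}),
        ],
    )
    indicators = pd.DataFrame(
        [[1, 1, 0], [0, 0, 0]],
        index=pd.Index(["d1", "d2"], name="drug_id"),
        columns=["u1", "u2", "u3"],
    )
    uses = UseMatrix(
        indicators=indicators,
        category_map={"u1": "catA", "u2": "catA", "u3": "catB"},
    )
    return PanelDataset(drugs=drugs, trials=trials, uses=uses, vocab=vocab)


SMALL_SCENARIO = dict(n_taxa=10, n_drugs=12, n_panellists=3, n_uses=3)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across tests (deterministic)."""
    scenario = SimulationScenario(seed=11, **SMALL_SCENARIO)
    return simulate_dataset(scenario)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
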