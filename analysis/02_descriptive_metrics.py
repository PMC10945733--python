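"""Descriptive statistics of the panel dataset.

Reads the fixture written by 01_simulate_panel.py, recomputes the
report-style summaries (per-quality report counts and percentages,
weak/medium/strong shares, pooled qualities per drug, versatility), writes
the machine-readable tables under results/descriptives/, and prints the
human-readable report.
"""

import argparse
from pathlib import Path

from phylotaste.metrics import (
    descriptive_summary,
    drug_versatility,
    render_report,
)
from phylotaste.panel_data import (
    QualityVocabulary,
    load_drug_table,
    load_trials,
    load_use_matrix,
    validate_dataset,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "descriptives")
    args = ap.parse_args()

    vocab = QualityVocabulary()
    drugs = load_drug_table(args.data / "drugs.csv")
    trials = load_trials(args.data / "trials.csv", vocab)
    uses = load_use_matrix(args.data / "uses.csv",
                           args.data / "use_categories.csv")
    report = validate_dataset(drugs, trials, uses, vocab)
    if not report.ok:
        raise SystemExit("dataset invalid:\n" + report.render())

    stats = descriptive_summary(trials, uses, vocab)
    args.out.mkdir(parents=True, exist_ok=True)
    stats.per_quality.to_csv(args.out / "per_quality.csv", index=False)
    stats.intensity_levels.to_csv(args.out / "intensity_levels.csv",
                                  index=False)
    drug_versatility(uses).to_csv(args.out / "versatility.csv", index=False)
    text = render_report(stats)
    (args.out / "report.txt").write_text(text)
    print(text)


if __name__ == "__main__":
    main()
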