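"""Generate the study-shaped synthetic panel dataset used by the analyses.

Writes the five fixture files (drug table, sensory trials, use matrix,
use-category map, Newick tree) plus the ground-truth manifest under
results/data/, and prints the headline dataset shape.  Everything
downstream (descriptives, versatility models, the use-model battery) reads
these files, so the whole analysis is reproducible from this one seed.
"""

import argparse
from pathlib import Path

from phylotaste.panel_data import validate_dataset
from phylotaste.simulate import SimulationScenario, simulate_dataset, write_fixture

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "data")
    args = ap.parse_args()

    scenario = SimulationScenario(seed=args.seed)
    paths = write_fixture(args.out, scenario)
    ds, tree, ranks, truth = simulate_dataset(scenario)
    report = validate_dataset(ds.drugs, ds.trials, ds.uses, ds.vocab)

    print(f"wrote fixture set to {args.out} (seed {args.seed})")
    print(report.render())
    print(
        f"\ntrue versatility counts: median "
        f"{truth.versatility['n_categories'].median():.0f}, "
        f"max {truth.versatility['n_categories'].max()}"
    )
    print(f"generating phylogenetic share (versatility response): "
          f"{truth.h2_response['versatility']:.2f}")
    for key, p in paths.items():
        print(f"  {key}: {p}")


if __name__ == "__main__":
    main()
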