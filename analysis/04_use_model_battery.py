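"""The full model battery and the quality x use effect map.

Runs every model of the design on the fixture from 01_simulate_panel.py —
two zero-truncated Poisson versatility models plus two probit models per
therapeutic use — then aggregates the quality-set use models into the
effect map: posterior modes masked at p_x < 0.05 and summed per quality
into the magnitude of effect.  Writes all tables under results/battery/
and prints the significant-cell counts.
"""

import argparse
from pathlib import Path

import pandas as pd

from phylotaste.battery import effect_map, run_battery
from phylotaste.panel_data import (
    PanelDataset,
    QualityVocabulary,
    load_drug_table,
    load_trials,
    load_use_matrix,
)
from phylotaste.pglmm import DESK_MCMC, MCMCSettings
from phylotaste.phylo import parse_newick, phylo_correlation

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "battery")
    args = ap.parse_args()

    vocab = QualityVocabulary()
    ds = PanelDataset(
        drugs=load_drug_table(args.data / "drugs.csv"),
        trials=load_trials(args.data / "trials.csv", vocab),
        uses=load_use_matrix(args.data / "uses.csv",
                             args.data / "use_categories.csv"),
        vocab=vocab,
    )
    tree = parse_newick((args.data / "tree.nwk").read_text())
    corr = phylo_correlation(tree, sorted(ds.drugs["taxon_name"].unique()))

    result = run_battery(
        ds, corr, MCMCSettings(**DESK_MCMC), master_seed=args.seed,
        drop_constant=True,
    )
    em = effect_map(result, alpha=args.alpha)

    args.out.mkdir(parents=True, exist_ok=True)
    rows = []
    for key, summ in result.versatility.items():
        rows.append(summ.coefficients.assign(model=f"versatility:{key}",
                                             h2_mode=summ.h2_mode))
    for use, sets in result.use_models.items():
        for fx, summ in sets.items():
            rows.append(summ.coefficients.assign(model=f"use:{use}:{fx}",
                                                 h2_mode=summ.h2_mode))
    pd.concat(rows).to_csv(args.out / "model_summaries.csv", index=False)
    em.betas.to_csv(args.out / "effect_map_betas.csv")
    em.masked_betas.to_csv(args.out / "effect_map_masked.csv")
    pd.DataFrame({"magnitude": em.magnitude, "total": em.total}).to_csv(
        args.out / "magnitude_of_effect.csv"
    )

    pos, neg = em.n_significant
    print(f"battery: {result.n_models} models "
          f"({len(result.skipped)} skipped)")
    for rec in result.skipped:
        print(f"  skipped {rec.model}: {rec.reason}")
    print(f"significant quality-use cells at p_x < {args.alpha}: "
          f"{pos} positive, {neg} negative")
    print("\nper-quality magnitude of effect (top 5 by |magnitude|):")
    top = em.magnitude.abs().sort_values(ascending=False).head(5).index
    for q in top:
        print(f"  {q}: {em.magnitude[q]:+.3f} (total {em.total[q]:+.3f})")
    print(
        "\nnote: probit coefficients under the flat published prior are "
        "scale-inflated at this dataset size whenever a quality-use pair is "
        "quasi-separated; magnitudes are comparable within a run, not "
        "across dataset sizes (see docs/methods.md)."
    )


if __name__ == "__main__":
    main()
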