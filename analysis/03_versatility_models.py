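"""Therapeutic-versatility regressions (zero-truncated Poisson PGLMMs).

Fits the two trial-level versatility models on the fixture written by
01_simulate_panel.py — (1) all 22 chemosensory qualities, (2) intensity +
complexity — with phylogeny, plant part and panellist as random effects,
writes the coefficient tables under results/versatility/, and prints the
intensity/complexity slopes, their sign-crossing probabilities p_x, and
the modal phylogenetic heritability h2.
"""

import argparse
from pathlib import Path

import pandas as pd

from phylotaste.battery import run_versatility_models
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
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "versatility")
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

    summaries = run_versatility_models(
        ds, corr, MCMCSettings(**DESK_MCMC), master_seed=args.seed,
        drop_constant=True,
    )
    args.out.mkdir(parents=True, exist_ok=True)
    for key, summ in summaries.items():
        summ.coefficients.to_csv(args.out / f"{key}.csv", index=False)
        print(f"\nmodel: versatility ~ {key}  (modal h2 = {summ.h2_mode:.3f})")
        show = summ.coefficients.set_index("name")
        rows = (["intensity", "complexity"] if key == "intensity_complexity"
                else ["bitter", "sweet", "sour", "musky"])
        print(show.loc[[r for r in rows if r in show.index],
                       ["mode", "lo95", "hi95", "px"]].round(3))
    pd.DataFrame(
        [(k, s.h2_mode) for k, s in summaries.items()],
        columns=["model", "h2_mode"],
    ).to_csv(args.out / "h2.csv", index=False)


if __name__ == "__main__":
    main()
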