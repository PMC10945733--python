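"""Synthetic tasting-panel datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a pure-birth ultrametric phylogeny (height 1) with genus/family labels
  assigned by clade blocks, so grafting is exercisable;
* 22 latent quality traits per drug with phylogenetic, plant-part,
  panellist and residual variance components, discretised to ordinal scores
  0-3 by fixed cut-points;
* drug-level binary use indicators from probit liabilities driven by
  drug-mean observed scores through a sparse true 22 x n_uses effect
  matrix, plus phylogenetic/part/residual liability components;
* a drug-level versatility count from a zero-truncated Poisson whose
  log-rate is linear in the drug-mean scores (true 22-vector of effects)
  plus the same response-level variance components.

Everything is deterministic given (scenario, seed); the returned
TruthBundle carries the realised effects needed to score recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import ScenarioError
from .panel_data import (
    DEFAULT_QUALITIES,
    PanelDataset,
    QualityVocabulary,
    UseMatrix,
    write_drug_table,
    write_trials,
    write_use_matrix,
)
from .phylo import RankMap, phylo_correlation

PLANT_PARTS = ("root", "bark", "herb", "seed", "leaf")


def _default_beta_versatility() -> np.ndarray:
    # 4 non-zero effects of drug-mean scores on the log versatility rate
    beta = np.zeros(22)
    q = list(DEFAULT_QUALITIES)
    beta[q.index("bitter")] = 0.12
    beta[q.index("sour")] = -0.12
    beta[q.index("sweet")] = 0.08
    beta[q.index("musky")] = 0.08
    return beta


def _default_beta_use(n_uses: int) -> np.ndarray:
    # 8 sparse probit-scale effects spread over the uses
    beta = np.zeros((22, n_uses))
    q = list(DEFAULT_QUALITIES)
    placements = [
        ("bitter", 0, 1.0),
        ("astringent", 1, 0.8),
        ("sweet", 2, 0.8),
        ("sour", 2, -0.8),
        ("musky", 3, 1.0),
        ("salty", 4, -0.8),
        ("starchy", 4, 0.8),
        ("smoky", 5, 1.0),
    ]
    for name, use, val in placements:
        if use < n_uses:
            beta[q.index(name), use] = val
    return beta


@dataclass
class SimulationScenario:
    """Study-shaped defaults: 80 taxa, 100 drugs, 5 panellists, ~570 trials
    (mean 5.7 per drug), 6 uses with 8 non-zero true quality effects."""

    n_taxa: int = 80
    n_drugs: int = 100
    n_panellists: int = 5
    mean_trials_per_drug: float = 5.7
    sd_trials_per_drug: float = 1.3
    n_uses: int = 6
    #: latent quality-trait variance components (per trait, unit-scale tree).
    #: Within-drug noise (panellist, resid) is kept small so trial scores
    #: closely proxy the drug-level profile that drives the responses.
    score_variances: dict = field(
        default_factory=lambda: {
            "phylo": 1.0, "plant_part": 0.15, "panellist": 0.02, "resid": 0.05
        }
    )
    #: log-rate variance components of the versatility count.  The fitted
    #: model has no drug-level residual term (responses repeat across a
    #: drug's trials), so non-phylogenetic drug-level response noise is
    #: unidentifiable and kept small by default.
    versatility_response_variances: dict = field(
        default_factory=lambda: {"phylo": 0.9, "plant_part": 0.05, "resid": 0.05}
    )
    #: probit-liability variance components of the use indicators; residual
    #: 1.0 matches the conventional identified probit scale
    use_response_variances: dict = field(
        default_factory=lambda: {"phylo": 1.0, "plant_part": 0.1, "resid": 1.0}
    )
    quality_baseline: float = -0.6
    cutpoints: tuple[float, float, float] = (0.8, 1.8, 2.8)
    beta_versatility: np.ndarray = field(default_factory=_default_beta_versatility)
    versatility_intercept: float = 1.4  # ~ log 4 uses at baseline
    beta_use: np.ndarray | None = None  # (22, n_uses); default sparse
    use_intercept: float = -0.5
    days_range: tuple[int, int] = (30, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta_versatility = np.asarray(self.beta_versatility, dtype=float)
        if self.beta_use is None:
            self.beta_use = _default_beta_use(self.n_uses)
        self.beta_use = np.asarray(self.beta_use, dtype=float)
        if self.beta_versatility.shape != (22,):
            raise ScenarioError("beta_versatility must have 22 entries")
        if self.beta_use.shape != (22, self.n_uses):
            raise ScenarioError("beta_use must be 22 x n_uses")
        all_vars = (
            list(self.score_variances.values())
            + list(self.versatility_response_variances.values())
            + list(self.use_response_variances.values())
        )
        if any(v < 0 for v in all_vars):
            raise ScenarioError("variances must be non-negative")
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ScenarioError("cut-points must be strictly increasing")
        if self.n_drugs < self.n_taxa:
            raise ScenarioError("need at least one drug per taxon")
        if self.n_drugs > self.n_taxa * len(PLANT_PARTS):
            raise ScenarioError(
                "too many drugs: at most one per (taxon, plant part) pair"
            )


@dataclass
class TruthBundle:
    """Everything needed to score recovery of the generating process."""

    scenario: SimulationScenario
    beta_versatility: np.ndarray
    beta_use: np.ndarray
    versatility: pd.DataFrame  # drug_id, n_categories (the true ZT-Poisson count)
    drug_mean_scores: pd.DataFrame  # drug x 22 mean observed scores
    drug_to_taxon: dict[str, str]
    #: generating phylogenetic share of the response-level variance, per
    #: response kind ("versatility", "use")
    h2_response: dict[str, float]

    def to_manifest(self) -> dict:
        sc = asdict(self.scenario)
        sc["beta_versatility"] = self.scenario.beta_versatility.tolist()
        sc["beta_use"] = self.scenario.beta_use.tolist()
        return {
            "scenario": sc,
            "h2_response": self.h2_response,
            "versatility": self.versatility.to_dict(orient="list"),
        }


def simulate_tree(n_taxa: int, seed: int = 0) -> tuple[dendropy.Tree, RankMap]:
    """Pure-birth ultrametric tree scaled to height 1.

    Tip labels are binomials ``GenXXX spY``; genera and families are clade
    blocks cut at fixed relative depths (0.75 and 0.35), recorded in the
    returned RankMap.
    """
    if n_taxa < 2:
        raise ScenarioError("need at least 2 taxa")
    rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    root.birth_time = 0.0
    root.split_time = 0.0  # the root is the first split; its edge has length 0
    active = []
    for _ in range(2):
        child = root.new_child()
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        node.split_time = t
        for _ in range(2):
            child = node.new_child()
            child.birth_time = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_taxa)

    for node in tree.preorder_node_iter():
        end = getattr(node, "split_time", t_end)
        node.edge.length = (end - node.birth_time) / t_end

    # name tips and assign genus/family blocks by depth thresholds
    tree.calc_node_root_distances()
    genus_of: dict[str, str] = {}
    family_of: dict[str, str] = {}
    g = f = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        pdepth = parent.root_distance if parent else 0.0
        if node.root_distance >= 0.35 and pdepth < 0.35:
            f += 1
            for leaf in node.leaf_iter():
                family_of[id(leaf)] = f"Fam{f:02d}"
        if node.root_distance >= 0.75 and pdepth < 0.75:
            g += 1
            for i, leaf in enumerate(node.leaf_iter(), 1):
                genus_of[id(leaf)] = (f"Gen{g:03d}", i)

    entries = {}
    for leaf in tree.leaf_node_iter():
        genus, i = genus_of[id(leaf)]
        label = f"{genus} sp{i}"
        leaf.taxon = tree.taxon_namespace.new_taxon(label=label)
        entries[label] = (genus, family_of.get(id(leaf)))
    return tree, RankMap(entries)


def _draw_ztpoisson(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Zero-truncated Poisson draws by redrawing zeros (rates here are O(1)+)."""
    out = rng.poisson(lam)
    while (out == 0).any():
        mask = out == 0
        out[mask] = rng.poisson(lam[mask])
    return out


def simulate_panel(
    scenario: SimulationScenario, tree: dendropy.Tree
) -> tuple[PanelDataset, TruthBundle]:
    """Generate drugs, trials and uses over ``tree`` with known truth."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    vocab = QualityVocabulary()
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(taxa) < scenario.n_taxa:
        raise ScenarioError("tree has fewer tips than n_taxa")
    taxa = taxa[: scenario.n_taxa]
    A = phylo_correlation(tree, taxa).values
    Lchol = np.linalg.cholesky(A + 1e-10 * np.eye(len(taxa)))

    # drugs: one per taxon, extras as additional plant parts of random taxa
    rows = []
    part_count = {t: 0 for t in taxa}
    for i, taxon in enumerate(taxa):
        rows.append((f"d{i:04d}", taxon, PLANT_PARTS[0]))
        part_count[taxon] = 1
    for j in range(scenario.n_taxa, scenario.n_drugs):
        candidates = [t for t in taxa if part_count[t] < len(PLANT_PARTS)]
        taxon = candidates[int(rng.integers(len(candidates)))]
        rows.append((f"d{j:04d}", taxon, PLANT_PARTS[part_count[taxon]]))
        part_count[taxon] += 1
    drugs = pd.DataFrame(rows, columns=["drug_id", "taxon_name", "plant_part"])
    drugs["genus"] = drugs["taxon_name"].str.split().str[0]
    drugs["family"] = pd.NA
    drugs = drugs[["drug_id", "taxon_name", "genus", "family", "plant_part"]]
    taxon_idx = {t: i for i, t in enumerate(taxa)}
    part_idx = {p: i for i, p in enumerate(PLANT_PARTS)}
    drug_to_taxon = dict(zip(drugs["drug_id"], drugs["taxon_name"]))

    sv = scenario.score_variances
    # drug-level latent quality traits (n_drugs x 22).  Phylogenetic
    # deviations are centred across taxa so the baseline pins prevalence
    # (the fitted intercept absorbs the root state in any case).
    phylo_fx = np.sqrt(sv["phylo"]) * (
        Lchol @ rng.standard_normal((len(taxa), 22))
    )
    phylo_fx = phylo_fx - phylo_fx.mean(axis=0)
    part_fx = np.sqrt(sv["plant_part"]) * rng.standard_normal((len(PLANT_PARTS), 22))
    drug_latent = (
        scenario.quality_baseline
        + phylo_fx[[taxon_idx[t] for t in drugs["taxon_name"]]]
        + part_fx[[part_idx[p] for p in drugs["plant_part"]]]
    )
    pan_fx = np.sqrt(sv["panellist"]) * rng.standard_normal(
        (scenario.n_panellists, 22)
    )

    # trials
    n_trials = np.clip(
        np.rint(
            rng.normal(
                scenario.mean_trials_per_drug,
                scenario.sd_trials_per_drug,
                size=scenario.n_drugs,
            )
        ).astype(int),
        1,
        None,
    )
    cut = np.asarray(scenario.cutpoints)
    trial_rows = []
    tid = 0
    for d in range(scenario.n_drugs):
        m = n_trials[d]
        if m <= scenario.n_panellists:
            panellists = rng.choice(scenario.n_panellists, size=m, replace=False)
        else:
            panellists = rng.integers(scenario.n_panellists, size=m)
        days = rng.integers(*scenario.days_range, size=m)
        for j in range(m):
            latent = (
                drug_latent[d]
                + pan_fx[panellists[j]]
                + np.sqrt(sv["resid"]) * rng.standard_normal(22)
            )
            scores = (latent[:, None] > cut[None, :]).sum(axis=1)
            trial_rows.append(
                (
                    f"t{tid:05d}",
                    drugs["drug_id"].iloc[d],
                    f"p{panellists[j]:02d}",
                    int(days[j]),
                    *scores.astype(int),
                )
            )
            tid += 1
    trials = pd.DataFrame(
        trial_rows,
        columns=["trial_id", "drug_id", "panellist_id", "days_since_collection"]
        + list(vocab.qualities),
    )

    # drug-mean observed scores drive the drug-level responses
    qbar = trials.groupby("drug_id")[list(vocab.qualities)].mean()
    qbar = qbar.loc[drugs["drug_id"]]
    Q = qbar.to_numpy()

    d_taxon = [taxon_idx[t] for t in drugs["taxon_name"]]
    d_part = [part_idx[p] for p in drugs["plant_part"]]

    def response_effects(n_cols: int, rv: dict) -> np.ndarray:
        phylo = np.sqrt(rv["phylo"]) * (
            Lchol @ rng.standard_normal((len(taxa), n_cols))
        )
        phylo = phylo - phylo.mean(axis=0)
        part = np.sqrt(rv["plant_part"]) * rng.standard_normal(
            (len(PLANT_PARTS), n_cols)
        )
        resid = np.sqrt(rv["resid"]) * rng.standard_normal(
            (scenario.n_drugs, n_cols)
        )
        return phylo[d_taxon] + part[d_part] + resid

    # binary uses from probit liabilities
    liab = scenario.use_intercept + Q @ scenario.beta_use
    liab = liab + response_effects(scenario.n_uses, scenario.use_response_variances)
    indicators = (liab > 0).astype(int)
    use_ids = [f"use{u:02d}" for u in range(scenario.n_uses)]
    category_map = {u: f"cat{i // 2:02d}" for i, u in enumerate(use_ids)}
    uses = UseMatrix(
        indicators=pd.DataFrame(
            indicators, index=pd.Index(drugs["drug_id"], name="drug_id"),
            columns=use_ids,
        ),
        category_map=category_map,
    )

    # versatility count from a zero-truncated Poisson
    log_rate = (
        scenario.versatility_intercept
        + Q @ scenario.beta_versatility
        + response_effects(1, scenario.versatility_response_variances)[:, 0]
    )
    counts = _draw_ztpoisson(rng, np.exp(log_rate))
    versatility = pd.DataFrame(
        {"drug_id": drugs["drug_id"], "n_categories": counts.astype(int)}
    )

    def share(rv: dict) -> float:
        return rv["phylo"] / sum(rv.values())

    h2_resp = {
        "versatility": share(scenario.versatility_response_variances),
        "use": share(scenario.use_response_variances),
    }
    dataset = PanelDataset(drugs=drugs, trials=trials, uses=uses, vocab=vocab)
    truth = TruthBundle(
        scenario=scenario,
        beta_versatility=scenario.beta_versatility,
        beta_use=scenario.beta_use,
        versatility=versatility,
        drug_mean_scores=qbar,
        drug_to_taxon=drug_to_taxon,
        h2_response=h2_resp,
    )
    return dataset, truth


def simulate_dataset(
    scenario: SimulationScenario | None = None,
) -> tuple[PanelDataset, dendropy.Tree, RankMap, TruthBundle]:
    """One-call generation of tree + panel dataset + truth."""
    scenario = scenario or SimulationScenario()
    tree, ranks = simulate_tree(scenario.n_taxa, scenario.seed)
    dataset, truth = simulate_panel(scenario, tree)
    return dataset, tree, ranks, truth


def write_fixture(
    outdir, scenario: SimulationScenario | None = None
) -> dict[str, str]:
    """Write the five fixture files plus a truth manifest; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = scenario or SimulationScenario()
    dataset, tree, ranks, truth = simulate_dataset(scenario)
    paths = {
        "drugs": outdir / "drugs.csv",
        "trials": outdir / "trials.csv",
        "uses": outdir / "uses.csv",
        "use_categories": outdir / "use_categories.csv",
        "tree": outdir / "tree.nwk",
        "manifest": outdir / "truth.json",
    }
    write_drug_table(dataset.drugs, paths["drugs"])
    write_trials(dataset.trials, paths["trials"])
    write_use_matrix(dataset.uses, paths["uses"], paths["use_categories"])
    tree.write(path=str(paths["tree"]), schema="newick")
    manifest = truth.to_manifest()
    manifest["seed"] = scenario.seed
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return {k: str(v) for k, v in paths.items()}
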