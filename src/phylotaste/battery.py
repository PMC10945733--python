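"""Orchestration of the full model battery and the effect-map aggregation.

The battery mirrors the study design: two zero-truncated Poisson models for
therapeutic versatility (all 22 qualities; intensity + complexity), then for
each therapeutic use two probit models (same two fixed-effect sets) — 94
models for the full 46-use matrix.  Uses whose indicator is constant are
skipped with a recorded reason.  Each model draws its seed deterministically
from a master seed, so reruns and any execution order give identical
results.

The effect map collects the 22 x n_uses posterior modes from the
quality-set use models, masks them at the significance rule p_x < alpha,
and aggregates a per-quality "magnitude of effect" (sum of significant
betas across uses) alongside the unmasked total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelError
from .metrics import drug_versatility
from .panel_data import PanelDataset
from .pglmm import (
    DesignData,
    MCMCSettings,
    ModelSpec,
    PosteriorSummary,
    build_design,
    default_random_terms,
    sample_posterior,
    summarize,
)
from .phylo import CorrelationMatrix


@dataclass
class SkipRecord:
    model: str
    reason: str


@dataclass
class BatteryResult:
    versatility: dict[str, PosteriorSummary]  # keys: qualities, intensity_complexity
    use_models: dict[str, dict[str, PosteriorSummary]]  # use -> set -> summary
    skipped: list[SkipRecord]
    master_seed: int
    qualities: list[str]

    @property
    def n_models(self) -> int:
        return len(self.versatility) + sum(len(v) for v in self.use_models.values())


def _model_seeds(master_seed: int, labels: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master_seed).spawn(len(labels))
    return {
        lbl: int(child.generate_state(1, np.uint32)[0])
        for lbl, child in zip(labels, children)
    }


def _fit(
    dataset: PanelDataset,
    spec: ModelSpec,
    versatility: pd.DataFrame | None,
    drug_to_taxon: dict[str, str] | None,
) -> tuple[PosteriorSummary, DesignData]:
    design = build_design(dataset, spec, versatility, drug_to_taxon)
    chain = sample_posterior(design, spec)
    return summarize(chain, design), design


def run_versatility_models(
    dataset: PanelDataset,
    corr: CorrelationMatrix,
    mcmc: MCMCSettings | None = None,
    versatility: pd.DataFrame | None = None,
    drug_to_taxon: dict[str, str] | None = None,
    master_seed: int = 0,
    fix_residual: float | None = None,
    drop_constant: bool = False,
) -> dict[str, PosteriorSummary]:
    """The two zero-truncated Poisson versatility models."""
    mcmc = mcmc or MCMCSettings()
    seeds = _model_seeds(master_seed, ["versatility_qualities", "versatility_ic"])
    out = {}
    for key, fx in (
        ("qualities", "qualities"),
        ("intensity_complexity", "intensity_complexity"),
    ):
        label = "versatility_qualities" if fx == "qualities" else "versatility_ic"
        spec = ModelSpec(
            response="versatility",
            family="zt_poisson",
            fixed_effects=fx,
            random_terms=default_random_terms(corr),
            fix_residual=fix_residual,
            drop_constant=drop_constant,
            mcmc=MCMCSettings(
                iterations=mcmc.iterations,
                burn_in=mcmc.burn_in,
                thin=mcmc.thin,
                seed=seeds[label],
            ),
        )
        try:
            out[key], _ = _fit(dataset, spec, versatility, drug_to_taxon)
        except ModelError as exc:
            raise ModelError(f"versatility model ({fx}): {exc}") from exc
    return out


def run_use_models(
    dataset: PanelDataset,
    corr: CorrelationMatrix,
    mcmc: MCMCSettings | None = None,
    drug_to_taxon: dict[str, str] | None = None,
    master_seed: int = 0,
    fix_residual: float | None = None,
    drop_constant: bool = False,
    fixed_effect_sets: tuple[str, ...] = ("qualities", "intensity_complexity"),
) -> tuple[dict[str, dict[str, PosteriorSummary]], list[SkipRecord]]:
    """Per-use probit models: one per (use, fixed-effect set).

    A use with a constant indicator (all 0 or all 1) is skipped with a
    recorded reason rather than crashing the battery.
    """
    mcmc = mcmc or MCMCSettings()
    uses = dataset.uses.indicators.columns
    labels = [f"use:{u}:{fx}" for u in uses for fx in fixed_effect_sets]
    seeds = _model_seeds(master_seed, labels)
    results: dict[str, dict[str, PosteriorSummary]] = {}
    skipped: list[SkipRecord] = []
    for use in uses:
        col = dataset.uses.indicators[use]
        if col.nunique() < 2:
            skipped.append(
                SkipRecord(f"use:{use}", f"constant response (all {col.iloc[0]})")
            )
            continue
        results[use] = {}
        for fx in fixed_effect_sets:
            label = f"use:{use}:{fx}"
            spec = ModelSpec(
                response=f"use:{use}",
                family="probit",
                fixed_effects=fx,
                random_terms=default_random_terms(corr),
                fix_residual=fix_residual,
                drop_constant=drop_constant,
                mcmc=MCMCSettings(
                    iterations=mcmc.iterations,
                    burn_in=mcmc.burn_in,
                    thin=mcmc.thin,
                    seed=seeds[label],
                ),
            )
            try:
                results[use][fx], _ = _fit(dataset, spec, None, drug_to_taxon)
            except ModelError as exc:
                skipped.append(SkipRecord(label, str(exc)))
    return results, skipped


def run_battery(
    dataset: PanelDataset,
    corr: CorrelationMatrix,
    mcmc: MCMCSettings | None = None,
    master_seed: int = 0,
    versatility: pd.DataFrame | None = None,
    drug_to_taxon: dict[str, str] | None = None,
    probit_fix_residual: float | None = None,
    drop_constant: bool = False,
) -> BatteryResult:
    """Run the complete battery (2 versatility + 2 per use)."""
    if versatility is None:
        versatility = drug_versatility(dataset.uses)
    vers = run_versatility_models(
        dataset, corr, mcmc, versatility, drug_to_taxon, master_seed,
        drop_constant=drop_constant,
    )
    use_models, skipped = run_use_models(
        dataset, corr, mcmc, drug_to_taxon, master_seed + 1,
        fix_residual=probit_fix_residual, drop_constant=drop_constant,
    )
    return BatteryResult(
        versatility=vers,
        use_models=use_models,
        skipped=skipped,
        master_seed=master_seed,
        qualities=list(dataset.vocab.qualities),
    )


@dataclass
class EffectMap:
    """22 x n_uses posterior-mode matrix with the significance mask and the
    per-quality magnitude-of-effect aggregation."""

    betas: pd.DataFrame  # qualities x uses, all posterior modes
    px: pd.DataFrame  # matching p_x values
    mask: pd.DataFrame  # True where p_x < alpha
    alpha: float
    magnitude: pd.Series = field(init=False)  # sum of significant betas
    total: pd.Series = field(init=False)  # sum of all betas

    def __post_init__(self) -> None:
        self.magnitude = self.betas.where(self.mask, 0.0).sum(axis=1)
        self.total = self.betas.sum(axis=1)

    @property
    def masked_betas(self) -> pd.DataFrame:
        """Non-significant cells zeroed, for display."""
        return self.betas.where(self.mask, 0.0)

    @property
    def n_significant(self) -> tuple[int, int]:
        """(positive, negative) counts of significant quality-use cells."""
        sig = self.betas[self.mask]
        return int((sig > 0).sum().sum()), int((sig < 0).sum().sum())


def effect_map(
    battery: BatteryResult,
    alpha: float = 0.05,
    stat: str = "mode",
) -> EffectMap:
    """Build the effect map from the quality-set use models.

    Skipped models contribute no cells (their columns are dropped).  The
    per-cell statistic is the posterior mode by default; ``stat="mean"``
    switches to the mean.
    """
    qualities = battery.qualities
    uses = [u for u in battery.use_models if "qualities" in battery.use_models[u]]
    betas = pd.DataFrame(0.0, index=qualities, columns=uses)
    px = pd.DataFrame(1.0, index=qualities, columns=uses)
    for u in uses:
        coefs = battery.use_models[u]["qualities"].coefficients.set_index("name")
        for q in qualities:
            if q not in coefs.index:  # dropped constant column: no cell
                continue
            betas.loc[q, u] = coefs.loc[q, stat]
            px.loc[q, u] = coefs.loc[q, "px"]
    return EffectMap(betas=betas, px=px, mask=px < alpha, alpha=alpha)


def benjamini_hochberg(px: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Optional FDR mask over the full quality x use grid (an extension to
    the per-model rule; clearly labelled in reports)."""
    flat = px.to_numpy().ravel()
    m = flat.size
    order = np.argsort(flat)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = flat[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return pd.DataFrame(
        mask.reshape(px.shape), index=px.index, columns=px.columns
    )
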