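"""Per-trial and per-drug chemosensory statistics and descriptive summaries.

Two trial-level metrics summarise a panellist's perception of one drug
sample:

* **intensity** — the sum of the 22 ordinal scores (0..66);
* **complexity** — the number of qualities scored non-zero (0..22).

The drug-level **therapeutic versatility** is the number of distinct broader
categories of use (of 25) a drug is recommended for, derived from the binary
use matrix through the use -> category map.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import IntegrityError
from .panel_data import QualityVocabulary, UseMatrix


def trial_intensity(scores) -> int:
    """Sum of all 22 ordinal scores of one trial."""
    return int(sum(scores))


def trial_complexity(scores) -> int:
    """Number of qualities scored non-zero in one trial."""
    return int(sum(1 for s in scores if s > 0))


def trial_metrics(
    trials: pd.DataFrame, vocab: QualityVocabulary | None = None
) -> pd.DataFrame:
    """Vectorised intensity/complexity for a trial table.

    Returns a frame with columns trial_id, intensity, complexity.
    Invariants: complexity <= intensity <= 3 * complexity.
    """
    vocab = vocab or QualityVocabulary()
    block = trials[list(vocab.qualities)]
    return pd.DataFrame(
        {
            "trial_id": trials["trial_id"],
            "intensity": block.sum(axis=1).astype(int),
            "complexity": (block > 0).sum(axis=1).astype(int),
        }
    )


def drug_versatility(uses: UseMatrix, drug_id: str | None = None) -> pd.DataFrame:
    """Number of uses and of distinct use categories per drug.

    With ``drug_id`` given, restrict to that drug (lookup error if absent).
    """
    ind = uses.indicators
    if drug_id is not None:
        if drug_id not in ind.index:
            raise IntegrityError(f"unknown drug {drug_id!r}")
        ind = ind.loc[[drug_id]]
    cats = pd.Series(uses.category_map)

    def n_categories(row) -> int:
        return cats[row.index[row == 1]].nunique()

    return pd.DataFrame(
        {
            "drug_id": ind.index,
            "n_uses": ind.sum(axis=1).astype(int).to_numpy(),
            "n_categories": ind.apply(n_categories, axis=1).astype(int).to_numpy(),
        }
    ).reset_index(drop=True)


def pooled_drug_qualities(
    trials: pd.DataFrame, vocab: QualityVocabulary | None = None
) -> pd.Series:
    """Per-drug count of distinct qualities scored non-zero by any panellist.

    This is the pooled (union over trials) count reported descriptively;
    the per-panellist complexity above is the modelling covariate.
    """
    vocab = vocab or QualityVocabulary()
    nz = trials[list(vocab.qualities)] > 0
    return nz.groupby(trials["drug_id"]).any().sum(axis=1).astype(int)


@dataclass
class DescriptiveStats:
    """Descriptive summaries of a panel dataset.

    per_quality: reports (trials with score>0) and % of all trials, per quality.
    intensity_levels: counts of weak/medium/strong scores and % of all
    perception reports.  A perception report is one non-zero
    (trial, quality) score.
    """

    per_quality: pd.DataFrame
    intensity_levels: pd.DataFrame
    n_trials: int
    n_perception_reports: int
    pooled_quality_range: tuple[int, int]
    mean_uses_per_drug: float
    per_use_records: pd.Series


def descriptive_summary(
    trials: pd.DataFrame,
    uses: UseMatrix,
    vocab: QualityVocabulary | None = None,
) -> DescriptiveStats:
    """Recompute the dataset's descriptive statistics.

    Percentage denominators follow the reporting convention: per-quality
    percentages divide by the total number of trials; per-level (weak,
    medium, strong) percentages divide by the total number of perception
    reports.
    """
    vocab = vocab or QualityVocabulary()
    block = trials[list(vocab.qualities)]
    n_trials = len(trials)
    counts = (block > 0).sum(axis=0).astype(int)
    total_reports = int(counts.sum())
    per_quality = pd.DataFrame(
        {
            "quality": list(vocab.qualities),
            "reports": counts.to_numpy(),
            "pct_of_trials": (
                100.0 * counts.to_numpy() / n_trials if n_trials else 0.0
            ),
        }
    )
    level_counts = {
        level: int((block == score).to_numpy().sum())
        for level, score in (("weak", 1), ("medium", 2), ("strong", 3))
    }
    intensity_levels = pd.DataFrame(
        {
            "level": list(level_counts),
            "reports": list(level_counts.values()),
            "pct_of_reports": [
                100.0 * c / total_reports if total_reports else 0.0
                for c in level_counts.values()
            ],
        }
    )
    pooled = pooled_drug_qualities(trials, vocab)
    versa = drug_versatility(uses)
    return DescriptiveStats(
        per_quality=per_quality,
        intensity_levels=intensity_levels,
        n_trials=n_trials,
        n_perception_reports=total_reports,
        pooled_quality_range=(int(pooled.min()), int(pooled.max()))
        if len(pooled)
        else (0, 0),
        mean_uses_per_drug=float(versa["n_uses"].mean()) if len(versa) else 0.0,
        per_use_records=uses.indicators.sum(axis=0).astype(int),
    )


def format_pct(x: float) -> str:
    """Report-rounding rule: >=10 to integer, <10 to one decimal."""
    return f"{x:.0f}" if x >= 10 else f"{x:.1f}"


def render_report(stats: DescriptiveStats) -> str:
    """Human-readable text report mirroring the descriptive summaries."""
    lines = [
        f"Sensory trials: {stats.n_trials}",
        f"Individual perception reports: {stats.n_perception_reports}",
        "",
        "Reports per quality (count; % of all assessed samples):",
    ]
    pq = stats.per_quality.sort_values("reports", ascending=False)
    for _, row in pq.iterrows():
        lines.append(
            f"  {row['quality']}: {row['reports']} reports;"
            f" {format_pct(row['pct_of_trials'])}%"
        )
    lines.append("")
    lines.append("Reports per intensity level (count; % of all perception reports):")
    for _, row in stats.intensity_levels.iterrows():
        lines.append(
            f"  {row['level']}: {row['reports']} reports;"
            f" {format_pct(row['pct_of_reports'])}%"
        )
    lo, hi = stats.pooled_quality_range
    lines += [
        "",
        f"Distinct qualities per drug (pooled over panellists): {lo} to {hi}",
        f"Mean therapeutic uses per drug: {stats.mean_uses_per_drug:.1f}",
        "",
        "Use records per therapeutic use:",
    ]
    for use, n in stats.per_use_records.sort_values(ascending=False).items():
        lines.append(f"  {use}: {n}")
    return "\n".join(lines)
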