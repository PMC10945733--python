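"""Domain types, delimited-text I/O, and validation for tasting-panel datasets.

A dataset couples three tables:

* a **drug table** — one row per botanical drug (a specific plant part of a
  specific taxon used therapeutically);
* a **sensory-trial table** — one row per (drug sample, panellist) tasting
  trial, carrying ordinal scores 0-3 over a fixed vocabulary of 22
  chemosensory qualities;
* a **use matrix** — binary drug x use indicators for 46 therapeutic uses,
  together with a map from uses into at most 25 broader categories of use.

All files are delimited text (comma by default; semicolon and tab are
accepted via ``sep``), UTF-8, with a header row.  A quality absent from a
trial row is an explicit score of 0 — the ordinal scale includes "absent" —
so loaded trial tables always carry a complete score vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    IntegrityError,
    MappingError,
    RangeError,
    SchemaError,
    VocabularyError,
)

#: The 22 chemosensory descriptors used by the tasting panel, in the fixed
#: order reused everywhere (columns of the effect map).  Hedonic and
#: self-referential descriptors are excluded by construction of the panel.
DEFAULT_QUALITIES: tuple[str, ...] = (
    "bitter",
    "sweet",
    "sour",
    "salty",
    "astringent",
    "aromatic",
    "herby_leafy",
    "stinging",
    "starchy",
    "musky",
    "soapy",
    "nutty",
    "woody",
    "mucilaginous",
    "balsamic",
    "burning_hot",
    "fresh_cooling",
    "smoky",
    "fruity",
    "earthy",
    "fatty",
    "resinous",
)

VALID_SCORES = frozenset({0, 1, 2, 3})

TRIAL_ID_COLUMNS = ("trial_id", "drug_id", "panellist_id", "days_since_collection")


@dataclass(frozen=True)
class QualityVocabulary:
    """Ordered vocabulary of chemosensory quality labels.

    Exactly 22 unique labels; the ordering is fixed and shared by every
    score vector, design matrix and effect map in the package.
    """

    qualities: tuple[str, ...] = DEFAULT_QUALITIES

    def __post_init__(self) -> None:
        if len(self.qualities) != 22:
            raise VocabularyError(
                f"expected 22 quality labels, got {len(self.qualities)}"
            )
        if len(set(self.qualities)) != len(self.qualities):
            raise VocabularyError("quality labels must be unique")

    def __iter__(self):
        return iter(self.qualities)

    def __len__(self) -> int:
        return 22

    def index(self, label: str) -> int:
        try:
            return self.qualities.index(label)
        except ValueError:
            raise VocabularyError(f"unknown quality label: {label!r}") from None


@dataclass
class UseMatrix:
    """Binary drug x use indicators plus the use -> category map.

    ``indicators`` is a DataFrame indexed by drug_id with one 0/1 column per
    use.  ``category_map`` is total over the columns and surjective onto at
    most 25 categories.
    """

    indicators: pd.DataFrame
    category_map: dict[str, str]

    def __post_init__(self) -> None:
        vals = self.indicators.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise RangeError("use matrix entries must be 0 or 1")
        missing = [u for u in self.indicators.columns if u not in self.category_map]
        if missing:
            raise MappingError(f"uses without a category: {missing}")

    @property
    def uses(self) -> list[str]:
        return list(self.indicators.columns)

    @property
    def categories(self) -> list[str]:
        return sorted(set(self.category_map[u] for u in self.uses))


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def add(self, severity: str, message: str, locator: str) -> None:
        self.errors.append((severity, message, locator))

    @property
    def ok(self) -> bool:
        """A dataset is loadable iff no error-severity entries exist."""
        return not any(sev == "error" for sev, _, _ in self.errors)

    def render(self) -> str:
        lines = ["validation report", "-----------------"]
        for key, val in self.counts.items():
            lines.append(f"{key}: {val}")
        if not self.errors:
            lines.append("no problems found")
        for sev, msg, loc in self.errors:
            lines.append(f"[{sev}] {msg} ({loc})")
        return "\n".join(lines)


@dataclass
class PanelDataset:
    """The three loaded tables plus the quality vocabulary."""

    drugs: pd.DataFrame
    trials: pd.DataFrame
    uses: UseMatrix
    vocab: QualityVocabulary = field(default_factory=QualityVocabulary)


def _read_delimited(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = ","
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def load_drug_table(path, sep: str | None = None) -> pd.DataFrame:
    """Load the drug table; one row per botanical drug.

    Required columns: ``drug_id``, ``taxon_name``, ``plant_part``.  The
    genus is parsed as the first whitespace-separated token of the binomial
    unless an explicit ``genus`` column is present; ``family`` and
    ``collection_date`` are optional.
    """
    df = _read_delimited(path, sep)
    for col in ("drug_id", "taxon_name", "plant_part"):
        if col not in df.columns:
            raise SchemaError(f"drug table missing required column {col!r}")
    dup = df["drug_id"][df["drug_id"].duplicated()]
    if not dup.empty:
        raise IntegrityError(f"duplicate drug_id values: {sorted(set(dup))}")
    pairs = df[["taxon_name", "plant_part"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        raise IntegrityError("duplicate (taxon_name, plant_part) pairs")
    if "genus" not in df.columns:
        df = df.assign(genus=df["taxon_name"].str.split().str[0])
    if "family" not in df.columns:
        df = df.assign(family=pd.NA)
    keep = ["drug_id", "taxon_name", "genus", "family", "plant_part"]
    if "collection_date" in df.columns:
        keep.append("collection_date")
    return df[keep].reset_index(drop=True)


def load_trials(
    path,
    vocab: QualityVocabulary | None = None,
    sep: str | None = None,
    layout: str = "wide",
) -> pd.DataFrame:
    """Load sensory trials; every trial carries a full 22-entry score vector.

    Wide layout: one column per quality; blank or absent cells are score 0.
    Long layout: columns ``quality`` and ``score``; unlisted qualities are 0.
    """
    vocab = vocab or QualityVocabulary()
    df = _read_delimited(path, sep)
    for col in ("trial_id", "drug_id", "panellist_id"):
        if col not in df.columns:
            raise SchemaError(f"trial table missing required column {col!r}")

    if layout == "long":
        if "quality" not in df.columns or "score" not in df.columns:
            raise SchemaError("long layout requires 'quality' and 'score' columns")
        unknown = set(df["quality"]) - set(vocab.qualities)
        if unknown:
            raise VocabularyError(f"unknown quality labels: {sorted(unknown)}")
        meta_cols = [c for c in TRIAL_ID_COLUMNS if c in df.columns]
        meta = df[meta_cols].drop_duplicates("trial_id").set_index("trial_id")
        wide = df.pivot_table(
            index="trial_id", columns="quality", values="score",
            aggfunc="first",
        )
        df = meta.join(wide).reset_index()

    extra = set(df.columns) - set(TRIAL_ID_COLUMNS) - set(vocab.qualities)
    if extra:
        raise VocabularyError(f"unknown quality labels: {sorted(extra)}")

    out = df[[c for c in TRIAL_ID_COLUMNS if c in df.columns]].copy()
    if "days_since_collection" not in out.columns:
        out["days_since_collection"] = 0
    out["days_since_collection"] = (
        pd.to_numeric(out["days_since_collection"]).fillna(0).astype(int)
    )
    for q in vocab.qualities:
        col = pd.to_numeric(df[q], errors="raise") if q in df.columns else 0
        out[q] = pd.Series(col, index=df.index).fillna(0).astype(int)
        bad = ~out[q].isin(list(VALID_SCORES))
        if bad.any():
            where = out.loc[bad, "trial_id"].iloc[0]
            raise RangeError(
                f"score outside {{0,1,2,3}} for quality {q!r} at trial {where}"
            )
    if out["trial_id"].duplicated().any():
        raise IntegrityError("duplicate trial_id values")
    return out.reset_index(drop=True)


def load_use_matrix(matrix_path, map_path, sep: str | None = None) -> UseMatrix:
    """Load the binary use matrix and the two-column use -> category map."""
    mat = _read_delimited(matrix_path, sep)
    if "drug_id" not in mat.columns:
        raise SchemaError("use matrix missing required column 'drug_id'")
    mat = mat.set_index("drug_id")
    try:
        mat = mat.apply(pd.to_numeric).astype(int)
    except ValueError as exc:
        raise RangeError(f"non-numeric cell in use matrix: {exc}") from exc
    if not mat.isin([0, 1]).all().all():
        raise RangeError("use matrix contains non-binary cells")

    cmap_df = _read_delimited(map_path, sep)
    for col in ("use_id", "category_id"):
        if col not in cmap_df.columns:
            raise SchemaError(f"category map missing required column {col!r}")
    category_map = dict(zip(cmap_df["use_id"], cmap_df["category_id"]))
    missing = [u for u in mat.columns if u not in category_map]
    if missing:
        raise MappingError(f"category map missing uses: {missing}")
    return UseMatrix(indicators=mat, category_map=category_map)


def validate_dataset(
    drugs: pd.DataFrame,
    trials: pd.DataFrame,
    uses: UseMatrix,
    vocab: QualityVocabulary | None = None,
) -> ValidationReport:
    """Cross-reference the three tables and tally dataset-level counts.

    ``counts.perception_reports`` is the number of non-zero (trial, quality)
    scores, which by definition equals the sum of per-trial complexity.
    """
    vocab = vocab or QualityVocabulary()
    report = ValidationReport()
    drug_ids = set(drugs["drug_id"])

    for _, row in trials.iterrows():
        if row["drug_id"] not in drug_ids:
            report.add(
                "error",
                f"trial references unknown drug {row['drug_id']!r}",
                f"trial_id={row['trial_id']}",
            )
    for drug_id in drug_ids - set(uses.indicators.index):
        report.add("error", "drug has no use-matrix row", f"drug_id={drug_id}")
    no_trials = drug_ids - set(trials["drug_id"])
    if no_trials:
        report.add(
            "warning",
            f"{len(no_trials)} drugs have no sensory trials",
            "drug table",
        )
    if len(trials) == 0:
        report.add("warning", "trial table is empty", "trial table")

    score_block = trials[list(vocab.qualities)] if len(trials) else pd.DataFrame()
    report.counts = {
        "drugs": len(drugs),
        "trials": len(trials),
        "panellists": trials["panellist_id"].nunique() if len(trials) else 0,
        "perception_reports": int((score_block > 0).to_numpy().sum())
        if len(trials)
        else 0,
    }
    return report


def write_drug_table(drugs: pd.DataFrame, path, sep: str = ",") -> None:
    drugs.to_csv(path, sep=sep, index=False)


def write_trials(trials: pd.DataFrame, path, sep: str = ",") -> None:
    trials.to_csv(path, sep=sep, index=False)


def write_use_matrix(uses: UseMatrix, matrix_path, map_path, sep: str = ",") -> None:
    uses.indicators.reset_index().to_csv(matrix_path, sep=sep, index=False)
    pd.DataFrame(
        {"use_id": list(uses.category_map), "category_id": list(uses.category_map.values())}
    ).to_csv(map_path, sep=sep, index=False)
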