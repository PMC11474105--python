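"""SAbDab-style dataset curation: deterministic, auditable filters and
leakage-safe train/validation/test splitting.

The pipeline mirrors published antibody-structure curation practice: drop
nanobodies, low-resolution structures, VH/VL orientation outliers (>3.5
standard deviations on any of the six ABangle summary statistics, computed
once on the pre-filter set), ultra-long CDRH3 loops (>30 residues), and
over-represented species (>15 occurrences, literal reading — see
``SpeciesMode``).  Validation structures must be human, better than 2.5 A
resolution and satisfy the CDRH3-length rule; the legacy test set is kept as
a subset of the test split; and any training entry sharing any CDR sequence
with an evaluation entry is removed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CurationEntry",
    "CurationConfig",
    "FilterReport",
    "SpeciesMode",
    "filter_resolution",
    "filter_nanobody",
    "filter_orientation_outliers",
    "filter_cdrh3_length",
    "filter_species_frequency",
    "select_validation_test",
    "dedup_train_against_eval",
    "run_curation",
    "read_entries_csv",
    "write_entries_csv",
]

CDR_KEYS = ("cdrh1", "cdrh2", "cdrh3", "cdrl1", "cdrl2", "cdrl3")


@dataclass
class CurationEntry:
    """One SAbDab-like record."""

    entry_id: str
    species: str
    resolution: float | None
    has_light_chain: bool
    orientation_stats: tuple[float, ...]
    heavy_seq: str = ""
    light_seq: str = ""
    cdr_seqs: dict[str, str] = field(default_factory=dict)
    human_annotated: bool = False

    def __post_init__(self):
        if len(self.orientation_stats) != 6:
            raise ValueError(
                f"{self.entry_id}: need exactly 6 orientation statistics"
            )
        self.orientation_stats = tuple(float(x) for x in self.orientation_stats)
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"{self.entry_id}: resolution must be positive")
        self.cdr_seqs = {k: (self.cdr_seqs.get(k, "") or "").upper() for k in CDR_KEYS}

    @property
    def cdrh3_length(self) -> int:
        return len(self.cdr_seqs["cdrh3"])


class SpeciesMode(str, Enum):
    """Reading of the species-frequency rule.

    ``literal``: remove species occurring more than the threshold (the rule
    as printed).  ``rare``: remove species occurring fewer than threshold
    times (the reading suggested by the outlier-removal motivation).
    """

    LITERAL = "literal"
    RARE = "rare"


class Cdrh3RuleMode(str, Enum):
    """Direction of the validation CDRH3-length rule (``long`` = > threshold,
    as printed; ``short`` = <= threshold)."""

    LONG = "long"
    SHORT = "short"


@dataclass
class CurationConfig:
    max_resolution: float = 3.5
    orientation_n_sd: float = 3.5
    max_cdrh3_length: int = 30
    species_threshold: int = 15
    species_mode: SpeciesMode = SpeciesMode.LITERAL
    n_validation: int = 150
    n_test: int = 100
    validation_max_resolution: float = 2.5
    validation_cdrh3_threshold: int = 22
    validation_cdrh3_mode: Cdrh3RuleMode = Cdrh3RuleMode.LONG
    legacy_test_ids: tuple[str, ...] = ()
    seed: int = 0


@dataclass
class FilterReport:
    """Audit trail: per-stage input/removed/retained counts and the ordered
    list of (entry_id, stage) removals."""

    stages: list[dict] = field(default_factory=list)
    removals: list[tuple[str, str]] = field(default_factory=list)
    seed: int | None = None

    def record(self, name: str, before: list, removed: list) -> None:
        self.stages.append(
            {
                "stage": name,
                "input": len(before),
                "removed": len(removed),
                "retained": len(before) - len(removed),
            }
        )
        self.removals.extend((e.entry_id, name) for e in removed)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"seed": self.seed, "stages": self.stages,
                 "removals": self.removals},
                indent=2,
            )
        )


def _split(entries, keep_fn):
    kept, removed = [], []
    for e in entries:
        (kept if keep_fn(e) else removed).append(e)
    return kept, removed


def filter_resolution(
    entries: list[CurationEntry],
    max_res: float = 3.5,
    report: FilterReport | None = None,
) -> list[CurationEntry]:
    """Keep entries with resolution <= max_res ('above' reads strictly);
    entries with missing resolution are removed, not silently kept."""
    kept, removed = _split(
        entries, lambda e: e.resolution is not None and e.resolution <= max_res
    )
    if report is not None:
        report.record("resolution", entries, removed)
    return kept


def filter_nanobody(
    entries: list[CurationEntry], report: FilterReport | None = None
) -> list[CurationEntry]:
    """Keep only paired entries (a light chain present)."""
    kept, removed = _split(entries, lambda e: e.has_light_chain)
    if report is not None:
        report.record("nanobody", entries, removed)
    return kept


def filter_orientation_outliers(
    entries: list[CurationEntry],
    n_sd: float = 3.5,
    report: FilterReport | None = None,
) -> list[CurationEntry]:
    """Remove entries >n_sd standard deviations from the mean in any of the
    six orientation statistics.

    Means and SDs are computed once on the input set (no iteration).  A
    statistic with zero spread is excluded from the test.
    """
    if not entries:
        return []
    stats = np.array([e.orientation_stats for e in entries])
    mean = stats.mean(axis=0)
    sd = stats.std(axis=0)
    usable = sd > 0
    z = np.zeros_like(stats)
    z[:, usable] = np.abs(stats[:, usable] - mean[usable]) / sd[usable]
    outlier = (z > n_sd).any(axis=1)
    kept = [e for e, o in zip(entries, outlier) if not o]
    removed = [e for e, o in zip(entries, outlier) if o]
    if report is not None:
        report.record("orientation", entries, removed)
    return kept


def filter_cdrh3_length(
    entries: list[CurationEntry],
    max_len: int = 30,
    report: FilterReport | None = None,
) -> list[CurationEntry]:
    """Remove ultra-long CDRH3 loops ('over 30 residues' reads strictly)."""
    kept, removed = _split(entries, lambda e: e.cdrh3_length <= max_len)
    if report is not None:
        report.record("cdrh3_length", entries, removed)
    return kept


def filter_species_frequency(
    entries: list[CurationEntry],
    threshold: int = 15,
    mode: SpeciesMode = SpeciesMode.LITERAL,
    report: FilterReport | None = None,
) -> list[CurationEntry]:
    """Species-frequency filter; missing species count as singleton species.

    ``literal`` removes species with more than ``threshold`` occurrences;
    ``rare`` removes species with fewer than ``threshold`` occurrences.
    """
    def label(e):
        return e.species.strip().lower() if e.species else f"__missing_{e.entry_id}"

    counts = Counter(label(e) for e in entries)
    if mode == SpeciesMode.LITERAL:
        keep = lambda e: counts[label(e)] <= threshold  # noqa: E731
    else:
        keep = lambda e: counts[label(e)] >= threshold  # noqa: E731
    kept, removed = _split(entries, keep)
    if report is not None:
        report.record(f"species[{mode.value}]", entries, removed)
    return kept


class SelectionShortfallError(RuntimeError):
    pass


def select_validation_test(
    entries: list[CurationEntry],
    config: CurationConfig,
) -> tuple[list[CurationEntry], list[CurationEntry], list[CurationEntry]]:
    """Draw validation and test splits; the remainder is the training pool.

    Validation candidates must be human-annotated, have resolution strictly
    below ``validation_max_resolution`` and satisfy the CDRH3-length rule.
    The test split is the reserved legacy ids (always kept) plus additional
    human entries up to ``n_test``.  Sampling is seeded and deterministic.
    """
    rng = np.random.default_rng(config.seed)
    by_id = {e.entry_id: e for e in entries}
    legacy = [by_id[i] for i in config.legacy_test_ids if i in by_id]
    legacy_ids = {e.entry_id for e in legacy}

    if config.validation_cdrh3_mode == Cdrh3RuleMode.LONG:
        cdrh3_ok = lambda e: e.cdrh3_length > config.validation_cdrh3_threshold  # noqa: E731
    else:
        cdrh3_ok = lambda e: e.cdrh3_length <= config.validation_cdrh3_threshold  # noqa: E731

    val_pool = [
        e
        for e in entries
        if e.entry_id not in legacy_ids
        and e.human_annotated
        and e.resolution is not None
        and e.resolution < config.validation_max_resolution
        and cdrh3_ok(e)
    ]
    if len(val_pool) < config.n_validation:
        raise SelectionShortfallError(
            f"validation pool has {len(val_pool)} eligible entries, "
            f"need {config.n_validation}"
        )
    val_idx = rng.choice(len(val_pool), size=config.n_validation, replace=False)
    val = [val_pool[i] for i in sorted(val_idx)]
    val_ids = {e.entry_id for e in val}

    n_extra = config.n_test - len(legacy)
    test_pool = [
        e
        for e in entries
        if e.entry_id not in legacy_ids
        and e.entry_id not in val_ids
        and e.human_annotated
    ]
    if n_extra < 0 or len(test_pool) < n_extra:
        raise SelectionShortfallError(
            f"test pool has {len(test_pool)} eligible entries, need {n_extra}"
        )
    extra_idx = rng.choice(len(test_pool), size=n_extra, replace=False)
    test = legacy + [test_pool[i] for i in sorted(extra_idx)]
    test_ids = {e.entry_id for e in test}
    rest = [
        e for e in entries if e.entry_id not in val_ids and e.entry_id not in test_ids
    ]
    return val, test, rest


def dedup_train_against_eval(
    train: list[CurationEntry],
    eval_sets: list[list[CurationEntry]],
    report: FilterReport | None = None,
) -> list[CurationEntry]:
    """Remove training entries sharing any same-region CDR sequence (exact,
    case-normalised) with any evaluation entry."""
    eval_cdrs: dict[str, set[str]] = {k: set() for k in CDR_KEYS}
    for entries in eval_sets:
        for e in entries:
            for k in CDR_KEYS:
                if e.cdr_seqs[k]:
                    eval_cdrs[k].add(e.cdr_seqs[k])

    def clean(e: CurationEntry) -> bool:
        return not any(
            e.cdr_seqs[k] and e.cdr_seqs[k] in eval_cdrs[k] for k in CDR_KEYS
        )

    kept, removed = _split(train, clean)
    if report is not None:
        report.record("dedup", train, removed)
    return kept


def run_curation(
    entries: list[CurationEntry], config: CurationConfig | None = None
) -> tuple[list[CurationEntry], list[CurationEntry], list[CurationEntry], FilterReport]:
    """The full pipeline in the published order: nanobody and resolution
    filters, orientation-outlier removal (statistics on the post-filter
    set), CDRH3-length filter, species filter, split selection, and
    train-vs-eval CDR deduplication."""
    config = config or CurationConfig()
    report = FilterReport(seed=config.seed)
    pool = filter_nanobody(entries, report=report)
    pool = filter_resolution(pool, config.max_resolution, report=report)
    pool = filter_orientation_outliers(pool, config.orientation_n_sd, report=report)
    pool = filter_cdrh3_length(pool, config.max_cdrh3_length, report=report)
    pool = filter_species_frequency(
        pool, config.species_threshold, config.species_mode, report=report
    )
    val, test, train = select_validation_test(pool, config)
    report.stages.append(
        {"stage": "split", "input": len(pool), "removed": 0, "retained": len(pool),
         "validation": len(val), "test": len(test), "train_pool": len(train)}
    )
    train = dedup_train_against_eval(train, [val, test], report=report)
    return train, val, test, report


# -- tabular IO -----------------------------------------------------------

_COLUMNS = [
    "entry_id", "species", "resolution", "has_light_chain",
    "ab1", "ab2", "ab3", "ab4", "ab5", "ab6",
    "heavy_seq", "light_seq",
    *CDR_KEYS,
    "human_annotated",
]


def write_entries_csv(entries: list[CurationEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        row = {
            "entry_id": e.entry_id,
            "species": e.species,
            "resolution": e.resolution,
            "has_light_chain": e.has_light_chain,
            "heavy_seq": e.heavy_seq,
            "light_seq": e.light_seq,
            "human_annotated": e.human_annotated,
        }
        row.update({f"ab{i+1}": v for i, v in enumerate(e.orientation_stats)})
        row.update(e.cdr_seqs)
        rows.append(row)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_entries_csv(path: str | Path) -> list[CurationEntry]:
    df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        entries.append(
            CurationEntry(
                entry_id=str(row["entry_id"]),
                species="" if pd.isna(row["species"]) else str(row["species"]),
                resolution=None if pd.isna(row["resolution"]) else float(row["resolution"]),
                has_light_chain=bool(row["has_light_chain"]),
                orientation_stats=tuple(float(row[f"ab{i+1}"]) for i in range(6)),
                heavy_seq="" if pd.isna(row.get("heavy_seq")) else str(row["heavy_seq"]),
                light_seq="" if pd.isna(row.get("light_seq")) else str(row["light_seq"]),
                cdr_seqs={
                    k: "" if pd.isna(row.get(k)) else str(row[k]) for k in CDR_KEYS
                },
                human_annotated=bool(row["human_annotated"]),
            )
        )
    return entries
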