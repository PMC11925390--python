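"""Activity-record curation and balanced classification-set construction.

Mirrors the standard cleanup applied to public bioactivity databases before
compound classification: drop oversized molecules, questionable activity
comments, non-standard measurement types, inexact relations, out-of-window
potencies, indirect assays and low-confidence records, then pair the
surviving actives with an equal number of randomly drawn decoys.
Potencies are handled in nM throughout; converting molar inputs is the
reader's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ACTIVE, INACTIVE, FingerprintDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityRecord",
    "CurationConfig",
    "curate",
    "build_classification_dataset",
    "read_activity_records",
    "write_activity_records",
    "write_audit",
]

DEFAULT_EXCLUDED_COMMENTS = frozenset(
    {
        "inactive",
        "inconclusive",
        "not active",
        "potential author error",
        "potential transcription error",
    }
)

#: audit keys in the order filters are applied; a rejected record is counted
#: under the FIRST failing filter only
FILTER_ORDER = (
    "malformed",
    "mass",
    "comment",
    "type",
    "relation",
    "potency_range",
    "relationship_type",
    "confidence",
)


@dataclass
class ActivityRecord:
    """One compound-target activity measurement.

    ``standard_value`` is the potency in nM. Fields may be ``None`` for
    malformed records, which curation rejects and counts separately.
    """

    compound_id: str
    molecular_mass: float | None = None
    activity_comment: str = ""
    activity_type: str | None = None
    relation: str | None = None
    standard_value: float | None = None
    target_relationship_type: str | None = None
    confidence_score: int | None = None
    target_id: str = ""


@dataclass
class CurationConfig:
    """Filter thresholds. Defaults reproduce the curation window used for
    high-confidence compound activity classes: mass <= 1000 Da, exact ("=")
    Ki/Kd/IC50 measurements between 10 pM (0.01 nM) and 10 uM (10000 nM),
    direct single-protein assays ("D") at the maximum confidence score of 9,
    and more than ``min_class_size`` qualifying actives per target."""

    max_mass: float = 1000.0
    excluded_comments: frozenset[str] = DEFAULT_EXCLUDED_COMMENTS
    allowed_types: frozenset[str] = frozenset({"Ki", "Kd", "IC50"})
    required_relation: str = "="
    potency_min: float = 0.01
    potency_max: float = 10000.0
    required_relationship_type: str = "D"
    required_confidence: int = 9
    min_class_size: int = 1000

    def __post_init__(self) -> None:
        if not self.potency_min < self.potency_max:
            raise ValueError("potency_min must be below potency_max")


def _first_failing_filter(rec: ActivityRecord, cfg: CurationConfig) -> str | None:
    """Name of the first filter the record fails, or None if it survives."""
    required = (
        rec.molecular_mass,
        rec.activity_type,
        rec.relation,
        rec.standard_value,
        rec.target_relationship_type,
        rec.confidence_score,
    )
    if any(v is None for v in required):
        return "malformed"
    if rec.molecular_mass > cfg.max_mass:
        return "mass"
    if rec.activity_comment in cfg.excluded_comments:
        return "comment"
    if rec.activity_type not in cfg.allowed_types:
        return "type"
    if rec.relation != cfg.required_relation:
        return "relation"
    if not cfg.potency_min <= rec.standard_value <= cfg.potency_max:
        return "potency_range"
    if rec.target_relationship_type != cfg.required_relationship_type:
        return "relationship_type"
    if rec.confidence_score != cfg.required_confidence:
        return "confidence"
    return None


def curate(
    records: list[ActivityRecord],
    config: CurationConfig | None = None,
    drop_duplicates: bool = True,
    enforce_min_class_size: bool = False,
) -> tuple[list[ActivityRecord], dict[str, int]]:
    """Apply all record filters; return survivors and a per-filter audit.

    A record survives iff it passes every filter. The audit maps each filter
    name (in application order) to the number of records it rejected; a
    record counts only towards the first filter it fails, so the survivor
    set is order-independent but the audit attribution is not.

    Duplicate compound-target measurements keep the first occurrence (an
    assumption; logged). With ``enforce_min_class_size`` targets whose
    surviving active count is <= ``min_class_size`` are dropped with a
    warning.
    """
    if not records:
        raise ValueError("records must be non-empty")
    cfg = config or CurationConfig()
    audit = {name: 0 for name in FILTER_ORDER}
    survivors: list[ActivityRecord] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for rec in records:
        failing = _first_failing_filter(rec, cfg)
        if failing is not None:
            audit[failing] += 1
            continue
        key = (rec.compound_id, rec.target_id)
        if drop_duplicates and key in seen:
            n_dup += 1
            continue
        seen.add(key)
        survivors.append(rec)
    if n_dup:
        logger.info("dropped %d duplicate compound-target measurements", n_dup)
    if enforce_min_class_size:
        counts: dict[str, int] = {}
        for rec in survivors:
            counts[rec.target_id] = counts.get(rec.target_id, 0) + 1
        small = {t for t, c in counts.items() if c <= cfg.min_class_size}
        if small:
            logger.warning(
                "dropping %d target classes below min_class_size=%d: %s",
                len(small), cfg.min_class_size, sorted(small),
            )
            survivors = [r for r in survivors if r.target_id not in small]
    return survivors, audit


def build_classification_dataset(
    actives: FingerprintDataset,
    decoy_pool: FingerprintDataset,
    seed: int,
) -> FingerprintDataset:
    """Balance actives with a seeded uniform random decoy sample.

    Returns the actives (labelled active) followed by ``len(actives)``
    decoys drawn without replacement from ``decoy_pool`` (labelled
    inactive). The pool must be disjoint from the actives by compound id
    and at least as large.
    """
    n = actives.n_instances
    if decoy_pool.n_instances < n:
        raise ValueError(
            f"decoy pool of {decoy_pool.n_instances} cannot balance {n} actives"
        )
    if actives.n_features != decoy_pool.n_features:
        raise ValueError("actives and decoy pool differ in feature count")
    overlap = set(actives.compound_ids) & set(decoy_pool.compound_ids)
    if overlap:
        raise ValueError(f"decoy pool overlaps actives: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(decoy_pool.n_instances, size=n, replace=False))
    decoys = decoy_pool.subset(pick)
    return FingerprintDataset(
        bits=np.vstack([actives.bits, decoys.bits]),
        labels=np.concatenate(
            [np.full(n, ACTIVE, dtype=np.int64), np.full(n, INACTIVE, dtype=np.int64)]
        ),
        compound_ids=list(actives.compound_ids) + list(decoys.compound_ids),
        feature_ids=actives.feature_ids,
        informative_ids=actives.informative_ids,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_COLUMNS = [
    "compound_id",
    "molecular_mass",
    "activity_comment",
    "activity_type",
    "relation",
    "standard_value",
    "target_relationship_type",
    "confidence_score",
    "target_id",
]


def write_activity_records(records: list[ActivityRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records], columns=_COLUMNS).to_csv(path, index=False)


def read_activity_records(path: str | Path) -> list[ActivityRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for key in ("molecular_mass", "standard_value"):
            if pd.isna(d[key]):
                d[key] = None
        for key in ("activity_type", "relation", "target_relationship_type"):
            if pd.isna(d[key]):
                d[key] = None
        d["confidence_score"] = None if pd.isna(d["confidence_score"]) else int(d["confidence_score"])
        d["activity_comment"] = "" if pd.isna(d["activity_comment"]) else str(d["activity_comment"])
        records.append(ActivityRecord(**d))
    return records


def write_audit(audit: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"filter": list(audit.keys()), "n_rejected": list(audit.values())}
    ).to_csv(path, index=False)
    for name, count in audit.items():
        logger.info("curation filter %-18s rejected %d", name, count)
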