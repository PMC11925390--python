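"""Seeded synthetic data: fingerprint datasets, toy cooperative games, activity records.

Every downstream stage of the package (curation, model training, attribution,
comparison statistics, remove-and-retrain) is testable on the outputs of this
module without any external download.  Fingerprint datasets emulate curated
compound classification sets: balanced active/inactive classes of sparse
binary vectors (folded ECFP-style bit vectors) with a planted subset of
class-discriminative bits whose identity is recorded as ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "FingerprintDataset",
    "ToyGame",
    "generate_fingerprint_dataset",
    "make_toy_game",
    "additive_game",
    "random_game",
    "generate_activity_records",
]

ACTIVE, INACTIVE = 1, 0
LABEL_NAMES = {ACTIVE: "active", INACTIVE: "inactive"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-signal fingerprint generator.

    Attributes
    ----------
    n_per_class : int
        Number of actives; the generator always produces the same number of
        inactives (balanced classes).
    n_features : int
        Fingerprint width. Desk-scale default is 256 bits; 2048 emulates the
        folded ECFP4 width used for real compound data.
    n_informative : int
        Number of planted class-discriminative bits.
    p_on_background : float
        Probability that a non-informative bit is set in any compound.
    p_on_active : float
        Probability that an informative bit is set in an active compound.
    p_on_inactive : float
        Probability that an informative bit is set in an inactive compound.
        Must not exceed ``p_on_active`` (the planted signal points towards
        the active class).
    label_noise : float
        Probability that a compound's label is flipped after bit generation;
        the bits stay tied to the pre-noise class.
    seed : int
        Seed for all randomness in the generator.
    """

    n_per_class: int = 100
    n_features: int = 256
    n_informative: int = 20
    p_on_background: float = 0.05
    p_on_active: float = 0.8
    p_on_inactive: float = 0.1
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        for name in ("p_on_background", "p_on_active", "p_on_inactive", "label_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")
        if self.p_on_active < self.p_on_inactive:
            raise ValueError(
                "p_on_active must be >= p_on_inactive (planted signal must "
                "point towards the active class)"
            )

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


@dataclass
class FingerprintDataset:
    """Binary instance x feature matrix with labels and identifiers.

    ``labels`` uses 1 for active (positive class) and 0 for inactive.
    ``informative_ids`` records the planted discriminative bits when the
    dataset was built by the generator, and is ``None`` for external data.
    """

    bits: np.ndarray
    labels: np.ndarray
    compound_ids: list[str]
    feature_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    informative_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-D matrix")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must contain only 0 and 1")
        if self.labels.shape != (self.bits.shape[0],):
            raise ValueError("labels must align with the rows of bits")
        if not np.isin(self.labels, (ACTIVE, INACTIVE)).all():
            raise ValueError("labels must be 0 (inactive) or 1 (active)")
        if len(self.compound_ids) != self.bits.shape[0]:
            raise ValueError("compound_ids must align with the rows of bits")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("compound_ids must be unique")
        if self.feature_ids is None:
            self.feature_ids = np.arange(self.bits.shape[1])
        self.feature_ids = np.asarray(self.feature_ids, dtype=np.int64)
        if self.feature_ids.shape != (self.bits.shape[1],):
            raise ValueError("feature_ids must align with the columns of bits")

    @property
    def n_instances(self) -> int:
        return self.bits.shape[0]

    @property
    def n_features(self) -> int:
        return self.bits.shape[1]

    def X(self) -> np.ndarray:
        """Feature matrix as float64, the dtype the classifiers consume."""
        return self.bits.astype(np.float64)

    # -- persistence ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.bits, columns=[f"bit_{i}" for i in self.feature_ids])
        df.insert(0, "label", [LABEL_NAMES[y] for y in self.labels])
        df.insert(0, "compound_id", self.compound_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write the wide one-row-per-compound CSV representation."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FingerprintDataset":
        df = pd.read_csv(path)
        bit_cols = [c for c in df.columns if c.startswith("bit_")]
        return cls(
            bits=df[bit_cols].to_numpy(),
            labels=(df["label"] == "active").astype(int).to_numpy(),
            compound_ids=df["compound_id"].astype(str).tolist(),
            feature_ids=np.array([int(c.split("_", 1)[1]) for c in bit_cols]),
        )

    def to_sparse_csv(self, path: str | Path) -> None:
        """Write the compact on-bit list format.

        One row per compound: ``compound_id,label,on_bits`` where ``on_bits``
        is a semicolon-separated list of set bit indices. ``n_features`` is
        kept in a header comment so all-zero trailing columns round-trip.
        """
        with open(path, "w") as fh:
            fh.write(f"# n_features={self.n_features}\n")
            fh.write("compound_id,label,on_bits\n")
            for cid, y, row in zip(self.compound_ids, self.labels, self.bits):
                on = ";".join(str(self.feature_ids[j]) for j in np.flatnonzero(row))
                fh.write(f"{cid},{LABEL_NAMES[y]},{on}\n")

    @classmethod
    def from_sparse_csv(cls, path: str | Path) -> "FingerprintDataset":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# n_features="):
                raise ValueError("missing n_features header in sparse CSV")
            n_features = int(header.split("=", 1)[1])
            fh.readline()  # column header
            cids, labels, rows = [], [], []
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                cid, label, on = line.split(",", 2)
                cids.append(cid)
                labels.append(ACTIVE if label == "active" else INACTIVE)
                row = np.zeros(n_features, dtype=np.uint8)
                if on:
                    row[[int(i) for i in on.split(";")]] = 1
                rows.append(row)
        return cls(bits=np.array(rows), labels=np.array(labels), compound_ids=cids)

    def subset(self, idx: Sequence[int]) -> "FingerprintDataset":
        idx = np.asarray(idx)
        return FingerprintDataset(
            bits=self.bits[idx],
            labels=self.labels[idx],
            compound_ids=[self.compound_ids[i] for i in idx],
            feature_ids=self.feature_ids,
            informative_ids=self.informative_ids,
        )


def generate_fingerprint_dataset(config: SyntheticConfig) -> FingerprintDataset:
    """Generate a balanced, planted-signal binary fingerprint dataset.

    Informative bit positions are drawn uniformly without replacement and
    recorded in ``informative_ids``.  Informative bits fire at the
    class-specific rates ``p_on_active`` / ``p_on_inactive``; all remaining
    bits fire at ``p_on_background`` regardless of class.  Label noise, if
    any, flips labels after bit generation so the planted bits remain tied
    to the pre-noise class.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_per_class, config.n_features
    informative = np.sort(rng.choice(m, size=config.n_informative, replace=False))

    labels = np.concatenate([np.ones(n, dtype=np.int64), np.zeros(n, dtype=np.int64)])
    bits = (rng.random((2 * n, m)) < config.p_on_background).astype(np.uint8)
    p_info = np.where(labels[:, None] == ACTIVE, config.p_on_active, config.p_on_inactive)
    bits[:, informative] = (
        rng.random((2 * n, config.n_informative)) < p_info
    ).astype(np.uint8)

    if config.label_noise > 0:
        flip = rng.random(2 * n) < config.label_noise
        labels = np.where(flip, 1 - labels, labels)

    compound_ids = [f"CPD{i:06d}" for i in range(2 * n)]
    return FingerprintDataset(
        bits=bits,
        labels=labels,
        compound_ids=compound_ids,
        feature_ids=np.arange(m),
        informative_ids=[int(i) for i in informative],
    )


# ---------------------------------------------------------------------------
# Toy cooperative games
# ---------------------------------------------------------------------------


class ToyGame:
    """Explicit cooperative game: a payoff for every coalition of players.

    Serves as the exact-arithmetic oracle fixture for the attribution module.
    Exposes the same vectorized ``values`` interface as the marginal value
    functions built from trained models, so the Shapley enumerator and
    KernelSHAP accept either interchangeably.
    """

    MAX_PLAYERS = 16

    def __init__(self, n_players: int, values: Mapping[frozenset | tuple, float]):
        if not 1 <= n_players <= self.MAX_PLAYERS:
            raise ValueError(f"n_players must be in 1..{self.MAX_PLAYERS}")
        self.n_players = int(n_players)
        table = np.empty(2**n_players, dtype=np.float64)
        seen = np.zeros(2**n_players, dtype=bool)
        for coalition, payoff in values.items():
            players = frozenset(int(p) for p in coalition)
            if not players <= set(range(n_players)):
                raise ValueError(f"coalition {sorted(players)} has unknown players")
            mask = sum(1 << p for p in players)
            table[mask] = float(payoff)
            seen[mask] = True
        if not seen.all():
            missing = int(np.flatnonzero(~seen)[0])
            players = [p for p in range(n_players) if missing >> p & 1]
            raise ValueError(f"missing coalition value for {players}")
        self._table = table

    # the attribution module's value-function protocol
    @property
    def n_features(self) -> int:
        return self.n_players

    def value(self, coalition: Iterable[int]) -> float:
        mask = 0
        for p in coalition:
            mask |= 1 << int(p)
        return float(self._table[mask])

    def values(self, Z: np.ndarray) -> np.ndarray:
        """Payoffs for a (k, n_players) boolean coalition-membership matrix."""
        Z = np.asarray(Z, dtype=bool)
        masks = Z @ (1 << np.arange(self.n_players))
        return self._table[masks]


def make_toy_game(spec: Mapping[frozenset | tuple, float]) -> ToyGame:
    """Build a :class:`ToyGame` from an explicit coalition -> payoff table.

    The table must cover all ``2**n`` coalitions including the empty one;
    the number of players is inferred from the largest player index seen.
    """
    players: set[int] = set()
    for coalition in spec:
        players |= {int(p) for p in coalition}
    n = max(players) + 1 if players else 1
    if len(spec) != 2**n:
        raise ValueError(
            f"expected {2**n} coalition values for {n} players, got {len(spec)}"
        )
    return ToyGame(n, spec)


def additive_game(weights: Sequence[float]) -> ToyGame:
    """Game with v(S) = sum of per-player weights in S; Shapley values equal the weights."""
    w = np.asarray(weights, dtype=float)
    n = len(w)
    spec = {}
    for r in range(n + 1):
        for S in itertools.combinations(range(n), r):
            spec[frozenset(S)] = float(w[list(S)].sum())
    return ToyGame(n, spec)


def random_game(n_players: int, seed: int, scale: float = 1.0) -> ToyGame:
    """Random game with i.i.d. normal payoffs and v(empty)=0."""
    rng = np.random.default_rng(seed)
    game = ToyGame.__new__(ToyGame)
    game.n_players = int(n_players)
    table = rng.normal(scale=scale, size=2**n_players)
    table[0] = 0.0
    game._table = table
    return game


# ---------------------------------------------------------------------------
# Activity-record fixtures for the curation stage
# ---------------------------------------------------------------------------


def generate_activity_records(seed: int, n: int, all_mass: float | None = None):
    """Generate toy activity records spanning pass and fail cases of every curation filter.

    Returns ``(records, expected_pass)`` where ``expected_pass[i]`` is the
    ground-truth survival flag for ``records[i]`` under the default
    :class:`~shapcompare.curation.CurationConfig`, computed here by explicit
    per-field checks that are independent of the curation module.

    ``all_mass`` forces every record's molecular mass to a single value
    (useful for single-filter saturation fixtures).
    """
    from .curation import ActivityRecord, CurationConfig

    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    cfg = CurationConfig()
    comments = ["", "active", "inactive", "inconclusive", "not active",
                "potential author error", "potential transcription error"]
    types = ["Ki", "Kd", "IC50", "other"]
    relations = ["=", ">", "<", ">="]
    rel_types = ["D", "H", "U"]

    records, expected = [], []
    for i in range(n):
        mass = float(all_mass) if all_mass is not None else float(rng.uniform(150, 1400))
        comment = str(rng.choice(comments))
        atype = str(rng.choice(types))
        relation = str(rng.choice(relations, p=[0.7, 0.1, 0.1, 0.1]))
        # log-uniform potency spanning both sides of the [10 pM, 10 uM] window
        value = float(10 ** rng.uniform(-3.5, 5.5))
        rel_type = str(rng.choice(rel_types, p=[0.8, 0.1, 0.1]))
        conf = int(rng.choice([9, 9, 9, 8, 7, 0]))
        rec = ActivityRecord(
            compound_id=f"REC{i:05d}",
            molecular_mass=mass,
            activity_comment=comment,
            activity_type=atype,
            relation=relation,
            standard_value=value,
            target_relationship_type=rel_type,
            confidence_score=conf,
            target_id="T1",
        )
        ok = (
            mass <= 1000.0
            and comment not in {"inactive", "inconclusive", "not active",
                                "potential author error", "potential transcription error"}
            and atype in {"Ki", "Kd", "IC50"}
            and relation == "="
            and 0.01 <= value <= 10000.0
            and rel_type == "D"
            and conf == 9
        )
        records.append(rec)
        expected.append(ok)
    assert cfg.max_mass == 1000.0  # fixture truth table mirrors the defaults
    return records, expected
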