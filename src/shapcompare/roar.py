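"""Remove-and-retrain (ROAR) validation of global feature rankings.

A meaningful importance ranking should let a model tolerate removal of its
least important features: performance stays near baseline until the highly
ranked features start to go, whereas removing randomly chosen features of
equal number degrades performance much sooner.  Removal deletes columns
from the representation (models are retrained on shorter vectors), it does
not zero-mask them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import AttributionMatrix
from .models import ModelSpec, TrialSplit, evaluate, fit_with_params
from .stats import normalize_rows

logger = logging.getLogger(__name__)

__all__ = [
    "FULL_SCHEDULE_2048",
    "DESK_SCHEDULE_256",
    "default_schedule",
    "global_feature_ranking",
    "RoarResult",
    "roar_run",
]

#: removal schedule for full-width 2048-bit fingerprints
FULL_SCHEDULE_2048 = (100, 1000, 1500, 1700, 1800, 1900, 1950, 2000, 2023, 2038, 2043)

#: desk-scale schedule for 256 features, mirroring the dense-near-full-removal
#: geometry of the 2048-bit schedule
DESK_SCHEDULE_256 = (25, 128, 192, 224, 240, 248, 251, 253, 254, 255)


def default_schedule(n_features: int) -> tuple[int, ...]:
    """Removal schedule for a feature count; known widths use the fixed
    schedules above, others get a proportional rescale of the 2048 one."""
    if n_features == 2048:
        return FULL_SCHEDULE_2048
    if n_features == 256:
        return DESK_SCHEDULE_256
    scaled = sorted(
        {
            min(n_features - 1, max(1, round(s * n_features / 2048)))
            for s in FULL_SCHEDULE_2048
        }
    )
    return tuple(scaled)


def global_feature_ranking(attr: AttributionMatrix | np.ndarray) -> np.ndarray:
    """Feature order by increasing global importance (least important first).

    Rows are normalized by their absolute sums; each feature's importance is
    the absolute sum of its normalized values across instances, ranked
    ascending with ties broken by lower feature id.
    """
    values = attr.values if isinstance(attr, AttributionMatrix) else np.asarray(attr)
    if values.size == 0:
        raise ValueError("empty attribution matrix")
    norm, valid = normalize_rows(values)
    if not valid.any():
        raise ValueError("all attribution rows are zero; ranking undefined")
    scores = np.abs(norm[valid]).sum(axis=0)
    return np.argsort(scores, kind="stable")  # stable: ties fall to lower id


@dataclass
class RoarResult:
    """MCC trajectories under informed and random feature removal."""

    schedule: tuple[int, ...]
    informed_mcc: np.ndarray          # (n_steps,)
    random_mcc: np.ndarray            # (n_controls, n_steps)
    control_seeds: list[int]
    method: str = ""
    model_label: str = ""

    def __post_init__(self) -> None:
        sched = np.asarray(self.schedule)
        if (np.diff(sched) <= 0).any():
            raise ValueError("schedule must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for step, (n_removed, mcc) in enumerate(zip(self.schedule, self.informed_mcc)):
            rows.append({"step": step, "n_removed": n_removed, "condition": "informed",
                         "seed": -1, "mcc": float(mcc),
                         "method": self.method, "model": self.model_label})
        for ci, seed in enumerate(self.control_seeds):
            for step, n_removed in enumerate(self.schedule):
                rows.append({"step": step, "n_removed": n_removed, "condition": "random",
                             "seed": seed, "mcc": float(self.random_mcc[ci, step]),
                             "method": self.method, "model": self.model_label})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _retrain_mcc(X, y, split, spec, params, keep, seed) -> float:
    model = fit_with_params(X[np.ix_(split.train_ids, keep)], y[split.train_ids],
                            spec, params, seed, split.trial_index)
    return evaluate(model, X[np.ix_(split.test_ids, keep)], y[split.test_ids]).mcc


def roar_run(
    X: np.ndarray,
    y: np.ndarray,
    split: TrialSplit,
    spec: ModelSpec,
    params: dict,
    ranking: np.ndarray,
    schedule: tuple[int, ...] | None = None,
    n_random_controls: int = 5,
    seed: int = 0,
    method: str = "",
    model_label: str = "",
) -> RoarResult:
    """Retrain along a removal schedule, informed vs random.

    At each step the first ``n`` features of ``ranking`` (least important
    first) are deleted, the model is retrained with the hyperparameters
    selected on the full representation (``params``) and MCC on the test
    split is recorded; the control repeats with seeded uniform random
    removals of equal size, one trajectory per control seed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n_features = X.shape[1]
    ranking = np.asarray(ranking)
    if sorted(ranking.tolist()) != list(range(n_features)):
        raise ValueError("ranking must be a permutation of the feature indices")
    if schedule is None:
        schedule = default_schedule(n_features)
    schedule = tuple(int(s) for s in schedule)
    if any(s >= n_features for s in schedule):
        raise ValueError(
            "schedule entries must be below the feature count "
            "(at least one feature must remain)"
        )

    informed = np.empty(len(schedule))
    for k, n_removed in enumerate(schedule):
        keep = np.sort(ranking[n_removed:])
        informed[k] = _retrain_mcc(X, y, split, spec, params, keep, seed)
        logger.info("informed removal %d/%d features: MCC=%.3f",
                    n_removed, n_features, informed[k])

    control_seeds = [
        int(s) for s in np.random.SeedSequence(seed).generate_state(n_random_controls)
        % (2**31)
    ]
    random_mcc = np.empty((n_random_controls, len(schedule)))
    for ci, cseed in enumerate(control_seeds):
        rng = np.random.default_rng(cseed)
        for k, n_removed in enumerate(schedule):
            drop = rng.choice(n_features, size=n_removed, replace=False)
            keep = np.setdiff1d(np.arange(n_features), drop)
            random_mcc[ci, k] = _retrain_mcc(X, y, split, spec, params, keep, cseed)
    return RoarResult(
        schedule=schedule, informed_mcc=informed, random_mcc=random_mcc,
        control_seeds=control_seeds, method=method, model_label=model_label,
    )
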