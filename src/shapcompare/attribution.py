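"""Shapley-value feature attribution: exact coalition enumeration and KernelSHAP.

The Shapley value of feature p for the prediction f(x) of one instance is its
mean marginal contribution over all coalitions S of the remaining features,

    phi_p = sum_{S subseteq T\\{p}} |S|! (|T|-|S|-1)! / |T|!  [v(S u {p}) - v(S)],

where the coalition value v(S) is the marginal expectation of the model
output: features in S take the instance's values, the rest are drawn from a
training-data background sample and the model output is averaged.  Exact
enumeration over all 2^M coalitions is feasible for small M and serves as
the ground truth here; KernelSHAP recovers the same values as the solution
of a weighted least-squares problem over (sampled or enumerated) coalitions
with the Shapley kernel weights, constrained so the attributions sum to
f(x) - v(empty) (efficiency).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EXACT_ENUMERATION_CAP",
    "SingularDesignError",
    "MarginalValueFunction",
    "ShapleyResult",
    "AttributionMatrix",
    "marginal_value_function",
    "sample_background",
    "exact_shapley",
    "kernel_shap_game",
    "kernel_shap",
    "attribute_dataset",
]

#: largest feature count for which 2^M enumeration is attempted
EXACT_ENUMERATION_CAP = 16

_PREDICT_CHUNK_ROWS = 32768


class SingularDesignError(ValueError):
    """Raised when sampled coalitions do not determine the regression."""


class MarginalValueFunction:
    """Coalition value v(S) under the marginal expectation.

    For a coalition S, every background row is overwritten with the
    instance's values at the coordinates in S and the model output is
    averaged over the modified rows.  Consequently v(full set) = f(instance)
    and v(empty) = mean background output, for any background.
    """

    def __init__(
        self,
        model_output: Callable[[np.ndarray], np.ndarray],
        instance: np.ndarray,
        background: np.ndarray,
    ):
        self.model_output = model_output
        self.instance = np.asarray(instance, dtype=np.float64).ravel()
        self.background = np.asarray(background, dtype=np.float64)
        if self.background.ndim != 2 or self.background.shape[0] == 0:
            raise ValueError("background must be a non-empty 2-D matrix")
        if self.background.shape[1] != self.instance.shape[0]:
            raise ValueError(
                f"dimension mismatch: instance has {self.instance.shape[0]} "
                f"features, background has {self.background.shape[1]}"
            )

    @property
    def n_features(self) -> int:
        return self.instance.shape[0]

    def values(self, Z: np.ndarray) -> np.ndarray:
        """Vectorized v(S) for a (k, n_features) boolean membership matrix."""
        Z = np.atleast_2d(np.asarray(Z, dtype=bool))
        k, m = Z.shape
        if m != self.n_features:
            raise ValueError("coalition matrix width does not match the instance")
        B = self.background.shape[0]
        out = np.empty(k, dtype=np.float64)
        chunk = max(1, _PREDICT_CHUNK_ROWS // B)
        for start in range(0, k, chunk):
            zc = Z[start : start + chunk]
            # composites: background rows with instance values where z is set
            comp = np.broadcast_to(
                self.background, (zc.shape[0], B, m)
            ).copy()
            mask = np.broadcast_to(zc[:, None, :], comp.shape)
            comp[mask] = np.broadcast_to(self.instance, comp.shape)[mask]
            preds = self.model_output(comp.reshape(-1, m))
            out[start : start + zc.shape[0]] = preds.reshape(zc.shape[0], B).mean(axis=1)
        return out

    def value(self, coalition: Sequence[int]) -> float:
        z = np.zeros(self.n_features, dtype=bool)
        z[list(coalition)] = True
        return float(self.values(z[None, :])[0])


def marginal_value_function(model, instance, background, seed: int | None = None) -> MarginalValueFunction:
    """Build the marginal-expectation value function for one instance.

    ``model`` may be a :class:`~shapcompare.models.TrainedModel` (its
    ``output`` scalar is explained) or any callable mapping a matrix of rows
    to scalar outputs. ``seed`` is accepted for interface symmetry; the
    marginal expectation itself is deterministic given the background.
    """
    fn = model.output if hasattr(model, "output") else model
    return MarginalValueFunction(fn, instance, background)


def sample_background(train_X: np.ndarray, max_rows: int = 100, seed: int = 0) -> np.ndarray:
    """Seeded random sample of at most ``max_rows`` training rows."""
    train_X = np.asarray(train_X, dtype=np.float64)
    if train_X.shape[0] <= max_rows:
        return train_X.copy()
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(train_X.shape[0], size=max_rows, replace=False))
    return train_X[pick]


@dataclass
class ShapleyResult:
    """Per-feature attributions phi with their base value v(empty) and f(x).

    For exact results the efficiency axiom sum(phi) + base_value = fx holds
    to numerical precision; KernelSHAP enforces it by construction.
    """

    phi: np.ndarray
    base_value: float
    fx: float
    method: str
    n_samples: int | None = None
    seed: int | None = None

    @property
    def efficiency_gap(self) -> float:
        return float(abs(self.phi.sum() + self.base_value - self.fx))


def _subset_masks(n: int) -> np.ndarray:
    """All 2^n coalition membership rows, indexed by their bitmask."""
    ints = np.arange(2**n, dtype=np.uint32)
    return (ints[:, None] >> np.arange(n)) & 1


def _shapley_size_weights(n: int) -> np.ndarray:
    """w[k] = k! (n-k-1)! / n! for k = 0..n-1 (exact, then float)."""
    fact = [math.factorial(i) for i in range(n + 1)]
    return np.array(
        [fact[k] * fact[n - k - 1] / fact[n] for k in range(n)], dtype=np.float64
    )


def exact_shapley(v, n_features: int | None = None) -> ShapleyResult:
    """Exact Shapley values by full coalition enumeration.

    ``v`` is any value function exposing ``n_features`` and a vectorized
    ``values(Z)`` (a :class:`MarginalValueFunction` or a toy game).  All
    2^M coalition values are evaluated in one pass; the cap of
    ``EXACT_ENUMERATION_CAP`` features keeps the enumeration tractable —
    larger problems must use :func:`kernel_shap`.
    """
    n = int(n_features if n_features is not None else v.n_features)
    if n != v.n_features:
        raise ValueError("n_features does not match the value function")
    if n > EXACT_ENUMERATION_CAP:
        raise ValueError(
            f"{n} features exceeds the exact-enumeration cap of "
            f"{EXACT_ENUMERATION_CAP}; use kernel_shap instead"
        )
    Z = _subset_masks(n).astype(bool)
    vals = np.asarray(v.values(Z), dtype=np.float64)
    sizes = Z.sum(axis=1)
    w = _shapley_size_weights(n)

    masks = np.arange(2**n, dtype=np.uint32)
    phi = np.empty(n, dtype=np.float64)
    for p in range(n):
        without = masks[(masks >> p) & 1 == 0]
        phi[p] = np.sum(w[sizes[without]] * (vals[without | (1 << p)] - vals[without]))
    return ShapleyResult(
        phi=phi, base_value=float(vals[0]), fx=float(vals[-1]),
        method="exact_enumeration",
    )


def _kernel_weights(n: int, sizes: np.ndarray) -> np.ndarray:
    """Shapley kernel pi(s) = (M-1) / (C(M,s) * s * (M-s)) per coalition."""
    comb = np.array([math.comb(n, int(s)) for s in sizes], dtype=np.float64)
    return (n - 1) / (comb * sizes * (n - sizes))


def _solve_constrained_wls(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray, total: float
) -> np.ndarray:
    """Weighted least squares for phi subject to sum(phi) = total.

    The constraint is eliminated by substituting the last coefficient,
    which keeps efficiency exact; with all proper coalitions enumerated the
    solution coincides with the exact Shapley values.
    """
    n = Z.shape[1]
    if n == 1:
        return np.array([total])
    z_last = Z[:, -1]
    y_adj = y - z_last * total
    design = Z[:, :-1] - z_last[:, None]
    sw = np.sqrt(w)
    sol, _, rank, _ = np.linalg.lstsq(design * sw[:, None], y_adj * sw, rcond=None)
    if rank < n - 1:
        raise SingularDesignError(
            "sampled coalitions are rank-deficient; increase n_samples"
        )
    phi = np.empty(n)
    phi[:-1] = sol
    phi[-1] = total - sol.sum()
    return phi


def _sample_coalitions(n: int, budget: int, seed: int | None):
    """Coalition design matrix and weights for a limited evaluation budget.

    Size pairs (s, n-s) are enumerated completely, smallest sizes first
    (where the kernel mass concentrates), while the full pair fits in the
    remaining budget; those rows carry their exact kernel weights.  The
    rest of the budget is filled with complementary pairs sampled from the
    leftover sizes proportionally to the kernel weights; duplicates are
    aggregated and the leftover kernel mass is split across the sampled
    rows by their multiplicity.
    """
    rng = np.random.default_rng(seed)
    s_grid = np.arange(1, n, dtype=np.int64)
    size_mass = (n - 1) / (s_grid * (n - s_grid))  # = C(n,s) * pi(s)
    size_mass /= size_mass.sum()

    rows: list[np.ndarray] = []
    weights: list[float] = []
    enumerated: set[int] = set()
    remaining = budget
    for s in range(1, n // 2 + 1):
        pair = [s] if 2 * s == n else [s, n - s]
        count = sum(math.comb(n, p) for p in pair)
        if count > remaining:
            break
        for p in pair:
            pi = size_mass[p - 1] / math.comb(n, p)  # normalized kernel weight
            for members in itertools.combinations(range(n), p):
                z = np.zeros(n)
                z[list(members)] = 1.0
                rows.append(z)
                weights.append(pi)
            enumerated.add(p)
        remaining -= count

    leftover = [int(s) for s in s_grid if s not in enumerated]
    if leftover and remaining >= 2:
        p_left = np.array([size_mass[s - 1] for s in leftover])
        mass_left = p_left.sum()
        p_left /= mass_left
        n_pairs = remaining // 2
        sampled: dict[tuple, int] = {}
        sizes_drawn = rng.choice(leftover, size=n_pairs, p=p_left)
        for s in sizes_drawn:
            members = tuple(np.sort(rng.choice(n, size=int(s), replace=False)))
            sampled[members] = sampled.get(members, 0) + 1
            comp = tuple(i for i in range(n) if i not in members)
            sampled[comp] = sampled.get(comp, 0) + 1
        n_drawn = sum(sampled.values())
        for members, count in sampled.items():
            z = np.zeros(n)
            z[list(members)] = 1.0
            rows.append(z)
            weights.append(mass_left * count / n_drawn)
    return np.array(rows), np.array(weights), len(rows)


def kernel_shap_game(
    v, n_samples: int | None = None, seed: int | None = None
) -> ShapleyResult:
    """KernelSHAP on an explicit value function / game.

    With ``n_samples=None`` (or >= 2^M - 2) all proper non-empty coalitions
    are enumerated with their exact Shapley-kernel weights, and the result
    matches :func:`exact_shapley` to numerical precision.  Otherwise the
    budget is spent the standard way: complementary size pairs (s, M-s) are
    enumerated completely in order of decreasing kernel mass for as long as
    they fit, and the remainder of the budget is sampled in complementary
    pairs from the leftover sizes with probability proportional to the
    kernel weights.  ``n_samples`` must be at least ``2 * M``, which
    guarantees all singleton coalitions are present and the regression is
    well-posed.
    """
    n = int(v.n_features)
    ones = np.ones((1, n), dtype=bool)
    zeros = np.zeros((1, n), dtype=bool)
    fx = float(np.asarray(v.values(ones))[0])
    base = float(np.asarray(v.values(zeros))[0])
    total = fx - base

    if n == 1:
        return ShapleyResult(np.array([total]), base, fx, "kernel_shap", n_samples, seed)

    n_all = 2**n - 2
    full = n_samples is None or n_samples >= n_all
    if full:
        masks = np.arange(1, 2**n - 1, dtype=np.uint32)
        Z = ((masks[:, None] >> np.arange(n)) & 1).astype(np.float64)
        sizes = Z.sum(axis=1)
        w = _kernel_weights(n, sizes)
        used = n_all
    else:
        if n_samples < 2 * n:
            raise ValueError(f"n_samples must be >= {2 * n} (2 * n_features)")
        Z, w, used = _sample_coalitions(n, n_samples, seed)

    y = np.asarray(v.values(Z.astype(bool)), dtype=np.float64) - base
    phi = _solve_constrained_wls(Z, y, w, total)
    return ShapleyResult(
        phi=phi, base_value=base, fx=fx, method="kernel_shap",
        n_samples=used, seed=seed,
    )


def kernel_shap(
    model,
    instance: np.ndarray,
    background: np.ndarray,
    n_samples: int | None = None,
    seed: int | None = None,
) -> ShapleyResult:
    """KernelSHAP for one instance of a trained model.

    Builds the marginal-expectation value function over ``background`` and
    delegates to :func:`kernel_shap_game`.
    """
    vf = marginal_value_function(model, instance, background)
    return kernel_shap_game(vf, n_samples=n_samples, seed=seed)


@dataclass
class AttributionMatrix:
    """Instance x feature attribution values for one (method, model, trial)."""

    values: np.ndarray
    base_values: np.ndarray
    fx: np.ndarray
    method: str
    model_label: str
    trial_index: int
    compound_ids: list[str]
    feature_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.base_values = np.asarray(self.base_values, dtype=np.float64)
        self.fx = np.asarray(self.fx, dtype=np.float64)
        self.feature_ids = np.asarray(self.feature_ids, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("column count must equal the number of feature ids")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV (compound_id, feature_id, value) + JSON sidecar."""
        path = Path(path)
        n, m = self.values.shape
        df = pd.DataFrame(
            {
                "compound_id": np.repeat(self.compound_ids, m),
                "feature_id": np.tile(self.feature_ids, n),
                "value": self.values.ravel(),
            }
        )
        df.to_csv(path, index=False)
        sidecar = {
            "method": self.method,
            "model": self.model_label,
            "trial_index": self.trial_index,
            "base_values": self.base_values.tolist(),
            "fx": self.fx.tolist(),
            "compound_ids": list(self.compound_ids),
            "feature_ids": self.feature_ids.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AttributionMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        df = pd.read_csv(path)
        cids = meta["compound_ids"]
        fids = np.asarray(meta["feature_ids"])
        values = (
            df.pivot(index="compound_id", columns="feature_id", values="value")
            .reindex(index=cids, columns=fids)
            .to_numpy()
        )
        return cls(
            values=values,
            base_values=np.asarray(meta["base_values"]),
            fx=np.asarray(meta["fx"]),
            method=meta["method"],
            model_label=meta["model"],
            trial_index=meta["trial_index"],
            compound_ids=cids,
            feature_ids=fids,
        )


def attribute_dataset(
    model,
    rows: np.ndarray,
    method: str = "kernel_shap",
    background: np.ndarray | None = None,
    n_samples: int | None = None,
    seed: int = 0,
    compound_ids: Sequence[str] | None = None,
    model_label: str = "",
    trial_index: int = -1,
    progress_every: int = 50,
) -> AttributionMatrix:
    """Attribute every row of a test split with one method.

    ``method`` is ``"exact_enumeration"`` or ``"kernel_shap"``. Sampled
    KernelSHAP runs draw one independent sub-seed per instance from
    ``seed``. An empty row list yields an empty matrix.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    if rows.size == 0:
        rows = rows.reshape(0, model.n_features if hasattr(model, "n_features") else 0)
    n, m = rows.shape
    if background is None:
        background = sample_background(model.train_X, seed=seed)
    if compound_ids is None:
        compound_ids = [f"row{i}" for i in range(n)]
    if method not in ("exact_enumeration", "kernel_shap"):
        raise ValueError(f"unknown attribution method {method!r}")

    sub_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(max(n, 1)) % (2**31)]
    values = np.empty((n, m))
    bases = np.empty(n)
    fxs = np.empty(n)
    for i in range(n):
        try:
            vf = marginal_value_function(model, rows[i], background)
            if method == "exact_enumeration":
                res = exact_shapley(vf)
            else:
                res = kernel_shap_game(vf, n_samples=n_samples, seed=sub_seeds[i])
        except Exception as exc:
            raise RuntimeError(
                f"attribution failed for instance {compound_ids[i]!r}: {exc}"
            ) from exc
        values[i] = res.phi
        bases[i] = res.base_value
        fxs[i] = res.fx
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("attributed %d/%d instances", i + 1, n)
    return AttributionMatrix(
        values=values,
        base_values=bases,
        fx=fxs,
        method=method,
        model_label=model_label or getattr(getattr(model, "spec", None), "method", ""),
        trial_index=trial_index,
        compound_ids=list(compound_ids),
        feature_ids=np.arange(m),
    )
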