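"""Statistics for characterizing and comparing feature-attribution distributions.

Covers the full comparison suite: cumulative present/absent value sums over
correctly predicted compounds, Gini coefficients (dispersion of importance),
compacity curves (fraction of features needed to reach a share of the total
absolute importance), per-feature consistency standard deviations, Pearson
correlation between methods, faithfulness (correlation of attributions with
single-bit-flip effects on the model output), and Wilcoxon signed-rank tests
with Holm-Bonferroni correction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .attribution import AttributionMatrix
from .synthetic import ACTIVE, LABEL_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "cumulative_present_absent",
    "gini",
    "compacity",
    "normalize_rows",
    "consistency_std",
    "correlation_between_methods",
    "faithfulness",
    "holm_adjust",
    "significance_tier",
    "wilcoxon_holm",
    "ReportEntry",
    "ComparisonReport",
    "build_comparison_report",
    "DEFAULT_COMPACITY_THRESHOLDS",
]

DEFAULT_COMPACITY_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def cumulative_present_absent(
    attr: AttributionMatrix,
    bits: np.ndarray,
    y_true: np.ndarray,
    y_pred: np.ndarray,
) -> pd.DataFrame:
    """Per-compound cumulative attribution sums over present and absent features.

    Only correctly predicted compounds contribute. A feature is *present*
    in a compound iff its bit is 1.  Returns one row per qualifying
    compound with raw sums and sums normalized by the row's total absolute
    attribution (NaN when that total is zero).
    """
    bits = np.asarray(bits)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    n = attr.n_instances
    if not (bits.shape[0] == len(y_true) == len(y_pred) == n):
        raise ValueError("attribution matrix, bits and predictions are misaligned")
    if bits.shape[1] != attr.n_features:
        raise ValueError("bits and attribution matrix differ in feature count")
    rows = []
    for i in range(n):
        if y_true[i] != y_pred[i]:
            continue
        phi = attr.values[i]
        present = bits[i] == 1
        abs_total = np.abs(phi).sum()
        ps, ab = float(phi[present].sum()), float(phi[~present].sum())
        rows.append(
            {
                "compound_id": attr.compound_ids[i],
                "true_class": LABEL_NAMES[int(y_true[i])],
                "present_sum": ps,
                "absent_sum": ab,
                "present_sum_norm": ps / abs_total if abs_total > 0 else np.nan,
                "absent_sum_norm": ab / abs_total if abs_total > 0 else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id", "true_class", "present_sum", "absent_sum",
            "present_sum_norm", "absent_sum_norm",
        ],
    )


def gini(values: Sequence[float]) -> float:
    """Gini coefficient of a non-negative importance vector.

    Zeros are removed first (the formula applies to non-zero values only);
    the remainder is sorted ascending and

        G = sum_i (2 i - n - 1) X_i / (n sum_i X_i),   i = 1..n.

    G is 0 for perfectly equal values and approaches 1 when one value
    dominates. All-zero input is an error; negative input is rejected
    (pass absolute attributions).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("gini of an empty vector is undefined")
    if (x < 0).any():
        raise ValueError("gini requires non-negative values; pass absolute values")
    x = np.sort(x[x != 0])
    n = x.size
    if n == 0:
        raise ValueError("gini is undefined for an all-zero vector")
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * x.sum()))


def compacity(
    values: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_COMPACITY_THRESHOLDS,
) -> np.ndarray:
    """Percentage of features needed to reach each absolute-importance share.

    With absolute values sorted descending, m(t) is the smallest count whose
    cumulative sum reaches t times the total absolute sum; the returned
    array holds 100 * m(t) / n per threshold and is non-decreasing in t.
    """
    x = np.abs(np.asarray(values, dtype=np.float64))
    if x.size == 0:
        raise ValueError("compacity of an empty vector is undefined")
    total = x.sum()
    if total == 0:
        raise ValueError("compacity is undefined for an all-zero vector")
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie in (0, 1)")
    csum = np.cumsum(np.sort(x)[::-1])
    m = np.searchsorted(csum, thresholds * total - 1e-12) + 1
    return 100.0 * m / x.size


def normalize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each row by its absolute sum; returns (normalized, valid_mask).

    Rows with an absolute sum of zero cannot be normalized; they are left
    as NaN, flagged invalid, and logged.
    """
    values = np.asarray(values, dtype=np.float64)
    totals = np.abs(values).sum(axis=1)
    valid = totals > 0
    if not valid.all():
        logger.warning("skipping %d all-zero attribution rows", int((~valid).sum()))
    out = np.full_like(values, np.nan)
    out[valid] = values[valid] / totals[valid, None]
    return out, valid


def consistency_std(
    attr: AttributionMatrix | np.ndarray,
    mask: np.ndarray | None = None,
    ddof: int = 1,
) -> np.ndarray:
    """Per-feature standard deviation of row-normalized attribution values.

    Each row is first normalized by its absolute sum; the std of each
    feature is then taken across the instances where its normalized value
    is non-zero (optionally further restricted by ``mask``). Features with
    fewer than two qualifying instances are NaN. Sample (n-1) std by
    default.
    """
    values = attr.values if isinstance(attr, AttributionMatrix) else np.asarray(attr)
    if values.size == 0:
        raise ValueError("empty attribution matrix")
    norm, valid = normalize_rows(values)
    qualify = valid[:, None] & (norm != 0) & ~np.isnan(norm)
    if mask is not None:
        qualify &= np.asarray(mask, dtype=bool)
    n_features = values.shape[1]
    out = np.full(n_features, np.nan)
    counts = qualify.sum(axis=0)
    for j in np.flatnonzero(counts >= 2):
        out[j] = np.std(norm[qualify[:, j], j], ddof=ddof)
    return out


def _subset_mask(bits: np.ndarray, subset: str) -> np.ndarray:
    bits = np.asarray(bits)
    if subset == "all":
        return np.ones_like(bits, dtype=bool)
    if subset == "present":
        return bits == 1
    if subset == "absent":
        return bits == 0
    raise ValueError(f"unknown subset {subset!r}; expected all/present/absent")


def correlation_between_methods(
    attrA: AttributionMatrix | np.ndarray,
    attrB: AttributionMatrix | np.ndarray,
    bits: np.ndarray | None = None,
    subset: str = "all",
) -> float:
    """Pearson r between two attribution matrices over pooled (instance,
    feature) pairs, optionally restricted to present or absent features.

    Returns NaN (with a warning) when either pooled vector has zero
    variance, where the correlation is undefined.
    """
    A = attrA.values if isinstance(attrA, AttributionMatrix) else np.asarray(attrA)
    B = attrB.values if isinstance(attrB, AttributionMatrix) else np.asarray(attrB)
    if A.shape != B.shape:
        raise ValueError("attribution matrices are not aligned")
    if subset != "all" and bits is None:
        raise ValueError("bits are required for present/absent subsets")
    mask = (
        np.ones_like(A, dtype=bool) if bits is None and subset == "all"
        else _subset_mask(bits, subset)
    )
    a, b = A[mask].ravel(), B[mask].ravel()
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("correlation undefined (subset=%s): zero variance", subset)
        return float("nan")
    return float(sps.pearsonr(a, b).statistic)


def faithfulness(
    model,
    instance: np.ndarray,
    attribution_row: np.ndarray,
    subset: str | np.ndarray = "present",
) -> float:
    """Correlation of attributions with single-bit-flip marginal contributions.

    For each feature i in the subset, the marginal contribution is
    m_i = f(x) - f(x with bit i inverted); the statistic is the Pearson
    correlation between the attribution values and the m_i. Undefined
    (NaN) for subsets smaller than two features or zero-variance vectors.
    ``model`` is a TrainedModel or a callable over row matrices.
    """
    fn = model.output if hasattr(model, "output") else model
    x = np.asarray(instance, dtype=np.float64).ravel()
    w = np.asarray(attribution_row, dtype=np.float64).ravel()
    if x.shape != w.shape:
        raise ValueError("instance and attribution row are misaligned")
    if isinstance(subset, str):
        idx = np.flatnonzero(_subset_mask(x[None, :], subset)[0])
    else:
        idx = np.asarray(subset, dtype=np.int64)
    if idx.size < 2:
        return float("nan")
    flipped = np.tile(x, (idx.size, 1))
    flipped[np.arange(idx.size), idx] = 1.0 - flipped[np.arange(idx.size), idx]
    fx = float(np.asarray(fn(x[None, :]))[0])
    m = fx - np.asarray(fn(flipped), dtype=np.float64)
    wi = w[idx]
    if np.ptp(wi) == 0 or np.ptp(m) == 0:
        return float("nan")
    return float(sps.pearsonr(wi, m).statistic)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (same order as input)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def significance_tier(p: float) -> str:
    """Conventional star tiers: ns, *, **, ***, **** at 5e-2/1e-2/1e-3/1e-4."""
    if np.isnan(p):
        return "missing"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"


def wilcoxon_holm(
    paired_sets: Sequence[tuple[str, Sequence[float], Sequence[float]]],
) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank tests with Holm correction.

    ``paired_sets`` holds (label, x, y) triples of equal-length paired
    vectors (length >= 5). Degenerate pairs (all differences zero) are
    reported as missing and excluded from the Holm family.
    """
    rows = []
    for label, x, y in paired_sets:
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if x.shape != y.shape or x.size < 5:
            raise ValueError(f"paired vectors for {label!r} must be equal length >= 5")
        keep = ~(np.isnan(x) | np.isnan(y))
        d = x[keep] - y[keep]
        if keep.sum() < 5 or np.all(d == 0):
            rows.append({"label": label, "n": int(keep.sum()), "p_raw": np.nan})
            continue
        res = sps.wilcoxon(x[keep], y[keep], alternative="two-sided")
        rows.append({"label": label, "n": int(keep.sum()), "p_raw": float(res.pvalue)})
    df = pd.DataFrame(rows, columns=["label", "n", "p_raw"])
    df["p_holm"] = np.nan
    defined = df["p_raw"].notna()
    if defined.any():
        df.loc[defined, "p_holm"] = holm_adjust(df.loc[defined, "p_raw"].to_numpy())
    df["tier"] = [significance_tier(p) for p in df["p_holm"]]
    return df


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class ReportEntry:
    """One (method, model, trial) attribution run with its test-split context."""

    method: str
    model_label: str
    trial_index: int
    attr: AttributionMatrix
    bits: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    model: object | None = None  # TrainedModel, needed for faithfulness
    seed: int = 0


@dataclass
class ComparisonReport:
    """All comparison statistics as plot-ready tables keyed by statistic name."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self.tables.items():
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        manifest = {"tables": {name: f"{name}.csv" for name in self.tables}}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return written


def _iter_correct(entry: ReportEntry, correct_only: bool):
    for i in range(entry.attr.n_instances):
        if correct_only and entry.y_true[i] != entry.y_pred[i]:
            continue
        yield i


def build_comparison_report(
    entries: Sequence[ReportEntry],
    thresholds: Sequence[float] = DEFAULT_COMPACITY_THRESHOLDS,
    correct_only: bool = True,
    compute_faithfulness: bool = True,
) -> ComparisonReport:
    """Assemble every comparison statistic from a set of attribution runs.

    Statistics follow the study design: per-instance measures are restricted
    to correctly predicted compounds (switchable), stratified by true class
    and feature state; correlations pool instances and trials per model.
    """
    meta = lambda e: {"method": e.method, "model": e.model_label,
                      "trial": e.trial_index, "seed": e.seed}

    cum_rows, gini_rows, comp_rows, faith_rows = [], [], [], []
    for e in entries:
        cum = cumulative_present_absent(e.attr, e.bits, e.y_true, e.y_pred)
        for rec in cum.to_dict("records"):
            cum_rows.append({**meta(e), **rec})
        for i in _iter_correct(e, correct_only):
            phi = e.attr.values[i]
            cls = LABEL_NAMES[int(e.y_true[i])]
            base = {**meta(e), "compound_id": e.attr.compound_ids[i], "true_class": cls}
            for state in ("present", "absent"):
                sel = np.abs(phi[_subset_mask(e.bits[i][None, :], state)[0]])
                g = gini(sel) if sel.size and sel.any() else np.nan
                gini_rows.append({**base, "feature_state": state, "gini": g})
            if np.abs(phi).sum() > 0:
                pct = compacity(phi, thresholds)
                for t, v in zip(thresholds, pct):
                    comp_rows.append({**base, "threshold": t, "pct_features": v})
            if compute_faithfulness and e.model is not None:
                for state in ("present", "absent"):
                    faith_rows.append(
                        {**base, "feature_state": state,
                         "r": faithfulness(e.model, e.bits[i], phi, state)}
                    )

    # consistency: pool trials per (method, model), stratified by class x state
    cons_rows = []
    groups: dict[tuple[str, str], list[ReportEntry]] = {}
    for e in entries:
        groups.setdefault((e.method, e.model_label), []).append(e)
    for (method, model_label), group in groups.items():
        keep = [
            (e, [i for i in _iter_correct(e, correct_only)]) for e in group
        ]
        values = np.vstack([e.attr.values[idx] for e, idx in keep if idx])
        bits = np.vstack([np.asarray(e.bits)[idx] for e, idx in keep if idx])
        classes = np.concatenate([np.asarray(e.y_true)[idx] for e, idx in keep if idx])
        fids = group[0].attr.feature_ids
        for cls in (ACTIVE, 1 - ACTIVE):
            rowsel = classes == cls
            if rowsel.sum() < 2:
                continue
            for state in ("present", "absent"):
                mask = _subset_mask(bits[rowsel], state)
                stds = consistency_std(values[rowsel], mask=mask)
                for j, s in enumerate(stds):
                    if not np.isnan(s):
                        cons_rows.append(
                            {"method": method, "model": model_label,
                             "true_class": LABEL_NAMES[cls], "feature_state": state,
                             "feature_id": int(fids[j]), "std": float(s)}
                        )

    # correlation: per model, method x method, pooled over trials
    corr_rows = []
    by_model: dict[str, dict[str, list[ReportEntry]]] = {}
    for e in entries:
        by_model.setdefault(e.model_label, {}).setdefault(e.method, []).append(e)
    for model_label, methods in by_model.items():
        names = sorted(methods)
        for ia in range(len(names)):
            for ib in range(ia + 1, len(names)):
                ea = sorted(methods[names[ia]], key=lambda e: e.trial_index)
                eb = sorted(methods[names[ib]], key=lambda e: e.trial_index)
                A = np.vstack([e.attr.values for e in ea])
                B = np.vstack([e.attr.values for e in eb])
                bits = np.vstack([np.asarray(e.bits) for e in ea])
                for subset in ("all", "present", "absent"):
                    r = correlation_between_methods(A, B, bits, subset)
                    corr_rows.append(
                        {"model": model_label, "method_a": names[ia],
                         "method_b": names[ib], "subset": subset, "r": r,
                         "n_pairs": int(_subset_mask(bits, subset).sum())}
                    )

    gini_df = pd.DataFrame(
        gini_rows, columns=["method", "model", "trial", "seed", "compound_id",
                            "true_class", "feature_state", "gini"])
    cum_df = pd.DataFrame(
        cum_rows, columns=["method", "model", "trial", "seed", "compound_id",
                           "true_class", "present_sum", "absent_sum",
                           "present_sum_norm", "absent_sum_norm"])

    # significance family: between-method Gini differences and
    # present-vs-absent cumulative sums, per model / class / state
    paired = []
    for model_label, methods in by_model.items():
        names = sorted(methods)
        sub = gini_df[gini_df["model"] == model_label]
        for ia in range(len(names)):
            for ib in range(ia + 1, len(names)):
                for cls in ("active", "inactive"):
                    for state in ("present", "absent"):
                        a = sub[(sub.method == names[ia]) & (sub.true_class == cls)
                                & (sub.feature_state == state)]
                        b = sub[(sub.method == names[ib]) & (sub.true_class == cls)
                                & (sub.feature_state == state)]
                        merged = a.merge(b, on=["trial", "compound_id"],
                                         suffixes=("_a", "_b"))
                        if len(merged) >= 5:
                            paired.append(
                                (f"{model_label}|gini|{cls}|{state}|"
                                 f"{names[ia]}_vs_{names[ib]}",
                                 merged["gini_a"].to_numpy(),
                                 merged["gini_b"].to_numpy())
                            )
        for method in names:
            sub_c = cum_df[(cum_df.model == model_label) & (cum_df.method == method)]
            for cls in ("active", "inactive"):
                s = sub_c[sub_c.true_class == cls]
                if len(s) >= 5:
                    paired.append(
                        (f"{model_label}|cumulative|{cls}|present_vs_absent|{method}",
                         s["present_sum"].to_numpy(), s["absent_sum"].to_numpy())
                    )
    wilcoxon_df = (
        wilcoxon_holm(paired) if paired
        else pd.DataFrame(columns=["label", "n", "p_raw", "p_holm", "tier"])
    )

    report = ComparisonReport()
    report.tables["cumulative"] = cum_df
    report.tables["gini"] = gini_df
    report.tables["compacity"] = pd.DataFrame(
        comp_rows, columns=["method", "model", "trial", "seed", "compound_id",
                            "true_class", "threshold", "pct_features"])
    report.tables["consistency"] = pd.DataFrame(
        cons_rows, columns=["method", "model", "true_class", "feature_state",
                            "feature_id", "std"])
    report.tables["correlation"] = pd.DataFrame(
        corr_rows, columns=["model", "method_a", "method_b", "subset", "r", "n_pairs"])
    report.tables["faithfulness"] = pd.DataFrame(
        faith_rows, columns=["method", "model", "trial", "seed", "compound_id",
                             "true_class", "feature_state", "r"])
    report.tables["significance"] = wilcoxon_df
    return report
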