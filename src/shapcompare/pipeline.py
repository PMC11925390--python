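"""End-to-end orchestration: generate -> curate -> train -> explain -> compare -> roar.

Every stage derives its seed deterministically from the master seed, writes
self-describing CSV/JSON outputs into the run directory, and can be executed
in isolation (later stages reload earlier outputs from disk).  A run
manifest records the configuration, seeds, outputs and library versions;
rerunning with an identical configuration reproduces every statistic table
byte for byte.

Exact enumeration cannot cover full-width fingerprints, so the pipeline
follows a scaled-down protocol for the model-specific exact method: features
are ranked by the pooled full-width KernelSHAP attributions, each trial's
model is retrained on the top-M features (M small enough to enumerate), and
exact Shapley values and KernelSHAP are then compared head-to-head on those
reduced models.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import AttributionMatrix, attribute_dataset, sample_background
from .curation import curate, write_activity_records, write_audit
from .models import (
    METHODS,
    ModelSpec,
    TrainedModel,
    evaluate,
    fit_with_params,
    split_trials,
    tune_and_train,
)
from .roar import default_schedule, global_feature_ranking, roar_run
from .stats import DEFAULT_COMPACITY_THRESHOLDS, ReportEntry, build_comparison_report
from .synthetic import (
    FingerprintDataset,
    SyntheticConfig,
    generate_activity_records,
    generate_fingerprint_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Pipeline", "run_pipeline", "derive_seed"]

# stage tags for seed derivation
_GENERATE, _CURATE, _TRAIN, _EXPLAIN, _ROAR = 1, 2, 3, 4, 6

#: single-point grids for desk-scale runs (no search; hyperparameters fixed
#: at mid-grid values that perform well on the planted-signal generator)
FAST_GRIDS: dict[str, dict[str, list]] = {
    "RFC": {"min_samples_leaf": [1], "min_samples_split": [2], "n_estimators": [100]},
    "SVM_RBF": {"C": [10], "gamma": [0.01]},
    "SVM_TAN": {"C": [10]},
    "FFNN": {"learning_rate_init": [0.001]},
}


def derive_seed(*parts: int) -> int:
    """Deterministic 31-bit seed from a tuple of integer tags."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Full configuration of one analysis run.

    ``grid_mode`` selects between the full hyperparameter grids
    (``"paper"``) and fixed single-point grids (``"fast"``, the desk-scale
    default).  ``top_m`` is the reduced width used for the exact-enumeration
    protocol and must stay within the enumeration cap.
    """

    out_dir: str = "shapcompare_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    methods: tuple[str, ...] = ("RFC", "SVM_TAN")
    grid_mode: str = "fast"
    n_trials: int = 10
    test_fraction: float = 0.1
    explain_max_instances: int = 10
    background_size: int = 32
    n_samples: int = 512
    top_m: int = 12
    compacity_thresholds: tuple[float, ...] = DEFAULT_COMPACITY_THRESHOLDS
    correct_only: bool = True
    roar_schedule: tuple[int, ...] | None = None
    n_random_controls: int = 5
    n_curation_records: int = 200

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; expected one of {METHODS}")
        if self.grid_mode not in ("fast", "paper"):
            raise ValueError("grid_mode must be 'fast' or 'paper'")
        if not 1 <= self.top_m <= 16:
            raise ValueError("top_m must be in 1..16 (exact-enumeration cap)")

    def model_spec(self, method: str) -> ModelSpec:
        grid = None if self.grid_mode == "paper" else {
            k: list(v) for k, v in FAST_GRIDS[method].items()
        }
        return ModelSpec(method=method, grid=grid)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        for key in ("methods", "compacity_thresholds", "roar_schedule"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class Pipeline:
    """Stage runner holding in-memory state and persisting every output."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.dataset: FingerprintDataset | None = None
        self.splits = None
        self.models: dict[tuple[str, int], TrainedModel] = {}
        self.attributions: dict[str, AttributionMatrix] = {}
        self.rankings: dict[str, np.ndarray] = {}
        self.entries: list[ReportEntry] = []
        self.outputs: list[str] = []

    # -- helpers -------------------------------------------------------

    def _write(self, name: str) -> Path:
        self.outputs.append(name)
        return self.out / name

    def _require_dataset(self) -> FingerprintDataset:
        if self.dataset is None:
            path = self.out / "dataset.csv"
            if path.exists():
                self.dataset = FingerprintDataset.from_csv(path)
            else:
                self.stage_generate()
        return self.dataset

    def _require_models(self):
        if not self.models:
            path = self.out / "models.pkl"
            if path.exists():
                with open(path, "rb") as fh:
                    self.models = pickle.load(fh)
                self.splits = split_trials(
                    self._require_dataset().labels, self.config.n_trials,
                    self.config.test_fraction, derive_seed(self.config.seed, _TRAIN),
                )
            else:
                self.stage_train()
        return self.models

    # -- stages --------------------------------------------------------

    def stage_generate(self) -> FingerprintDataset:
        cfg = self.config
        syn = cfg.synthetic.with_seed(derive_seed(cfg.seed, _GENERATE))
        logger.info("generate: %d per class, %d features, %d informative",
                    syn.n_per_class, syn.n_features, syn.n_informative)
        self.dataset = generate_fingerprint_dataset(syn)
        self.dataset.to_csv(self._write("dataset.csv"))
        self.dataset.to_sparse_csv(self._write("dataset_sparse.csv"))
        (self._write("informative_ids.json")).write_text(
            json.dumps(self.dataset.informative_ids)
        )
        return self.dataset

    def stage_curate(self) -> None:
        """Demonstration curation pass on a generated activity-record table."""
        cfg = self.config
        records, expected = generate_activity_records(
            derive_seed(cfg.seed, _CURATE), cfg.n_curation_records
        )
        write_activity_records(records, self._write("activity_records.csv"))
        survivors, audit = curate(records)
        write_activity_records(survivors, self._write("curated_records.csv"))
        write_audit(audit, self._write("curation_audit.csv"))
        logger.info("curate: %d/%d records survive", len(survivors), len(records))

    def stage_train(self) -> pd.DataFrame:
        cfg = self.config
        ds = self._require_dataset()
        X, y = ds.X(), ds.labels
        self.splits = split_trials(
            y, cfg.n_trials, cfg.test_fraction, derive_seed(cfg.seed, _TRAIN)
        )
        rows = []
        for mi, method in enumerate(cfg.methods):
            spec = cfg.model_spec(method)
            for split in self.splits:
                seed = derive_seed(cfg.seed, _TRAIN, mi, split.trial_index)
                model = tune_and_train(X, y, split, spec, seed)
                self.models[(method, split.trial_index)] = model
                rep = evaluate(model, X[split.test_ids], y[split.test_ids])
                rows.append({"model": method, "trial": split.trial_index,
                             "seed": seed, **rep.as_dict(),
                             "params": json.dumps(model.params, sort_keys=True)})
                logger.info("train %s trial %d: MCC=%.3f",
                            method, split.trial_index, rep.mcc)
        perf = pd.DataFrame(rows)
        perf.to_csv(self._write("performance.csv"), index=False)
        with open(self._write("models.pkl"), "wb") as fh:
            pickle.dump(self.models, fh)
        sidecar = {
            f"{m}_trial{t}": {"method": m, "trial": t,
                              "seed": model.seed, "params": model.params}
            for (m, t), model in self.models.items()
        }
        (self._write("models.json")).write_text(json.dumps(sidecar, indent=1))
        return perf

    def _explain_rows(self, split):
        """Deterministic subset of test rows to attribute in one trial."""
        ids = np.asarray(split.test_ids)[: self.config.explain_max_instances]
        return ids

    def stage_explain(self) -> None:
        cfg = self.config
        ds = self._require_dataset()
        self._require_models()
        X, y = ds.X(), ds.labels
        self.entries = []
        for mi, method in enumerate(cfg.methods):
            full_mats = []
            # full-width KernelSHAP
            for split in self.splits:
                model = self.models[(method, split.trial_index)]
                ids = self._explain_rows(split)
                seed = derive_seed(cfg.seed, _EXPLAIN, mi, split.trial_index)
                background = sample_background(model.train_X, cfg.background_size, seed)
                attr = attribute_dataset(
                    model, X[ids], method="kernel_shap", background=background,
                    n_samples=cfg.n_samples, seed=seed,
                    compound_ids=[ds.compound_ids[i] for i in ids],
                    model_label=method, trial_index=split.trial_index,
                )
                name = f"attr_{method}_kernel_shap_full_trial{split.trial_index}.csv"
                attr.to_csv(self._write(name))
                self.outputs.append(name.replace(".csv", ".json"))
                full_mats.append((split, ids, attr, model))
                self.entries.append(ReportEntry(
                    method="kernel_shap_full", model_label=method,
                    trial_index=split.trial_index, attr=attr, bits=ds.bits[ids],
                    y_true=y[ids], y_pred=model.predict(X[ids]), model=model,
                    seed=seed,
                ))
            ranking = global_feature_ranking(
                np.vstack([a.values for _, _, a, _ in full_mats])
            )
            self.rankings[method] = ranking
            pd.DataFrame({
                "rank": np.arange(len(ranking)), "feature_id": ranking,
            }).to_csv(self._write(f"ranking_{method}.csv"), index=False)

            # reduced top-M protocol: exact enumeration vs KernelSHAP
            top = np.sort(ranking[-cfg.top_m:])
            label = f"{method}_top{cfg.top_m}"
            for split, ids, _, model in full_mats:
                seed = derive_seed(cfg.seed, _EXPLAIN, mi, split.trial_index, 1)
                reduced = fit_with_params(
                    X[np.ix_(split.train_ids, top)], y[split.train_ids],
                    model.spec, model.params, seed, split.trial_index,
                )
                background = sample_background(
                    reduced.train_X, cfg.background_size, seed
                )
                rows = X[np.ix_(ids, top)]
                cids = [ds.compound_ids[i] for i in ids]
                pred = reduced.predict(rows)
                for attr_method in ("exact_enumeration", "kernel_shap"):
                    attr = attribute_dataset(
                        reduced, rows, method=attr_method, background=background,
                        n_samples=None, seed=seed, compound_ids=cids,
                        model_label=label, trial_index=split.trial_index,
                    )
                    name = f"attr_{label}_{attr_method}_trial{split.trial_index}.csv"
                    attr.to_csv(self._write(name))
                    self.outputs.append(name.replace(".csv", ".json"))
                    self.entries.append(ReportEntry(
                        method=attr_method, model_label=label,
                        trial_index=split.trial_index, attr=attr,
                        bits=ds.bits[np.ix_(ids, top)], y_true=y[ids],
                        y_pred=pred, model=reduced, seed=seed,
                    ))

    def stage_compare(self) -> None:
        if not self.entries:
            self.stage_explain()
        report = build_comparison_report(
            self.entries,
            thresholds=self.config.compacity_thresholds,
            correct_only=self.config.correct_only,
        )
        written = report.write(self.out / "comparison")
        self.outputs += [f"comparison/{p.name}" for p in written]
        self.outputs.append("comparison/manifest.json")

    def stage_roar(self) -> None:
        cfg = self.config
        ds = self._require_dataset()
        self._require_models()
        if not self.rankings:
            self.stage_explain()
        X, y = ds.X(), ds.labels
        split = self.splits[0]
        for mi, method in enumerate(cfg.methods):
            model = self.models[(method, split.trial_index)]
            result = roar_run(
                X, y, split, model.spec, model.params, self.rankings[method],
                schedule=cfg.roar_schedule, n_random_controls=cfg.n_random_controls,
                seed=derive_seed(cfg.seed, _ROAR, mi),
                method="kernel_shap_full", model_label=method,
            )
            result.to_csv(self._write(f"roar_{method}.csv"))

    def run(self) -> Path:
        """Execute all stages and write the run manifest."""
        self.stage_generate()
        self.stage_curate()
        self.stage_train()
        self.stage_explain()
        self.stage_compare()
        self.stage_roar()
        import scipy
        import sklearn

        manifest = {
            "config": self.config.to_dict(),
            "seed": self.config.seed,
            "outputs": sorted(set(self.outputs)),
            "versions": {
                "shapcompare": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }
        path = self.out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the path of the run manifest."""
    return Pipeline(config).run()
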