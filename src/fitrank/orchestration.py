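"""Config-driven end-to-end runs: simulate → preprocess → encode → replicate →
rank → validate, with all artifacts written to a run directory.

Classification runs produce ``replicates.csv``, ``decision_matrix.csv``,
``ranking_entropy.json``, ``ranking_subjective.json``, ``tukey.csv``,
``anova.json``, ``manova.json``, a ``manifest.json`` and a ``report.md``.
Regression runs produce ``regression_results.csv`` plus manifest/report.
Reruns with the same config reproduce every numeric output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import LabeledDataset
from .encoders import encode_by_name
from .exceptions import FitrankError, InvalidConfigError
from .mcda import build_decision_matrix, entropy_weights, subjective_weights, topsis_rank
from .metrics import CRITERIA, regression_metrics
from .modeling import (
    Alternative,
    ClassifierSpec,
    RegressorSpec,
    ReplicateTable,
    fit_regressor,
    run_replicates,
)
from .preprocessing import (
    build_labeled_dataset,
    clean_table,
    filter_ph,
    frequency_filter,
)
from .sampling import SplitSpec, stratified_split_indices
from .stats import anova_oneway, manova_pillai, tukey_table
from .synthetic_data import (
    AffibodySimConfig,
    NespSimConfig,
    simulate_affibody_library,
    simulate_enrichment_reads,
    simulate_nesp_like,
)

__all__ = ["ExperimentConfig", "run_experiment", "write_report", "SAMPLER_TAGS"]

#: Short sampler tags used in alternative ids.
SAMPLER_TAGS = {"none": "NS", "under": "US", "over": "RO", "smote": "SM"}


@dataclass(frozen=True)
class ExperimentConfig:
    task: str = "classification"  # classification | regression
    affibody: AffibodySimConfig = field(default_factory=AffibodySimConfig)
    nesp: NespSimConfig = field(default_factory=NespSimConfig)
    labeled_csv: str | None = None  # optional file source (sequence,label)
    encodings: tuple[str, ...] = ("onehot", "physchem", "mock64")
    samplers: tuple[str, ...] = ("under", "over", "smote")
    ensembles: tuple[str, ...] = ("vote", "concat")
    seeds: tuple[int, ...] = tuple(range(20))
    test_fraction: float = 0.2
    length_min: int | None = None
    length_max: int | None = None
    data_sizes: tuple[int, ...] | None = None
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    regressor: RegressorSpec = field(default_factory=RegressorSpec)
    smote_k: int = 5

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise InvalidConfigError(f"unknown task {self.task!r}")
        if len(set(self.seeds)) != len(self.seeds):
            raise InvalidConfigError("seeds must be unique")
        for combiner in self.ensembles:
            if combiner not in ("vote", "concat"):
                raise InvalidConfigError(f"unknown ensemble {combiner!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        if "affibody" in raw and isinstance(raw["affibody"], dict):
            aff = dict(raw["affibody"])
            if "variable_positions" in aff:
                aff["variable_positions"] = frozenset(aff["variable_positions"])
            raw["affibody"] = AffibodySimConfig(**aff)
        if "nesp" in raw and isinstance(raw["nesp"], dict):
            nesp = dict(raw["nesp"])
            for key in ("length_range", "ph_values"):
                if key in nesp:
                    nesp[key] = tuple(nesp[key])
            raw["nesp"] = NespSimConfig(**nesp)
        if "classifier" in raw and isinstance(raw["classifier"], dict):
            raw["classifier"] = ClassifierSpec(**raw["classifier"])
        if "regressor" in raw and isinstance(raw["regressor"], dict):
            reg = dict(raw["regressor"])
            for key in ("n_estimators_range", "max_depth_range"):
                if key in reg:
                    reg[key] = tuple(reg[key])
            raw["regressor"] = RegressorSpec(**reg)
        for key in ("encodings", "samplers", "ensembles", "seeds", "data_sizes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _json_default(obj):
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _build_classification_dataset(config: ExperimentConfig) -> LabeledDataset:
    if config.labeled_csv is not None:
        frame = pd.read_csv(config.labeled_csv)
        return LabeledDataset.from_frame(frame, source=config.labeled_csv)
    dataset, _ = simulate_affibody_library(config.affibody)
    naive, macs, facs = simulate_enrichment_reads(dataset, config.affibody)
    naive_clean, _ = clean_table(naive)
    macs_clean, _ = clean_table(macs)
    facs_clean, _ = clean_table(facs)
    return build_labeled_dataset(
        set(naive_clean.counts),
        frequency_filter(macs_clean),
        frequency_filter(facs_clean),
    )


def _length_filter(dataset: LabeledDataset, config: ExperimentConfig) -> LabeledDataset:
    if config.length_min is None and config.length_max is None:
        return dataset
    lo = config.length_min or 0
    hi = config.length_max or 10**9
    keep = [i for i, s in enumerate(dataset.sequences) if lo <= len(s) <= hi]
    return dataset.subset(keep)


def _alternatives(config: ExperimentConfig) -> list[Alternative]:
    alternatives = [
        Alternative(
            id=f"{name}_{SAMPLER_TAGS[sampler]}",
            encodings=(name,),
            sampler=sampler,
        )
        for name in config.encodings
        for sampler in config.samplers
    ]
    ensemble_encodings = tuple(config.encodings)
    if len(ensemble_encodings) >= 2:
        for combiner in config.ensembles:
            for sampler in config.samplers:
                alternatives.append(
                    Alternative(
                        id=f"{combiner}_{SAMPLER_TAGS[sampler]}",
                        encodings=ensemble_encodings,
                        sampler=sampler,
                        combine=combiner,
                    )
                )
    return alternatives


def _run_classification(config: ExperimentConfig, run_dir: Path) -> None:
    dataset = _length_filter(_build_classification_dataset(config), config)
    encodings = {
        name: encode_by_name(name, dataset.sequences, dataset.ids)
        for name in config.encodings
    }
    alternatives = _alternatives(config)
    replicates = run_replicates(
        encodings,
        dataset.labels,
        alternatives,
        config.seeds,
        split=SplitSpec(test_fraction=config.test_fraction),
        classifier=config.classifier,
        smote_k=config.smote_k,
    )
    replicates.frame.to_csv(run_dir / "replicates.csv", index=False)
    if replicates.failures:
        (run_dir / "failures.json").write_text(
            json.dumps(
                [
                    {"alternative": a, "seed": s, "error": e}
                    for a, s, e in replicates.failures
                ],
                indent=2,
            )
            + "\n"
        )

    matrix = build_decision_matrix(replicates)
    matrix.to_frame().to_csv(run_dir / "decision_matrix.csv", index=False)
    topsis_rank(matrix, entropy_weights(matrix)).write_json(
        run_dir / "ranking_entropy.json"
    )
    topsis_rank(matrix, subjective_weights()).write_json(
        run_dir / "ranking_subjective.json"
    )

    frame = replicates.frame
    f1_groups = {
        alt: group["F1"].to_numpy() for alt, group in frame.groupby("alternative")
    }
    f_stat, p_value = anova_oneway(f1_groups)
    (run_dir / "anova.json").write_text(
        json.dumps({"metric": "F1", "F": f_stat, "p": p_value}, indent=2) + "\n"
    )
    scores_by_metric = {
        metric: {
            alt: group[metric].to_numpy() for alt, group in frame.groupby("alternative")
        }
        for metric in CRITERIA
    }
    tukey_table(scores_by_metric).to_csv(run_dir / "tukey.csv", index=False)
    manova_groups = {
        alt: group[list(CRITERIA)].to_numpy()
        for alt, group in frame.groupby("alternative")
    }
    try:
        pillai, manova_p = manova_pillai(manova_groups)
        manova_payload = {"statistic": "Pillai", "value": pillai, "p": manova_p}
    except FitrankError as exc:
        manova_payload = {"statistic": "Pillai", "error": str(exc)}
    (run_dir / "manova.json").write_text(json.dumps(manova_payload, indent=2) + "\n")


def _run_regression(config: ExperimentConfig, run_dir: Path) -> None:
    table = filter_ph(simulate_nesp_like(config.nesp), ph=7.0)
    sequences = [str(s) for s in table.frame["sequence"]]
    targets = table.frame["tm"].to_numpy(dtype=float)
    dataset = _length_filter(
        LabeledDataset(
            ids=[f"nesp_{i:06d}" for i in range(len(sequences))],
            sequences=sequences,
            labels=targets,
            source="nesp-sim",
        ),
        config,
    )
    ragged = len({len(s) for s in dataset.sequences}) > 1
    encodings = [name for name in config.encodings if not (ragged and name == "onehot")]
    sizes = list(config.data_sizes) if config.data_sizes else [len(dataset)]
    rows = []
    for size in sizes:
        if size > len(dataset):
            raise InvalidConfigError(
                f"data size {size} exceeds available records {len(dataset)}"
            )
        for seed in config.seeds:
            rng = np.random.default_rng(seed)
            chosen = (
                np.sort(rng.choice(len(dataset), size=size, replace=False))
                if size < len(dataset)
                else np.arange(len(dataset))
            )
            cohort = dataset.subset(chosen)
            train_idx, test_idx = stratified_split_indices(
                np.zeros(len(cohort), dtype=int),
                SplitSpec(test_fraction=0.3, seed=seed, stratified=False),
            )
            for name in encodings:
                matrix = encode_by_name(name, cohort.sequences, cohort.ids)
                handle, params, val_report = fit_regressor(
                    matrix.values[train_idx],
                    cohort.labels[train_idx],
                    config.regressor,
                    seed=seed,
                )
                test_report = regression_metrics(
                    cohort.labels[test_idx], handle.predict(matrix.values[test_idx])
                )
                rows.append(
                    {
                        "encoding": name,
                        "data_size": size,
                        "seed": seed,
                        "n_estimators": params["n_estimators"],
                        "max_depth": params["max_depth"],
                        "val_MSE": val_report.mse,
                        "val_R2": val_report.r2,
                        "test_MSE": test_report.mse,
                        "test_R2": test_report.r2,
                    }
                )
    pd.DataFrame(rows).to_csv(run_dir / "regression_results.csv", index=False)


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Run the configured experiment, writing all artifacts under ``out_dir``."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "fitrank_version": __version__,
        "task": config.task,
        "seeds": list(config.seeds),
        "config": config.to_dict(),
    }
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default) + "\n"
    )
    if config.task == "classification":
        _run_classification(config, run_dir)
    else:
        _run_regression(config, run_dir)
    write_report(run_dir)
    return run_dir


#: Artifacts a complete classification run is expected to contain.
_CLASSIFICATION_ARTIFACTS = (
    "replicates.csv",
    "decision_matrix.csv",
    "ranking_entropy.json",
    "ranking_subjective.json",
    "tukey.csv",
    "anova.json",
    "manova.json",
)


def write_report(run_dir: str | Path) -> tuple[Path, list[str]]:
    """Render a human-readable summary of a run directory.

    Missing artifacts are listed as absent; the report is still produced.
    Returns (report path, list of missing artifact names). Regeneration is
    idempotent.
    """
    run_dir = Path(run_dir)
    lines = ["# Run report", ""]
    missing: list[str] = []

    manifest_path = run_dir / "manifest.json"
    task = None
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        task = manifest.get("task")
        lines += [
            f"- task: {task}",
            f"- seeds: {manifest.get('seeds')}",
            f"- fitrank version: {manifest.get('fitrank_version')}",
            "",
        ]
    else:
        missing.append("manifest.json")

    expected = (
        ("regression_results.csv",)
        if task == "regression"
        else _CLASSIFICATION_ARTIFACTS
    )
    for name in expected:
        if not (run_dir / name).exists():
            missing.append(name)

    replicates_path = run_dir / "replicates.csv"
    if replicates_path.exists():
        frame = pd.read_csv(replicates_path)
        summary = frame.groupby("alternative")[list(CRITERIA)].agg(["mean", "std"])
        lines += ["## Mean +/- SD per alternative", ""]
        for alt in summary.index:
            cells = ", ".join(
                f"{metric}={summary.loc[alt, (metric, 'mean')]:.4f}"
                f"+/-{summary.loc[alt, (metric, 'std')]:.4f}"
                for metric in CRITERIA
            )
            lines.append(f"- **{alt}**: {cells}")
        lines.append("")

    for scheme in ("entropy", "subjective"):
        path = run_dir / f"ranking_{scheme}.json"
        if path.exists():
            ranking = json.loads(path.read_text())
            lines += [f"## Ranking ({scheme} weights)", ""]
            for entry in sorted(ranking["alternatives"], key=lambda e: e["rank"]):
                lines.append(
                    f"{entry['rank']}. {entry['alternative']} "
                    f"(closeness {entry['closeness']:.4f})"
                )
            lines.append("")

    for name, label in (("anova.json", "ANOVA"), ("manova.json", "MANOVA")):
        path = run_dir / name
        if path.exists():
            payload = json.loads(path.read_text())
            lines += [f"## {label}", "", f"```{json.dumps(payload)}```", ""]

    tukey_path = run_dir / "tukey.csv"
    if tukey_path.exists():
        tukey = pd.read_csv(tukey_path)
        n_reject = int(tukey["reject"].sum())
        lines += [
            "## Tukey pairwise decisions",
            "",
            f"- {n_reject} of {len(tukey)} pairwise-metric comparisons rejected the null",
            "",
        ]

    regression_path = run_dir / "regression_results.csv"
    if regression_path.exists():
        frame = pd.read_csv(regression_path)
        summary = frame.groupby(["encoding", "data_size"])[["test_MSE", "test_R2"]].mean()
        lines += ["## Regression (test means)", "", summary.to_string(), ""]

    if missing:
        lines += ["## Missing artifacts", ""] + [f"- {name}" for name in missing] + [""]

    report_path = run_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path, missing
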