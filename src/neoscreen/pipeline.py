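"""End-to-end orchestration: simulate → reference intervals → cutoff screen →
features → train → risk-score assessment → evaluation, bound by one seeded,
replayable configuration.

The pipeline mirrors how a screening program would deploy the two schemes:
reference intervals come from the screening population itself, while the risk
models are trained on a separate case-enriched cohort (emulating the large
multi-site corpus a production model is trained on) and then applied to the
screening cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    DEFAULT_CARRIER_MULTIPLIER,
    Cohort,
    CohortValidationError,
    generate_cohort,
    load_baselines,
)
from .evaluation import (
    confusion_counts,
    diagnostic_metrics,
    incidence_denominator,
    positive_rate,
    zygosity_stratified_tp_rate,
)
from .features import cohort_medians, feature_frame
from .reference import (
    SUSPECTED,
    estimate_intervals,
    intervals_to_csv,
    outcomes_to_frame,
    run_two_tier,
    screen_panel,
)
from .registry import build_disease_registry
from .risk import (
    DEFAULT_ALGORITHMS,
    HIGH_RISK,
    assess_cohort,
    record_positive,
    save_bundle,
    train_risk_models,
)

logger = logging.getLogger("neoscreen")


@dataclass
class PipelineConfig:
    seed: int
    cohort_size: int = 50_000
    train_size: int = 30_000
    train_enrichment: float = 60.0
    registry_path: str | None = None
    baselines_path: str | None = None
    split_ratio: float = 0.8
    algorithms: Sequence[str] = DEFAULT_ALGORITHMS
    carrier_multiplier: float = DEFAULT_CARRIER_MULTIPLIER
    recall_multiplier: float = 5.0
    retest_correlation: float = 0.8
    output_dir: str = "neoscreen_run"
    save_models: bool = False

    def validate(self) -> None:
        if self.cohort_size <= 0:
            raise CohortValidationError("cohort_size must be positive")
        if self.train_size <= 0:
            raise CohortValidationError("train_size must be positive")
        if not 0 < self.split_ratio < 1:
            raise CohortValidationError("split_ratio must lie in (0, 1)")
        if not 0 <= self.retest_correlation <= 1:
            raise CohortValidationError("retest_correlation must lie in [0, 1]")
        for path in (self.registry_path, self.baselines_path):
            if path is not None and not Path(path).exists():
                raise CohortValidationError(f"path not found: {path}")


@dataclass
class RunManifest:
    config: dict
    hashes: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_cohort(path: str | Path) -> Cohort:
    return Cohort.from_csv(path)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.to_csv(path)


def evaluate_run(
    cohort: Cohort,
    outcomes_frame: pd.DataFrame,
    ml_positive: pd.Series,
    registry,
) -> dict:
    """Evaluation report comparing the cutoff branch and the risk-score branch.

    Mirrors the study design: both schemes are compared on initial positive
    rate over the whole cohort, and on diagnostic metrics within the
    'suspected' subset (cutoff-positive subjects whose secondary screen stayed
    abnormal — the pool that would be referred for confirmatory sequencing),
    where truth counts both affected subjects and carriers as positive.
    """
    n = len(cohort)
    truth_positive = (~cohort.truth_disease.isna()).to_numpy()
    ml_pos = ml_positive.reindex(cohort.frame["id"]).fillna(False).to_numpy(dtype=bool)
    cutoff_pos = (outcomes_frame["initial_result"] == "positive").to_numpy()

    report: dict = {
        "n_screened": n,
        "initial_positive": {
            "reference_interval": int(cutoff_pos.sum()),
            "ml_system": int(ml_pos.sum()),
        },
        "positive_rate": {
            "reference_interval": positive_rate(int(cutoff_pos.sum()), n),
            "ml_system": positive_rate(int(ml_pos.sum()), n),
        },
    }

    suspected = (outcomes_frame["secondary_result"] == SUSPECTED).to_numpy()
    report["n_suspected"] = int(suspected.sum())
    if suspected.any():
        truth_s = truth_positive[suspected]
        metrics = {}
        for method, pred in (
            ("reference_interval", cutoff_pos[suspected]),
            ("ml_system", ml_pos[suspected]),
        ):
            tally = confusion_counts(pred, truth_s)
            m = diagnostic_metrics(tally).rounded()
            metrics[method] = {
                "tp": tally.tp, "fp": tally.fp, "tn": tally.tn, "fn": tally.fn,
                **m.as_dict(),
            }
        report["suspected_metrics"] = metrics
        n_cases = int(truth_s.sum())
        if n_cases:
            report["incidence_denominator"] = incidence_denominator(n_cases, n)
        strata = zygosity_stratified_tp_rate(
            cohort.truth_disease[suspected],
            cohort.truth_zygosity[suspected],
            ml_pos[suspected],
        )
        report["ml_zygosity_tp"] = {
            f"{d}/{z}": {"detected": r.n_detected, "total": r.n_total}
            for (d, z), r in strata.items()
        }

    # whole-cohort sensitivity by zygosity (simulation ground truth is known
    # for every subject, unlike the sequenced subset of a real program)
    for zyg in ("affected", "carrier"):
        mask = (cohort.truth_zygosity == zyg).to_numpy()
        if mask.any():
            report[f"sensitivity_{zyg}"] = {
                "reference_interval": positive_rate(int(cutoff_pos[mask].sum()), int(mask.sum())),
                "ml_system": positive_rate(int(ml_pos[mask].sum()), int(mask.sum())),
            }
    return report


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write artifacts plus a manifest to the output
    directory. Identical configs produce identical artifact hashes."""
    config.validate()
    started = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    registry = build_disease_registry(config.registry_path)
    baselines = load_baselines(config.baselines_path)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    seed_eval, seed_train, seed_retest, seed_model = seeds

    stage = "simulate"
    try:
        logger.info("simulating screening cohort (n=%d, seed=%d)", config.cohort_size, seed_eval)
        cohort = generate_cohort(
            config.cohort_size, registry, baselines, seed=seed_eval,
            carrier_multiplier=config.carrier_multiplier,
        )
        logger.info(
            "simulating training cohort (n=%d, enrichment=%.0fx)",
            config.train_size, config.train_enrichment,
        )
        train_cohort = generate_cohort(
            config.train_size, registry, baselines, seed=seed_train,
            carrier_multiplier=config.carrier_multiplier,
            enrichment=config.train_enrichment, id_prefix="T",
        )
        cohort.to_csv(outdir / "cohort.csv")

        stage = "intervals"
        intervals = estimate_intervals(cohort)
        intervals_to_csv(intervals, outdir / "intervals.csv")

        stage = "screen"
        outcomes = run_two_tier(
            cohort, intervals, registry,
            retest_correlation=config.retest_correlation,
            seed=seed_retest, baselines=baselines,
        )
        oframe = outcomes_to_frame(outcomes)
        oframe.to_csv(outdir / "outcomes.csv", index=False)

        stage = "features"
        medians = cohort_medians(train_cohort)
        train_features = feature_frame(train_cohort, medians)
        eval_features = feature_frame(cohort, medians)

        stage = "train"
        bundle = train_risk_models(
            train_features,
            train_cohort.truth_disease,
            registry,
            algorithms=config.algorithms,
            seed=seed_model,
            ratio=config.split_ratio,
            recall_multiplier=config.recall_multiplier,
        )
        logger.info(
            "trained %d disease models (skipped: %s)",
            len(bundle.models), ", ".join(bundle.skipped) or "none",
        )
        if config.save_models:
            save_bundle(bundle, outdir / "models")

        stage = "assess"
        assessments = assess_cohort(
            eval_features, bundle.models, bundle.calibrations, bundle.thresholds,
            record_ids=cohort.frame["id"],
        )
        ml_positive = record_positive(assessments)
        pred = pd.DataFrame(
            {"id": cohort.frame["id"],
             "ml_positive": ml_positive.reindex(cohort.frame["id"]).fillna(False).to_numpy()}
        )
        pred.to_csv(outdir / "ml_predictions.csv", index=False)

        stage = "evaluate"
        report = evaluate_run(cohort, oframe, ml_positive, registry)
        report["skipped_diseases"] = list(bundle.skipped)
        report["thresholds"] = bundle.thresholds
        (outdir / "report.json").write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config=_jsonable(dataclasses.asdict(config)),
        hashes={
            name: _sha256(outdir / name)
            for name in ("cohort.csv", "intervals.csv", "outcomes.csv",
                         "ml_predictions.csv", "report.json")
        },
        started=started,
        finished=time.time(),
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
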