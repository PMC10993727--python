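"""Published counts from the 309,102-newborn screening comparison and helpers
that push them back through the evaluation module.

The packaged count table holds only integer counts (confusion cells, per
disease detected/total, zygosity strata, screening totals); every percentage,
rate and incidence ratio is recomputed here from those counts.
"""

from __future__ import annotations

import importlib.resources
import json
from typing import Mapping

import numpy as np

from .evaluation import (
    ConfusionCounts,
    DiseaseRateRow,
    confusion_counts,
    diagnostic_metrics,
    incidence_ratio,
    per_disease_rates,
    positive_rate,
    round_half_up,
    zygosity_stratified_tp_rate,
)


def load_study_counts() -> dict:
    text = importlib.resources.files("neoscreen.data").joinpath("study_counts.json").read_text()
    return json.loads(text)


def _vectors_from_confusion(c: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Expand a 2×2 count table into predicted/truth vectors."""
    predicted = np.concatenate(
        [
            np.ones(c["tp"], bool), np.ones(c["fp"], bool),
            np.zeros(c["tn"], bool), np.zeros(c["fn"], bool),
        ]
    )
    truth = np.concatenate(
        [
            np.ones(c["tp"], bool), np.zeros(c["fp"], bool),
            np.zeros(c["tn"], bool), np.ones(c["fn"], bool),
        ]
    )
    return predicted, truth


def reproduce_published_metrics(counts: dict | None = None) -> dict:
    """Recompute every published percentage, rate and ratio from raw counts.

    Returns a nested dict: per-method diagnostic metrics among the suspected
    cases, per-disease false-negative rates for both schemes, zygosity-
    stratified true-positive rates, initial positive rates and incidence
    ratios. All values are full-precision floats rounded half-up to 2 dp,
    matching table conventions.
    """
    counts = load_study_counts() if counts is None else counts
    out: dict = {"metrics": {}, "fn_rates": {}, "tp_rates": {}, "positive_rates": {},
                 "incidence": {}}

    for method in ("ml_system", "reference_interval"):
        pred, truth = _vectors_from_confusion(counts["confusion"][method])
        tally = confusion_counts(pred, truth)
        metrics = diagnostic_metrics(tally).rounded()
        out["metrics"][method] = {"counts": tally, **metrics.as_dict()}

    for method, key in (("ml_system", "ml_detected"), ("reference_interval", "ri_detected")):
        truth_vec: list[str] = []
        det_vec: list[bool] = []
        for row in counts["per_disease"]:
            truth_vec.extend([row["disease"]] * row["total"])
            det_vec.extend([True] * row[key] + [False] * (row["total"] - row[key]))
        rows = per_disease_rates(truth_vec, det_vec,
                                 diseases=[r["disease"] for r in counts["per_disease"]])
        out["fn_rates"][method] = {r.disease: round_half_up(r.fn_rate) for r in rows}

    truth_d: list[str] = []
    truth_z: list[str] = []
    det: list[bool] = []
    for row in counts["zygosity_tp"]:
        truth_d.extend([row["disease"]] * row["total"])
        truth_z.extend([row["zygosity"]] * row["total"])
        det.extend([True] * row["detected"] + [False] * (row["total"] - row["detected"]))
    strata = zygosity_stratified_tp_rate(truth_d, truth_z, det)
    out["tp_rates"] = {
        f"{d}/{z}": round_half_up(r.tp_rate) for (d, z), r in strata.items()
    }
    pooled = counts["pooled_zygosity_tp"]
    out["tp_rates"]["pooled/affected"] = round_half_up(
        DiseaseRateRow("ALL", pooled["affected"]["detected"], pooled["affected"]["total"]).tp_rate
    )
    out["tp_rates"]["pooled/carrier"] = round_half_up(
        DiseaseRateRow("ALL", pooled["carrier"]["detected"], pooled["carrier"]["total"]).tp_rate
    )

    n = counts["n_screened"]
    out["positive_rates"] = {
        "reference_interval": round_half_up(
            positive_rate(counts["initial_positive"]["reference_interval"], n)
        ),
        "ml_system": round_half_up(positive_rate(counts["initial_positive"]["ml_system"], n)),
    }
    out["incidence"] = {
        name: incidence_ratio(entry["cases"], entry["screened"])
        for name, entry in counts["incidence"].items()
    }
    return out
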