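"""Diagnostic-efficiency evaluation: confusion counts, sensitivity /
specificity / PPV / NPV / accuracy, per-disease false-negative rates,
zygosity-stratified true-positive rates, screening positive rates and
incidence ratios.

All quantities are computed at full precision; rounding (half-up, two
decimals, matching how screening programs print their tables) happens only in
the presentation helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import AFFECTED, CARRIER


class EvaluationError(ValueError):
    pass


def round_half_up(value: float, digits: int = 2) -> float:
    """Round half away from zero at ``digits`` decimals (table convention)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise EvaluationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predicted: Sequence, truth: Sequence) -> ConfusionCounts:
    """Standard 2×2 tally of binary predictions against binary truth."""
    p = np.asarray(predicted).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise EvaluationError(f"length mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The five rates, as percentages; ``None`` where the denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float

    def rounded(self, digits: int = 2) -> "DiagnosticMetrics":
        r = lambda v: None if v is None else round_half_up(v, digits)
        return DiagnosticMetrics(
            sensitivity=r(self.sensitivity),
            specificity=r(self.specificity),
            ppv=r(self.ppv),
            npv=r(self.npv),
            accuracy=round_half_up(self.accuracy, digits),
        )

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); PPV = TP/(TP+FP);
    NPV = TN/(TN+FN); accuracy = (TP+TN)/total — each ×100."""
    if counts.total == 0:
        raise EvaluationError("all confusion counts are zero")

    def rate(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return DiagnosticMetrics(
        sensitivity=rate(counts.tp, counts.tp + counts.fn),
        specificity=rate(counts.tn, counts.tn + counts.fp),
        ppv=rate(counts.tp, counts.tp + counts.fp),
        npv=rate(counts.tn, counts.tn + counts.fn),
        accuracy=100.0 * (counts.tp + counts.tn) / counts.total,
    )


@dataclass(frozen=True)
class DiseaseRateRow:
    disease: str
    n_detected: int
    n_total: int

    @property
    def fn_rate(self) -> float:
        if self.n_total == 0:
            raise EvaluationError(f"{self.disease}: no true cases")
        return 100.0 * (1.0 - self.n_detected / self.n_total)

    @property
    def tp_rate(self) -> float:
        return 100.0 * self.n_detected / self.n_total


def per_disease_rates(
    truth_disease: Sequence,
    detected: Sequence,
    diseases: Sequence[str] | None = None,
) -> list[DiseaseRateRow]:
    """Detected counts and false-negative rates among true cases, per disease.

    ``truth_disease`` holds each subject's confirmed disease (None/'' for
    none); ``detected`` marks whether the method called that subject positive.
    """
    truth = pd.Series(list(truth_disease))
    det = np.asarray(detected).astype(bool)
    if len(truth) != len(det):
        raise EvaluationError("length mismatch between truth and detections")
    is_case = ~(truth.isna() | (truth == ""))
    order = diseases if diseases is not None else sorted(truth[is_case].unique())
    rows = []
    for d in order:
        mask = (truth == d).to_numpy()
        rows.append(
            DiseaseRateRow(disease=d, n_detected=int(det[mask].sum()), n_total=int(mask.sum()))
        )
    return rows


def zygosity_stratified_tp_rate(
    truth_disease: Sequence,
    truth_zygosity: Sequence,
    detected: Sequence,
) -> dict[tuple[str, str], DiseaseRateRow]:
    """Detected/total per (disease, zygosity) stratum, plus pooled affected
    and pooled carrier rows under the pseudo-disease key ``'ALL'``."""
    truth = pd.Series(list(truth_disease))
    zyg = pd.Series(list(truth_zygosity))
    det = np.asarray(detected).astype(bool)
    if not (len(truth) == len(zyg) == len(det)):
        raise EvaluationError("length mismatch among inputs")
    is_case = ~(truth.isna() | (truth == ""))
    out: dict[tuple[str, str], DiseaseRateRow] = {}
    for d in sorted(truth[is_case].unique()):
        for z in (AFFECTED, CARRIER):
            mask = ((truth == d) & (zyg == z)).to_numpy()
            if mask.sum() == 0:
                continue  # empty stratum: not available
            out[(d, z)] = DiseaseRateRow(d, int(det[mask].sum()), int(mask.sum()))
    for z in (AFFECTED, CARRIER):
        mask = (is_case & (zyg == z)).to_numpy()
        if mask.sum():
            out[("ALL", z)] = DiseaseRateRow("ALL", int(det[mask].sum()), int(mask.sum()))
    return out


def positive_rate(n_positive: int, n_screened: int) -> float:
    """Screen-positive percentage."""
    if n_screened <= 0:
        raise EvaluationError("n_screened must be positive")
    if not 0 <= n_positive <= n_screened:
        raise EvaluationError("n_positive must lie in [0, n_screened]")
    return 100.0 * n_positive / n_screened


def incidence_denominator(n_cases: int, n_screened: int) -> int:
    if n_cases <= 0:
        raise EvaluationError("n_cases must be positive")
    return int(round(n_screened / n_cases))


def incidence_ratio(n_cases: int, n_screened: int) -> str:
    """Incidence as the conventional '1:N' string (N = rounded screened/cases)."""
    return f"1:{incidence_denominator(n_cases, n_screened):,}"


def metrics_table(counts_by_method: Mapping[str, ConfusionCounts]) -> pd.DataFrame:
    """Per-method confusion counts and rounded metrics as one tidy table."""
    rows = []
    for method, counts in counts_by_method.items():
        m = diagnostic_metrics(counts).rounded()
        rows.append(
            {
                "method": method,
                "tn": counts.tn, "tp": counts.tp, "fn": counts.fn, "fp": counts.fp,
                **{k: v for k, v in m.as_dict().items()},
            }
        )
    return pd.DataFrame(rows)
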