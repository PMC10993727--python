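"""Cutoff-scheme screening: nonparametric reference intervals and the
two-tier screen → recall → secondary-screen workflow.

Reference intervals follow the standard nonparametric rank convention for
clinical reference limits: for percentile p on n sorted values the target
rank is ``r = p/100 * (n + 1)``, linearly interpolated between adjacent order
statistics and clamped to ``[1, n]``. A disease is flagged only when one of
its marker analytes violates the interval on the disease's deviation side
(raised markers on the high side, lowered markers on the low side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort, ScreeningRecord, baseline_marginal, class_marginal, load_baselines
from .registry import AFFECTED, CARRIER, HIGH, DiseaseDefinition

POSITIVE = "positive"
NEGATIVE = "negative"
SUSPECTED = "suspected"
CLEARED = "cleared"
NOT_APPLICABLE = "not-applicable"

#: Below this source-sample size a nonparametric interval is statistically
#: unreliable and the estimate is flagged (clinical guidance commonly asks
#: for at least 120 reference subjects).
DEFAULT_MIN_N = 120


@dataclass(frozen=True)
class ReferenceInterval:
    analyte: str
    lower: float
    upper: float
    n_source: int
    reliable: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError(f"{self.analyte}: interval bounds must be finite")
        if self.lower > self.upper:
            raise ValueError(f"{self.analyte}: lower {self.lower} > upper {self.upper}")


@dataclass
class ScreenOutcome:
    record_id: str
    initial_result: str
    recalled: bool
    secondary_result: str
    flagged_diseases: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.recalled and self.initial_result != POSITIVE:
            raise ValueError("only initial positives can be recalled")
        if self.secondary_result != NOT_APPLICABLE and not self.recalled:
            raise ValueError("secondary result requires a recall")


def _rank_percentile(sorted_values: np.ndarray, pct: float) -> float:
    n = len(sorted_values)
    r = np.clip(pct / 100.0 * (n + 1), 1.0, float(n))
    lo = int(np.floor(r)) - 1
    hi = min(lo + 1, n - 1)
    frac = r - np.floor(r)
    return float(sorted_values[lo] + frac * (sorted_values[hi] - sorted_values[lo]))


def estimate_reference_interval(
    values: Sequence[float],
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
    analyte: str = "",
    min_n: int = DEFAULT_MIN_N,
) -> ReferenceInterval:
    """Nonparametric percentile reference interval from raw values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot estimate a reference interval from no values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("reference values must be finite")
    if not (0 < lower_pct < upper_pct < 100):
        raise ValueError("percentiles must satisfy 0 < lower < upper < 100")
    reliable = arr.size >= min_n
    if not reliable:
        warnings.warn(
            f"reference interval for {analyte or 'analyte'} estimated from only "
            f"{arr.size} values (< {min_n}); flagged unreliable",
            stacklevel=2,
        )
    s = np.sort(arr)
    return ReferenceInterval(
        analyte=analyte,
        lower=_rank_percentile(s, lower_pct),
        upper=_rank_percentile(s, upper_pct),
        n_source=int(arr.size),
        reliable=reliable,
    )


def estimate_intervals(
    cohort: Cohort,
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
    min_n: int = DEFAULT_MIN_N,
) -> dict[str, ReferenceInterval]:
    """Per-analyte intervals estimated from a whole cohort."""
    panel = cohort.panel_matrix()
    return {
        analyte: estimate_reference_interval(
            panel[analyte].to_numpy(), lower_pct, upper_pct, analyte=analyte, min_n=min_n
        )
        for analyte in cohort.analytes
    }


def intervals_to_csv(intervals: Mapping[str, ReferenceInterval], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"analyte": iv.analyte, "lower": iv.lower, "upper": iv.upper,
             "n_source": iv.n_source, "reliable": iv.reliable}
            for iv in intervals.values()
        ]
    ).to_csv(path, index=False)


def intervals_from_csv(path: str | Path) -> dict[str, ReferenceInterval]:
    frame = pd.read_csv(path)
    return {
        row.analyte: ReferenceInterval(
            analyte=row.analyte, lower=row.lower, upper=row.upper,
            n_source=int(row.n_source), reliable=bool(getattr(row, "reliable", True)),
        )
        for row in frame.itertuples(index=False)
    }


def _disease_flag_mask(
    panel: pd.DataFrame,
    intervals: Mapping[str, ReferenceInterval],
    disease: DiseaseDefinition,
) -> np.ndarray:
    """Boolean vector: disease flagged for each row of the panel matrix."""
    flagged = np.zeros(len(panel), dtype=bool)
    for marker in disease.markers:
        if marker.analyte not in panel.columns:
            raise KeyError(f"record panel missing marker analyte {marker.analyte!r}")
        if marker.analyte not in intervals:
            raise KeyError(f"no reference interval for marker analyte {marker.analyte!r}")
        iv = intervals[marker.analyte]
        values = panel[marker.analyte].to_numpy()
        if marker.direction == HIGH:
            flagged |= values > iv.upper
        else:
            flagged |= values < iv.lower
    return flagged


def screen_panel(
    panel: pd.DataFrame,
    intervals: Mapping[str, ReferenceInterval],
    registry: Sequence[DiseaseDefinition],
) -> pd.DataFrame:
    """Vectorized initial screen: one row per subject, one column per disease."""
    flags = {d.abbreviation: _disease_flag_mask(panel, intervals, d) for d in registry}
    out = pd.DataFrame(flags, index=panel.index)
    out["initial_positive"] = out.any(axis=1) if len(registry) else np.zeros(len(panel), bool)
    return out


def screen_record(
    record: ScreeningRecord,
    intervals: Mapping[str, ReferenceInterval],
    registry: Sequence[DiseaseDefinition],
) -> tuple[str, tuple[str, ...]]:
    """Screen a single record; returns (initial result, flagged diseases)."""
    panel = pd.DataFrame([record.panel])
    flags = screen_panel(panel, intervals, registry)
    flagged = tuple(d.abbreviation for d in registry if bool(flags.iloc[0][d.abbreviation]))
    return (POSITIVE if flagged else NEGATIVE), flagged


def _redraw_correlated(
    cohort: Cohort,
    mask: np.ndarray,
    registry: Sequence[DiseaseDefinition],
    baselines: pd.DataFrame,
    rho: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gaussian-copula correlated re-draw of the panel for masked subjects.

    Each analyte value is mapped to a normal score through its generating
    marginal (baseline log-normal, or the subject's disease-class marginal for
    marker analytes), mixed with fresh noise at correlation ``rho``, and mapped
    back through the same marginal.
    """
    sub = cohort.frame.loc[mask].reset_index(drop=True)
    panel = sub.loc[:, list(cohort.analytes)].copy()
    if rho == 1.0:
        return panel
    eps = 1e-12
    noise = rng.standard_normal(panel.shape)
    by_abbr = {d.abbreviation: d for d in registry}

    for j, analyte in enumerate(cohort.analytes):
        row = baselines.loc[analyte]
        base = baseline_marginal(float(row["median"]), float(row["log_sd"]))
        x1 = panel[analyte].to_numpy(dtype=float)
        # marginal per subject: baseline unless this analyte marks their disease
        dists = np.zeros(len(sub), dtype=int)  # 0 = baseline
        specials = []
        for abbr, d in by_abbr.items():
            for zyg in (AFFECTED, CARRIER):
                params = d.params_for(zyg)
                if analyte not in params:
                    continue
                grp = (sub["truth_disease"] == abbr) & (sub["truth_zygosity"] == zyg)
                if grp.any():
                    specials.append((grp.to_numpy(), class_marginal(params[analyte])))
        z1 = norm.ppf(np.clip(base.cdf(x1), eps, 1 - eps))
        z2 = rho * z1 + np.sqrt(1 - rho**2) * noise[:, j]
        x2 = base.ppf(norm.cdf(z2))
        for grp_mask, dist in specials:
            zg = norm.ppf(np.clip(dist.cdf(x1[grp_mask]), eps, 1 - eps))
            z2g = rho * zg + np.sqrt(1 - rho**2) * noise[grp_mask, j]
            x2[grp_mask] = dist.ppf(norm.cdf(z2g))
        panel[analyte] = np.maximum(x2, 0.0)
    return panel


def run_two_tier(
    cohort: Cohort,
    intervals: Mapping[str, ReferenceInterval],
    registry: Sequence[DiseaseDefinition],
    retest_correlation: float = 0.8,
    seed: int = 0,
    baselines: pd.DataFrame | None = None,
) -> list[ScreenOutcome]:
    """Initial screen, recall of positives, and a simulated secondary screen.

    The secondary specimen is a correlated re-draw of the first panel
    (Gaussian copula, correlation ``retest_correlation``); a recalled subject
    is ``suspected`` when the re-drawn panel still flags any disease.
    """
    if not 0 <= retest_correlation <= 1:
        raise ValueError("retest_correlation must lie in [0, 1]")
    baselines = load_baselines() if baselines is None else baselines
    rng = np.random.default_rng(seed)

    panel = cohort.panel_matrix()
    initial = screen_panel(panel, intervals, registry)
    pos_mask = initial["initial_positive"].to_numpy()

    secondary_flagged = np.zeros(len(cohort), dtype=bool)
    if pos_mask.any():
        redrawn = _redraw_correlated(
            cohort, pos_mask, registry, baselines, retest_correlation, rng
        )
        second = screen_panel(redrawn, intervals, registry)
        secondary_flagged[pos_mask] = second["initial_positive"].to_numpy()

    outcomes = []
    disease_cols = [d.abbreviation for d in registry]
    flag_matrix = initial[disease_cols].to_numpy() if disease_cols else np.zeros((len(cohort), 0), bool)
    ids = cohort.frame["id"].tolist()
    for i in range(len(cohort)):
        positive = bool(pos_mask[i])
        flagged = tuple(np.array(disease_cols)[flag_matrix[i]]) if positive else ()
        outcomes.append(
            ScreenOutcome(
                record_id=ids[i],
                initial_result=POSITIVE if positive else NEGATIVE,
                recalled=positive,
                secondary_result=(
                    (SUSPECTED if secondary_flagged[i] else CLEARED)
                    if positive
                    else NOT_APPLICABLE
                ),
                flagged_diseases=flagged,
            )
        )
    return outcomes


def outcomes_to_frame(outcomes: Sequence[ScreenOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": o.record_id,
                "initial_result": o.initial_result,
                "recalled": o.recalled,
                "secondary_result": o.secondary_result,
                "flagged_diseases": ";".join(o.flagged_diseases),
            }
            for o in outcomes
        ],
        columns=["record_id", "initial_result", "recalled", "secondary_result", "flagged_diseases"],
    )
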