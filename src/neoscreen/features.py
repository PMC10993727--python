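"""Multiple-of-median (MoM) standardization and feature construction.

MoM divides each analyte concentration by the population median of that
analyte, giving a dimensionless ratio that removes laboratory and regional
scale shifts — the same normalization used throughout prenatal and neonatal
screening. Feature vectors for the risk models combine the analyte MoMs with
gestational age, blood-collection interval and birth weight.

Feature ranking uses information gain (mutual information of a discretized
feature with the binary label, in bits) followed by a Pearson-correlation
redundancy filter.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, Covariates
from .panel import DEFAULT_ANALYTES

COVARIATE_FEATURES = ("gestational_age_weeks", "collection_interval_d", "birth_weight_g")


class FeatureError(ValueError):
    pass


def cohort_medians(cohort: Cohort) -> pd.Series:
    """Per-analyte medians of a cohort, the default MoM denominators."""
    return cohort.panel_matrix().median(axis=0)


def compute_mom(
    panel: Mapping[str, float] | pd.DataFrame,
    medians: Mapping[str, float] | pd.Series,
) -> dict[str, float] | pd.DataFrame:
    """MoM(a) = concentration(a) / median(a), for a single panel or a matrix."""
    meds = pd.Series(medians, dtype=float)
    bad = meds[meds <= 0]
    if len(bad):
        raise FeatureError(
            f"non-positive median for analyte(s): {', '.join(bad.index.astype(str))}"
        )
    if isinstance(panel, pd.DataFrame):
        return panel.loc[:, meds.index] / meds
    return {a: float(panel[a]) / float(meds[a]) for a in meds.index if a in panel}


def assemble_features(
    mom: Mapping[str, float],
    covariates: Covariates,
    analytes: Sequence[str] = DEFAULT_ANALYTES,
) -> tuple[list[str], np.ndarray]:
    """One subject's feature vector: analyte MoMs in panel order, then
    gestational age, collection interval and birth weight."""
    missing = [a for a in analytes if a not in mom]
    if missing:
        raise FeatureError(f"MoM profile missing analytes: {', '.join(missing)}")
    names = [f"{a}_mom" for a in analytes] + list(COVARIATE_FEATURES)
    values = np.array(
        [mom[a] for a in analytes]
        + [covariates.gestational_age, covariates.collection_interval, covariates.birth_weight],
        dtype=float,
    )
    return names, values


def feature_frame(cohort: Cohort, medians: Mapping[str, float] | pd.Series | None = None) -> pd.DataFrame:
    """Vectorized feature matrix for a whole cohort.

    ``medians`` defaults to the cohort's own medians; supply external medians
    to harmonize a cohort against a reference laboratory.
    """
    meds = cohort_medians(cohort) if medians is None else pd.Series(medians, dtype=float)
    mom = compute_mom(cohort.panel_matrix(), meds)
    mom.columns = [f"{a}_mom" for a in mom.columns]
    covs = cohort.frame.loc[:, list(COVARIATE_FEATURES)].astype(float)
    return pd.concat([mom, covs.set_axis(mom.index)], axis=1)


def _discretize(values: np.ndarray, bins: int) -> np.ndarray:
    """Quantile-bin a feature; already-discrete features are left as is."""
    uniq = np.unique(values)
    if len(uniq) <= bins:
        return np.searchsorted(uniq, values)
    edges = np.unique(np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(values, edges)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(feature: Sequence, labels: Sequence, bins: int = 10) -> float:
    """IG = H(labels) − Σ_v p(v) H(labels | feature = v), in bits.

    Continuous features are discretized into ``bins`` quantile bins.
    """
    x = np.asarray(feature)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise FeatureError(f"feature length {x.shape[0]} != label length {y.shape[0]}")
    if x.shape[0] == 0:
        raise FeatureError("empty inputs")
    if np.issubdtype(x.dtype, np.number):
        x = _discretize(x.astype(float), bins)
    h = _entropy(y)
    cond = 0.0
    for v in np.unique(x):
        mask = x == v
        cond += mask.mean() * _entropy(y[mask])
    return max(h - cond, 0.0)


def select_features(
    features: pd.DataFrame,
    labels: Sequence,
    ig_threshold: float = 0.001,
    redundancy_r: float = 0.95,
    bins: int = 10,
) -> list[str]:
    """Rank features by information gain and drop redundant ones.

    Features are sorted by IG (descending, ties broken by name), features
    below ``ig_threshold`` bits are discarded, and a feature is dropped when
    its absolute Pearson correlation with an already-kept feature exceeds
    ``redundancy_r``.
    """
    if ig_threshold < 0:
        raise FeatureError("ig_threshold must be >= 0")
    if not 0 < redundancy_r <= 1:
        raise FeatureError("redundancy_r must lie in (0, 1]")
    y = np.asarray(labels)
    gains = {}
    disc = {}
    for name in features.columns:
        values = features[name].to_numpy(dtype=float)
        gains[name] = information_gain(values, y, bins=bins)
        disc[name] = _discretize(values, bins).astype(float)
    ranked = sorted(gains, key=lambda name: (-gains[name], name))
    kept: list[str] = []
    for name in ranked:
        if gains[name] < ig_threshold:
            break
        # redundancy filter: Pearson correlation on the discretized scale
        if all(abs(_safe_corr(disc[name], disc[other])) <= redundancy_r for other in kept):
            kept.append(name)
    if not kept:
        import warnings

        warnings.warn("no feature exceeded the information-gain threshold", stacklevel=2)
    return kept


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
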