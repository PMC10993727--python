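"""Seeded synthetic screening cohorts.

Healthy analyte concentrations are drawn from log-normal baselines (median and
log-scale sd per analyte), the standard right-skewed positive model for
metabolite panels. For affected and carrier subjects the disease's marker
analytes are instead drawn from a class-specific marginal that reproduces the
configured mean ± SD *exactly*:

* a zero-truncated normal whose parent parameters are solved so that the
  post-truncation moments equal the configured ones (the configured values are
  sample statistics of observed, necessarily non-negative, concentrations);
* a moment-matched log-normal when no zero-truncated normal can realize the
  configured coefficient of variation (a truncated normal requires mean/sd
  strictly above 1; e.g. a carrier class with sd comparable to its mean).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import norm

from .panel import DEFAULT_ANALYTES, validate_panel
from .registry import (
    AFFECTED,
    CARRIER,
    UNAFFECTED,
    ClassParams,
    DiseaseDefinition,
    build_disease_registry,
    registry_by_abbr,
    total_prevalence,
)

#: Default ratio of carrier prevalence to affected prevalence per disease,
#: set so carriers slightly outnumber affected among confirmed positives
#: (80 carriers vs 72 affected).
DEFAULT_CARRIER_MULTIPLIER = 80.0 / 72.0

COVARIATE_COLUMNS = (
    "gestational_age_weeks",
    "birth_weight_g",
    "collection_interval_d",
    "sex",
    "feeding",
)

TRUTH_COLUMNS = ("truth_disease", "truth_zygosity")


class CohortValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Covariates:
    gestational_age: float  # weeks
    birth_weight: float  # grams
    collection_interval: float  # days from birth to blood draw
    sex: str
    feeding: str

    def __post_init__(self) -> None:
        if not 24 <= self.gestational_age <= 44:
            raise CohortValidationError(
                f"gestational age {self.gestational_age} outside [24, 44] weeks"
            )
        if self.birth_weight <= 0:
            raise CohortValidationError("birth weight must be positive")
        if self.collection_interval < 0:
            raise CohortValidationError("collection interval must be >= 0")


@dataclass(frozen=True)
class ScreeningRecord:
    id: str
    covariates: Covariates
    panel: Mapping[str, float]
    truth_disease: str | None = None
    truth_zygosity: str = UNAFFECTED

    def __post_init__(self) -> None:
        if (self.truth_disease is None) != (self.truth_zygosity == UNAFFECTED):
            raise CohortValidationError(
                "truth_zygosity must be 'unaffected' exactly when truth_disease is absent"
            )


class _Degenerate:
    """Point-mass marginal used when a class sd is zero."""

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size: int = 1, random_state=None) -> np.ndarray:
        return np.full(size, self.value)

    def cdf(self, x):
        return np.where(np.asarray(x) < self.value, 0.0, 1.0)

    def ppf(self, q):
        return np.full_like(np.asarray(q, dtype=float), self.value)


@functools.lru_cache(maxsize=256)
def _truncnorm_parent_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated normal with given truncated moments.

    Solved on the standardized truncation point alpha = -mu/sigma using the
    classical truncated-normal moment identities, with the hazard lambda(alpha)
    evaluated in log space for stability deep in either tail.
    """

    target = mean / sd

    def hazard(a: float) -> float:
        return float(np.exp(norm.logpdf(a) - norm.logsf(a)))

    def ratio(a: float) -> float:
        lam = hazard(a)
        var_factor = 1.0 - lam * (lam - a)
        if var_factor <= 0:
            return np.inf
        return (lam - a) / np.sqrt(var_factor)

    f = lambda a: ratio(a) - target
    lo, hi = -12.0, 12.0
    if f(lo) < 0:  # mean/sd > ~12: truncation mass is negligible
        return float(mean), float(sd)
    alpha = optimize.brentq(f, lo, hi, xtol=1e-12)
    lam = hazard(alpha)
    sigma = sd / np.sqrt(1.0 - lam * (lam - alpha))
    mu = -alpha * sigma
    return float(mu), float(sigma)


def class_marginal(params: ClassParams):
    """Frozen marginal distribution reproducing a class's mean ± SD on [0, ∞)."""
    m, s = params.mean, params.sd
    if s == 0:
        return _Degenerate(m)
    if m / s >= 1.2:
        mu, sigma = _truncnorm_parent_params(m, s)
        return stats.truncnorm(a=-mu / sigma, b=np.inf, loc=mu, scale=sigma)
    # CV too high for a zero-truncated normal: moment-matched log-normal
    log_var = np.log1p((s / m) ** 2)
    return stats.lognorm(s=np.sqrt(log_var), scale=m * np.exp(-log_var / 2.0))


def baseline_marginal(median: float, log_sd: float):
    """Healthy log-normal marginal parameterized by median and log-scale sd."""
    if log_sd == 0:
        return _Degenerate(median)
    return stats.lognorm(s=log_sd, scale=median)


def load_baselines(path: str | Path | None = None) -> pd.DataFrame:
    """Healthy baseline table (index: analyte; columns: median, log_sd)."""
    if path is None:
        with importlib.resources.as_file(
            importlib.resources.files("neoscreen.data").joinpath("baselines.csv")
        ) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    table = table.set_index("analyte")
    missing = [a for a in DEFAULT_ANALYTES if a not in table.index]
    if missing:
        raise CohortValidationError(f"baselines missing analytes: {', '.join(missing)}")
    return table


def sample_disease_status(
    n: int,
    registry: Sequence[DiseaseDefinition],
    carrier_multiplier: float = DEFAULT_CARRIER_MULTIPLIER,
    seed: int | np.random.Generator = 0,
    enrichment: float = 1.0,
) -> list[tuple[str | None, str]]:
    """Independently assign each of ``n`` subjects a (disease, zygosity) status.

    Per disease, affected status is drawn at ``enrichment × prevalence`` and
    carrier status at ``carrier_multiplier`` times that; the remainder is
    unaffected. ``enrichment`` > 1 produces case-enriched cohorts for model
    training.
    """
    if n < 0:
        raise CohortValidationError(f"n must be >= 0, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = []
    outcomes: list[tuple[str | None, str]] = []
    for d in registry:
        p = d.prevalence * enrichment
        probs.extend([p, p * carrier_multiplier])
        outcomes.extend([(d.abbreviation, AFFECTED), (d.abbreviation, CARRIER)])
    mass = float(np.sum(probs))
    if mass >= 1.0:
        raise CohortValidationError(
            f"affected + carrier probability mass {mass:.3f} must be < 1"
        )
    probs.append(1.0 - mass)
    outcomes.append((None, UNAFFECTED))
    idx = rng.choice(len(outcomes), size=n, p=np.asarray(probs))
    return [outcomes[i] for i in idx]


def sample_panel(
    status: tuple[DiseaseDefinition | None, str],
    baselines: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Draw one subject's full analyte panel given their (disease, zygosity)."""
    disease, zygosity = status
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    panel: dict[str, float] = {}
    for analyte in DEFAULT_ANALYTES:
        row = baselines.loc[analyte]
        dist = baseline_marginal(float(row["median"]), float(row["log_sd"]))
        panel[analyte] = float(dist.rvs(size=1, random_state=rng)[0])
    if disease is not None and zygosity != UNAFFECTED:
        for analyte, params in disease.params_for(zygosity).items():
            dist = class_marginal(params)
            panel[analyte] = float(dist.rvs(size=1, random_state=rng)[0])
    return panel


def _sample_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    ga = np.clip(rng.normal(39.0, 1.5, size=n), 24.0, 44.0).round(1)
    bw = np.clip(rng.normal(3300.0, 450.0, size=n), 600.0, 6000.0).round(0)
    ci = np.clip(np.round(rng.normal(4.0, 1.5, size=n)), 1, 28).astype(int)
    sex = rng.choice(np.array(["M", "F"]), size=n)
    feeding = rng.choice(
        np.array(["breast", "formula", "mixed"]), size=n, p=[0.6, 0.2, 0.2]
    )
    return pd.DataFrame(
        {
            "gestational_age_weeks": ga,
            "birth_weight_g": bw,
            "collection_interval_d": ci,
            "sex": sex,
            "feeding": feeding,
        }
    )


class Cohort:
    """A screening cohort backed by a pandas DataFrame (one row per neonate)."""

    def __init__(self, frame: pd.DataFrame, analytes: Sequence[str] = DEFAULT_ANALYTES):
        self.analytes = tuple(analytes)
        expected = ["id", *COVARIATE_COLUMNS, *self.analytes, *TRUTH_COLUMNS]
        missing = [c for c in expected if c not in frame.columns]
        extra = [c for c in frame.columns if c not in expected]
        if missing or extra:
            raise CohortValidationError(
                f"cohort schema mismatch: missing columns {missing}, unexpected {extra}"
            )
        self.frame = frame.loc[:, expected].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def truth_disease(self) -> pd.Series:
        return self.frame["truth_disease"]

    @property
    def truth_zygosity(self) -> pd.Series:
        return self.frame["truth_zygosity"]

    def panel_matrix(self) -> pd.DataFrame:
        return self.frame.loc[:, list(self.analytes)]

    def records(self) -> Iterator[ScreeningRecord]:
        positions = {a: self.frame.columns.get_loc(a) for a in self.analytes}
        for row in self.frame.itertuples(index=False):
            d = row.truth_disease
            disease = None if (d is None or (isinstance(d, float) and np.isnan(d)) or d == "") else d
            yield ScreeningRecord(
                id=row.id,
                covariates=Covariates(
                    gestational_age=row.gestational_age_weeks,
                    birth_weight=row.birth_weight_g,
                    collection_interval=row.collection_interval_d,
                    sex=row.sex,
                    feeding=row.feeding,
                ),
                panel={a: float(row[pos]) for a, pos in positions.items()},
                truth_disease=disease,
                truth_zygosity=row.truth_zygosity if disease is not None else UNAFFECTED,
            )

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["truth_disease"] = out["truth_disease"].fillna("")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, analytes: Sequence[str] = DEFAULT_ANALYTES) -> "Cohort":
        frame = pd.read_csv(path, dtype={"truth_disease": "string", "id": "string"})
        if len(frame) == 0 and "truth_disease" not in frame.columns:
            raise CohortValidationError("empty file without header")
        td = frame["truth_disease"].astype(object)
        frame["truth_disease"] = np.where(
            pd.isna(td) | (td == ""), None, td
        )
        frame["id"] = frame["id"].astype(str) if len(frame) else frame["id"]
        return cls(frame, analytes=analytes)


def generate_cohort(
    n: int,
    registry: Sequence[DiseaseDefinition] | None = None,
    baselines: pd.DataFrame | None = None,
    seed: int = 0,
    carrier_multiplier: float = DEFAULT_CARRIER_MULTIPLIER,
    enrichment: float = 1.0,
    id_prefix: str = "N",
) -> Cohort:
    """Generate a seeded cohort of ``n`` screening records.

    The disease-status sampler, the covariate sampler and the panel sampler
    each consume an independent child stream of the master seed, so any one
    component can be regenerated without disturbing the others.
    """
    if n < 0:
        raise CohortValidationError(f"cohort size must be >= 0, got {n}")
    registry = build_disease_registry() if registry is None else registry
    baselines = load_baselines() if baselines is None else baselines

    ss = np.random.SeedSequence(seed)
    status_rng, cov_rng, panel_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    status = sample_disease_status(
        n, registry, carrier_multiplier=carrier_multiplier, seed=status_rng,
        enrichment=enrichment,
    )
    truth_disease = np.array([d for d, _ in status], dtype=object)
    truth_zygosity = np.array([z for _, z in status], dtype=object)

    covs = _sample_covariates(n, cov_rng)

    # Healthy draws for every analyte, then per-(disease, zygosity) overwrite
    # of that disease's marker analytes; iteration order is fixed so the
    # random stream is reproducible.
    panel = {}
    for analyte in DEFAULT_ANALYTES:
        row = baselines.loc[analyte]
        dist = baseline_marginal(float(row["median"]), float(row["log_sd"]))
        panel[analyte] = np.asarray(dist.rvs(size=n, random_state=panel_rng), dtype=float)
    for d in registry:
        for zygosity in (AFFECTED, CARRIER):
            mask = (truth_disease == d.abbreviation) & (truth_zygosity == zygosity)
            k = int(mask.sum())
            if k == 0:
                continue
            for analyte in sorted(d.params_for(zygosity)):
                dist = class_marginal(d.params_for(zygosity)[analyte])
                panel[analyte][mask] = dist.rvs(size=k, random_state=panel_rng)

    width = max(6, len(str(max(n, 1))))
    frame = pd.DataFrame({"id": [f"{id_prefix}{i:0{width}d}" for i in range(n)]})
    frame = pd.concat([frame, covs, pd.DataFrame(panel)], axis=1)
    frame["truth_disease"] = truth_disease
    frame["truth_zygosity"] = truth_zygosity
    return Cohort(frame)
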