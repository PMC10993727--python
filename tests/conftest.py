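import warnings

import numpy as np
import pytest

from neoscreen.cohort import generate_cohort, load_baselines
from neoscreen.pipeline import PipelineConfig, run_pipeline
from neoscreen.registry import build_disease_registry


@pytest.fixture(scope="session")
def registry():
    return build_disease_registry()


@pytest.fixture(scope="session")
def baselines():
    return load_baselines()


@pytest.fixture(scope="session")
def small_cohort(registry, baselines):
    """A 4,000-subject screening cohort at natural prevalence."""
    return generate_cohort(4000, registry, baselines, seed=42)


@pytest.fixture(scope="session")
def enriched_cohort(registry, baselines):
    """A case-enriched cohort suitable for model training at small scale."""
    return generate_cohort(6000, registry, baselines, seed=43, enrichment=150,
                           id_prefix="T")


@pytest.fixture(scope="session")
def pipeline_manifests(tmp_path_factory):
    """The same small pipeline configuration run twice, for replay checks."""
    manifests = []
    for tag in ("a", "b"):
        outdir = tmp_path_factory.mktemp(f"run_{tag}")
        config = PipelineConfig(
            seed=123,
            cohort_size=2500,
            train_size=2500,
            train_enrichment=250,
            output_dir=str(outdir),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            manifests.append(run_pipeline(config))
    return manifests
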