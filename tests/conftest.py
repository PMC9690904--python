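import numpy as np
import pandas as pd
import pytest

import episig as es


@pytest.fixture(scope="session")
def small_design() -> es.SimDesign:
    """A quick design for unit tests: 3,000 probes, 60 planted, 12 cases."""
    return es.SimDesign(
        n_probes=3_000,
        n_signature_probes=60,
        n_cases=12,
        n_control_pool=60,
        n_other_cohorts=2,
        samples_per_other_cohort=8,
        n_outlier_cases=2,
        n_validation_cases=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design) -> es.SimulatedDataset:
    manifest = es.generate_manifest(small_design.n_probes, seed=small_design.seed)
    return es.generate_dataset(small_design, manifest)


@pytest.fixture(scope="session")
def small_discovery(small_dataset):
    config = es.PipelineConfig(seed=11)
    return config, es.run_discovery(config, small_dataset)


@pytest.fixture(scope="session")
def study_dataset() -> es.SimulatedDataset:
    """The full-size study conditions: 20,000 probes, 200 planted hypo
    signature probes, 20 discovery cases, 2 outliers, 9 validation cases,
    a VUS carrier and a 100-control pool."""
    design = es.SimDesign(seed=1)
    manifest = es.generate_manifest(design.n_probes, seed=design.seed)
    return es.generate_dataset(design, manifest)


@pytest.fixture(scope="session")
def study_discovery(study_dataset):
    config = es.PipelineConfig(seed=1)
    return config, es.run_discovery(config, study_dataset)
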