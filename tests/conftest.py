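import pytest

from organedit.pipeline import run_pipeline
from organedit.synthetic_data import SimulationConfig, generate_dataset

#: compact configuration for fast unit tests
SMALL_CONFIG = SimulationConfig(
    seed=11,
    genome_length=24_000,
    n_genes=14,
    multi_segment_fraction=0.3,
    n_edit_sites=40,
    artifact_per_rule=3,
    n_expression_genes=80,
    n_factor_genes=20,
)

#: the default study design at a fixed seed, shared by the acceptance suite
STUDY_CONFIG = SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def study():
    """Default-design dataset plus the full pipeline result on it."""
    cfg = STUDY_CONFIG
    ds = generate_dataset(cfg)
    vcfs = {
        cond: [ds.vcf_records[(cond, f"rep{r + 1}")] for r in range(cfg.replicates)]
        for cond in cfg.conditions
    }
    result = run_pipeline(ds.genome, ds.features, vcfs, list(cfg.conditions))
    return ds, result


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    ds = small_dataset
    cfg = ds.config
    vcfs = {
        cond: [ds.vcf_records[(cond, f"rep{r + 1}")] for r in range(cfg.replicates)]
        for cond in cfg.conditions
    }
    return run_pipeline(ds.genome, ds.features, vcfs, list(cfg.conditions))
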