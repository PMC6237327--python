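from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import strokeclock as sc

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def design() -> sc.StudyDesign:
    return sc.StudyDesign()


@pytest.fixture(scope="session")
def sheet(design) -> pd.DataFrame:
    return design.sample_sheet()


@pytest.fixture(scope="session")
def study_lownoise() -> sc.SyntheticDataset:
    """Published archetype composition, low noise: used for recovery checks."""
    return sc.study_dataset(noise_sd=0.1, seed=1)


@pytest.fixture(scope="session")
def study_noisefree() -> sc.SyntheticDataset:
    return sc.study_dataset(noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def limma_fixture():
    """Frozen small matrix with heterogeneous gene variances plus the
    independently computed reference results for it."""
    mat = sc.read_expression(DATA_DIR / "limma_fixture_expression.tsv")
    sample_sheet = sc.read_sample_sheet(DATA_DIR / "limma_fixture_samples.csv")
    oracle = pd.read_csv(DATA_DIR / "limma_oracle_results.tsv", sep="\t").set_index("gene_id")
    prior_lines = (DATA_DIR / "limma_oracle_prior.txt").read_text().split()
    prior = {"df.prior": float(prior_lines[1]), "s2.prior": float(prior_lines[3])}
    return mat, sample_sheet, oracle, prior


def default_panel(dataset: sc.SyntheticDataset, k: int = 3) -> list[str]:
    """First k genes of each archetype, from the generator truth."""
    truth = dataset.truth.set_index("gene_id")
    return [
        g for lab in "ABCDEFGH"
        for g in truth[truth["archetype"] == lab].index[:k]
    ]
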