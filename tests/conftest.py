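from pathlib import Path

import pytest

from thermoscm import GaConfig, LabeledDataset, ProteinRecord, SimulationParams, generate_dataset

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """Separable toy dataset: Glu-rich positives, Ala-rich negatives."""
    return LabeledDataset(
        positives=[
            ProteinRecord("p1", "EEEEKEEKEE"),
            ProteinRecord("p2", "EKEEEEEKEE"),
            ProteinRecord("p3", "EEEKEKEEEE"),
            ProteinRecord("p4", "EEKEEEEEKE"),
        ],
        negatives=[
            ProteinRecord("n1", "AAAAQAAQAA"),
            ProteinRecord("n2", "AQAAAAAQAA"),
            ProteinRecord("n3", "AAAQAQAAAA"),
            ProteinRecord("n4", "AAQAAAAAQA"),
        ],
    )


@pytest.fixture(scope="session")
def planted_train() -> LabeledDataset:
    """Default planted-signal benchmark (training draw)."""
    return generate_dataset(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def planted_test() -> LabeledDataset:
    """Fresh draw from the same conditions for held-out evaluation."""
    return generate_dataset(SimulationParams(seed=8))


@pytest.fixture(scope="session")
def null_train() -> LabeledDataset:
    """No planted signal: both classes from the background model."""
    return generate_dataset(SimulationParams(seed=7, enriched={}))


@pytest.fixture(scope="session")
def reduced_ga() -> GaConfig:
    """Desk-scale GA configuration used by the synthetic-benchmark tests."""
    return GaConfig(population_size=20, generations=20, runs=3, seed=7)
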