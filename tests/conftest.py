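from pathlib import Path

import pytest

from pathwayviews.fixtures import FixtureSpec, canonical_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def canonical_doc():
    """The frozen reference pathway: 5 data nodes (one redundant pair),
    1 group of 2, 3 interactions (one anchored), 1 label, 1 shape."""
    return canonical_fixture()


@pytest.fixture
def golden_gpml_text():
    return (DATA_DIR / "canonical.gpml").read_text()


@pytest.fixture
def demo_data_path():
    return DATA_DIR / "demo_data.tsv"


@pytest.fixture
def demo_mapping_path():
    return DATA_DIR / "demo_mapping.tsv"


def fixture_specs(n=50, base_seed=100):
    """A spread of valid fixture shapes for property-style sweeps."""
    specs = []
    for i in range(n):
        specs.append(
            FixtureSpec(
                n_datanodes=2 + (i % 7),
                n_redundant_pairs=(i % 3) if (i % 3) <= (2 + i % 7) // 2 else 0,
                n_groups=1 if (2 + i % 7) >= 2 and i % 2 else 0,
                group_size=2,
                n_interactions=i % 4 if (2 + i % 7) >= 2 else 0,
                n_anchors=min(1, i % 4),
                n_labels=i % 2,
                n_shapes=(i + 1) % 2,
                seed=base_seed + i,
            )
        )
    return specs
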