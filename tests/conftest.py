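import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from amoebahgt.simulate import (
    generate_host_genome,
    generate_reference_panels,
    implant_transfers,
    panel_proteome,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


@pytest.fixture(scope="session")
def small_panels():
    """3 viral families x 5 proteins plus cellular decoys (150±30 aa)."""
    return generate_reference_panels(3, 5, (150.0, 30.0), seed=11)


@pytest.fixture(scope="session")
def small_genome(small_panels):
    """6-scaffold host genome with 6 implants at 10% divergence."""
    panels, _cellular, _tax = small_panels
    genome = generate_host_genome(6, 5, 0.583, seed=12, orf_length_aa=(140.0, 25.0))
    return implant_transfers(genome, panels, 6, 0.1, seed=13)


@pytest.fixture(scope="session")
def small_database(small_panels):
    panels, cellular, tax = small_panels
    return panel_proteome(panels, cellular), tax
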