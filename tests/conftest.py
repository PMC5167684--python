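import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py importable

from oligostate.sequence_io import ALPHABET, ProteinRecord


def random_records(n: int, length_range=(35, 60), seed: int = 0) -> list[ProteinRecord]:
    """Uniform-composition random records, deterministic given the seed."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(ALPHABET[c] for c in rng.choice(20, size=length))
        records.append(ProteinRecord(id=f"seq_{i:03d}", sequence=seq))
    return records


@pytest.fixture(scope="session")
def oracle_records() -> list[ProteinRecord]:
    """25 random length-35-60 sequences used for descriptor oracle checks."""
    return random_records(25, (35, 60), seed=42)
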