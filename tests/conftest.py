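import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.reference imports

from irscape.synthetic_genome import (
    DepletionSpec,
    LengthDist,
    NucleosomeSpec,
    PlantSpec,
    SynthConfig,
    generate,
)


def random_sequence(rng: np.random.Generator, length: int, at: float) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def small_synth():
    """A modest planted synthetic dataset shared across test modules."""
    cfg = SynthConfig(
        n_chromosomes=1,
        genes_per_chrom=40,
        intergenic=LengthDist(700, 150, 300),
        plants=(
            PlantSpec("III", 8, 0, "polya", -60, -31, prob=0.8),
            PlantSpec("VII", 6, 3, "start_codon", 30, 60, prob=0.6),
        ),
        nucleosomes=NucleosomeSpec(
            depletion=(
                DepletionSpec(mode="planted", window=(-40, 40), prob=0.9,
                              types=("III",)),
            )
        ),
        seed=20260,
    )
    return generate(cfg)
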