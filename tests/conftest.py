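import numpy as np
import pandas as pd
import pytest

from ovigene import popgen

# published genotype tallies of the two study loci
SMAD5_COUNTS = {"AA": 256, "AG": 150, "GG": 27}
SMAD7_COUNTS = {"CC": 409, "CT": 24}


@pytest.fixture
def smad5_counts() -> popgen.GenotypeCounts:
    return popgen.counts_from_mapping("g.51537A>G", SMAD5_COUNTS)


@pytest.fixture
def smad7_counts() -> popgen.GenotypeCounts:
    return popgen.counts_from_mapping("g.319C>T", SMAD7_COUNTS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)


def genotype_frame_from_counts(counts: dict[str, int], locus: str) -> pd.DataFrame:
    """Expand a genotype tally into one per-animal row each."""
    rows = []
    i = 0
    for genotype, count in counts.items():
        for _ in range(count):
            rows.append((f"ewe{i:04d}", locus, genotype))
            i += 1
    return pd.DataFrame(rows, columns=["animal_id", "locus", "genotype"])
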