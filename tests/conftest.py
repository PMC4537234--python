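from __future__ import annotations

import numpy as np
import pytest

from regcascade.core import GenomicInterval, RegionSet
from regcascade.simulate import SyntheticConfig, generate_dataset


def random_region_set(rng, label="rs", n=8, n_chroms=2, length=1000, max_len=120):
    """Small random RegionSet for oracle-equivalence tests."""
    ivs = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, length - max_len))
        end = start + int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, end))
    return RegionSet(label, ivs)


def triples(rs):
    return [(iv.chrom, iv.start, iv.end) for iv in rs.intervals]


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default-condition synthetic dataset, written to disk once."""
    outdir = tmp_path_factory.mktemp("default_ds")
    return generate_dataset(SyntheticConfig(seed=11), outdir)
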