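from __future__ import annotations

import numpy as np
import pytest

from hypertx import FragmentSet, GenomeSpec, Region, RegionSet


@pytest.fixture
def toy_genome() -> GenomeSpec:
    return GenomeSpec({"chr1": 1000, "chr2": 500, "chrM": 100}, mito="chrM")


@pytest.fixture
def flat_genome() -> GenomeSpec:
    """Single 100-bp chromosome, no mitochondrion."""
    return GenomeSpec({"chr1": 100})


def make_fs(genome: GenomeSpec | None, frags, sample_id="s", **kw) -> FragmentSet:
    chroms = np.array([f[0] for f in frags], dtype=object)
    starts = np.array([f[1] for f in frags], dtype=np.int64)
    ends = np.array([f[2] for f in frags], dtype=np.int64)
    return FragmentSet(sample_id=sample_id, chroms=chroms, starts=starts, ends=ends,
                       genome=genome, **kw)


def tiling_fragments(genome: GenomeSpec, step: int = 100):
    """Non-overlapping fragments covering every bp exactly once."""
    frags = []
    for chrom in genome.chroms:
        L = genome.lengths[chrom]
        for s in range(0, L, step):
            frags.append((chrom, s, min(s + step, L)))
    return frags


def random_regions(rng: np.random.Generator, genome: GenomeSpec, n: int,
                   max_width: int = 50, prefix: str = "r") -> RegionSet:
    regions = []
    chroms = [c for c in genome.chroms]
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        L = genome.lengths[chrom]
        width = int(rng.integers(1, min(max_width, L) + 1))
        start = int(rng.integers(0, L - width + 1))
        regions.append(Region(chrom, start, start + width, f"{prefix}{i}"))
    return RegionSet(regions)
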