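"""Independent brute-force oracles used to cross-check the library paths.

These deliberately use naive per-bp / per-pair formulations (slice additions
and double loops) rather than the prefix-sum, searchsorted or reduceat
implementations in the package.
"""

from __future__ import annotations

import numpy as np


def coverage_oracle(genome, fragments):
    """Per-bp raw coverage via per-fragment slice additions."""
    arrays = {c: np.zeros(genome.lengths[c]) for c in genome.chroms}
    for chrom, start, end in fragments:
        arrays[chrom][start:end] += 1
    return arrays


def normalized_oracle(genome, fragments):
    arrays = coverage_oracle(genome, fragments)
    total = sum(a.sum() for a in arrays.values())
    return {c: a * genome.size / total for c, a in arrays.items()}


def region_mean_oracle(norm_arrays, regions):
    """Length-averaged signal per region by summing individual base pairs."""
    out = []
    for r in regions:
        arr = norm_arrays[r.chrom]
        total = 0.0
        for i in range(r.start, r.end):
            total += arr[i]
        out.append(total / (r.end - r.start))
    return np.array(out)


def region_sum_oracle(norm_arrays, regions):
    out = []
    for r in regions:
        out.append(float(np.sum(norm_arrays[r.chrom][r.start:r.end])))
    return np.array(out)


def blocks_oracle(genome, arrays):
    """Linear scan for maximal positive runs; returns (chrom, start, end, auc)."""
    blocks = []
    for chrom in genome.chroms:
        arr = arrays[chrom]
        start = None
        for i in range(len(arr)):
            if arr[i] > 0 and start is None:
                start = i
            elif arr[i] <= 0 and start is not None:
                blocks.append((chrom, start, i, float(np.sum(arr[start:i]))))
                start = None
        if start is not None:
            blocks.append((chrom, start, len(arr), float(np.sum(arr[start:]))))
    return blocks


def count_matrix_oracle(samples, regions):
    """Double loop over (region, fragment) pairs with >= 1 bp overlap."""
    out = np.zeros((len(regions), len(samples)), dtype=np.int64)
    for j, fs in enumerate(samples):
        frags = list(zip(fs.chroms, fs.starts, fs.ends))
        for i, r in enumerate(regions):
            n = 0
            for chrom, s, e in frags:
                if chrom == r.chrom and s < r.end and e > r.start:
                    n += 1
            out[i, j] = n
    return out


def subtract_oracle(regions, mask):
    """O(n*m) pairwise overlap filter."""
    kept = []
    for r in regions:
        hit = any(
            m.chrom == r.chrom and m.start < r.end and m.end > r.start for m in mask
        )
        if not hit:
            kept.append(r)
    return kept


def overlap_top_oracle(top_regions, peakcalls):
    """Per-region count of pairs with any overlapping peak, by double loop."""
    counts = []
    for r in top_regions:
        n = 0
        for call in peakcalls.values():
            if any(
                p.chrom == r.chrom and p.start < r.end and p.end > r.start
                for p in call.peaks
            ):
                n += 1
        counts.append(n)
    return counts
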