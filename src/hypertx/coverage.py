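"""Genome-scaled normalized coverage tracks and per-region signal.

The track value at base pair ``i`` is ``n_i = (c_i / T) * G`` where ``c_i``
counts fragments spanning ``i``, ``T`` is the total per-bp count mass and
``G`` the genome size, so uniform raw coverage yields 1.0 everywhere and the
track always sums to ``G``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fragments import FragmentSet
from .genome import GenomeSpec
from .regions import RegionSet
from .regions import subtract_regions as subtract_regions  # re-export: region filtering

__all__ = [
    "CoverageTrack",
    "RegionSignal",
    "make_track",
    "region_signal",
    "region_sum",
    "write_bedgraph",
    "read_bedgraph",
    "subtract_regions",
]


@dataclass
class CoverageTrack:
    genome: GenomeSpec
    data: dict[str, np.ndarray]  # per-chromosome dense float64 arrays
    total_raw: float  # T: summed raw per-bp counts (= total fragment bp)
    _prefix: dict[str, np.ndarray] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    @property
    def size(self) -> int:
        return self.genome.size

    def chrom(self, name: str) -> np.ndarray:
        return self.data[name]

    def sum(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def prefix(self, chrom: str) -> np.ndarray:
        """Cumulative sums with a leading zero; interval sums in O(1)."""
        if self._prefix is None:
            self._prefix = {}
        if chrom not in self._prefix:
            arr = self.data[chrom]
            p = np.empty(arr.size + 1, dtype=np.float64)
            p[0] = 0.0
            np.cumsum(arr, out=p[1:])
            self._prefix[chrom] = p
        return self._prefix[chrom]

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        p = self.prefix(chrom)
        return float(p[end] - p[start])


@dataclass
class RegionSignal:
    """Length-averaged normalized signal per region for one sample."""

    sample_id: str
    region_ids: list[str]
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.region_ids, self.values))


def make_track(fs: FragmentSet, genome: GenomeSpec) -> CoverageTrack:
    """Build the genome-scaled normalized coverage track for one sample."""
    if len(fs) == 0:
        raise ValueError("cannot build a coverage track from an empty FragmentSet")
    data: dict[str, np.ndarray] = {}
    total = 0.0
    for chrom in genome.chroms:
        L = genome.lengths[chrom]
        sel = fs.chroms == chrom
        if not sel.any():
            data[chrom] = np.zeros(L, dtype=np.float64)
            continue
        diff = np.bincount(fs.starts[sel], minlength=L + 1).astype(np.int64)
        diff -= np.bincount(fs.ends[sel], minlength=L + 1)
        cov = np.cumsum(diff[:L]).astype(np.float64)
        data[chrom] = cov
        total += cov.sum()
    scale = genome.size / total
    for chrom in data:
        data[chrom] *= scale
    return CoverageTrack(genome=genome, data=data, total_raw=total)


def _region_sums(track: CoverageTrack, regions: RegionSet) -> np.ndarray:
    out = np.empty(len(regions), dtype=np.float64)
    for i, r in enumerate(regions):
        out[i] = track.interval_sum(r.chrom, r.start, r.end)
    return out


def region_sum(track: CoverageTrack, regions: RegionSet, sample_id: str = "") -> RegionSignal:
    """Summed normalized counts within each region (no length correction)."""
    regions.validate(track.genome)
    return RegionSignal(sample_id=sample_id, region_ids=regions.ids,
                        values=_region_sums(track, regions))


def region_signal(track: CoverageTrack, regions: RegionSet, sample_id: str = "") -> RegionSignal:
    """Length-averaged normalized counts per region.

    Regions vary in size, so sums are divided by region length to make the
    per-region values comparable.
    """
    regions.validate(track.genome)
    widths = np.array([r.width for r in regions], dtype=np.float64)
    if (widths <= 0).any():
        raise ValueError("zero-length region")
    return RegionSignal(sample_id=sample_id, region_ids=regions.ids,
                        values=_region_sums(track, regions) / widths)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length-encoded 4-column bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in track.genome.chroms:
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def read_bedgraph(path: str | Path, genome: GenomeSpec,
                  total_raw: float = float("nan")) -> CoverageTrack:
    data = {c: np.zeros(genome.lengths[c], dtype=np.float64) for c in genome.chroms}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            s, e = int(s), int(e)
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if s < last_end.get(chrom, 0):
                raise ValueError(f"{path}:{lineno}: overlapping or unsorted intervals")
            last_end[chrom] = e
            data[chrom][s:e] = float(v)
    return CoverageTrack(genome=genome, data=data, total_raw=total_raw)


def write_region_signal(sig: RegionSignal, regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tchrom\tstart\tend\tclass\tvalue\n")
        for r, v in zip(regions, sig.values):
            fh.write(f"{r.region_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.region_class}\t{float(v)!r}\n")
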