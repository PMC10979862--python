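"""Annotated genomic intervals (regulatory elements, histone genes, tiles)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from .genome import GenomeSpec


class Region(NamedTuple):
    chrom: str
    start: int
    end: int
    region_id: str
    region_class: str = "."

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class RegionSet:
    """An ordered collection of half-open intervals with ids and class labels."""

    regions: list[Region]
    _by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False, compare=False
    )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    @property
    def ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def classes(self) -> list[str]:
        return [r.region_class for r in self.regions]

    def select(self, region_class: str) -> "RegionSet":
        return RegionSet([r for r in self.regions if r.region_class == region_class])

    def select_ids(self, ids) -> "RegionSet":
        wanted = set(ids)
        return RegionSet([r for r in self.regions if r.region_id in wanted])

    def validate(self, genome: GenomeSpec) -> None:
        for r in self.regions:
            if r.chrom not in genome:
                raise ValueError(f"region {r.region_id}: unknown chromosome {r.chrom!r}")
            if not (0 <= r.start < r.end <= genome.lengths[r.chrom]):
                raise ValueError(
                    f"region {r.region_id}: [{r.start},{r.end}) outside {r.chrom} bounds"
                )

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, original indices), sorted by start."""
        if self._by_chrom is None:
            grouped: dict[str, list[tuple[int, int, int]]] = {}
            for i, r in enumerate(self.regions):
                grouped.setdefault(r.chrom, []).append((r.start, r.end, i))
            out = {}
            for chrom, rows in grouped.items():
                rows.sort()
                s = np.array([x[0] for x in rows], dtype=np.int64)
                e = np.array([x[1] for x in rows], dtype=np.int64)
                idx = np.array([x[2] for x in rows], dtype=np.int64)
                out[chrom] = (s, e, idx)
            self._by_chrom = out
        return self._by_chrom

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.region_class}\n")

    @classmethod
    def read_bed(cls, path: str | Path) -> "RegionSet":
        regions = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                rid = parts[3] if len(parts) > 3 else f"region_{lineno}"
                cls_label = parts[4] if len(parts) > 4 else "."
                if start >= end:
                    raise ValueError(f"{path}:{lineno}: start >= end")
                regions.append(Region(chrom, start, end, rid, cls_label))
        return cls(regions)


def subtract_regions(regions: RegionSet, mask: RegionSet) -> RegionSet:
    """Retain regions with zero overlap with any mask interval.

    Matches ``bedtools intersect -v`` semantics: any overlap of >= 1 bp
    removes the region; half-open abutment is not an overlap.
    """
    mask_by_chrom = {}
    for chrom, (s, e, _) in mask.by_chrom().items():
        # prefix-max of ends supports overlap queries on possibly-nested masks
        mask_by_chrom[chrom] = (s, np.maximum.accumulate(e))
    kept = []
    for r in regions:
        hit = False
        if r.chrom in mask_by_chrom:
            ms, me_max = mask_by_chrom[r.chrom]
            k = int(np.searchsorted(ms, r.end, side="left"))  # masks with start < r.end
            if k > 0 and me_max[k - 1] > r.start:
                hit = True
        if not hit:
            kept.append(r)
    return RegionSet(kept)
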