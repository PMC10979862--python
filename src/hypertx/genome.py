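"""Genome description: ordered chromosomes with lengths and a mitochondrial flag."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names with lengths; one chromosome may be mitochondrial.

    The total genome size ``G`` (sum of all declared lengths, chrM included)
    is the scaling constant for normalized coverage tracks.
    """

    lengths: dict[str, int]
    mito: str | None = None
    _order: tuple[str, ...] = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.mito is not None and self.mito not in self.lengths:
            raise ValueError(f"mitochondrial chromosome {self.mito!r} not in genome")
        object.__setattr__(self, "_order", tuple(self.lengths))

    @property
    def chroms(self) -> tuple[str, ...]:
        return self._order

    @property
    def size(self) -> int:
        """Total genome size G in bp."""
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def chrom_index(self, chrom: str) -> int:
        return self._order.index(chrom)

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self._order:
                fh.write(f"{name}\t{self.lengths[name]}\n")

    @classmethod
    def read_chrom_sizes(cls, path: str | Path, mito: str | None = None) -> "GenomeSpec":
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
                lengths[parts[0]] = int(parts[1])
        if mito is None and "chrM" in lengths:
            mito = "chrM"
        return cls(lengths=lengths, mito=mito)
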