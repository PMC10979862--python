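"""Fragment-file handling and sample preparation.

Covers BED3 reading/writing with validation, exact-coordinate duplicate
removal, pooling of replicate sets, fragment-count equalization by
downsampling, sample QC, and mitochondrial signal accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSpec

QC_MIN_FRAGMENTS = 100_000
QC_MIN_TOTAL_BP = 10_000_000


@dataclass
class FragmentSet:
    """One sample's mapped fragments as parallel coordinate arrays."""

    sample_id: str
    chroms: np.ndarray  # str array
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    condition: str = "na"  # "tumor" | "normal" | "na"
    pair_id: str = ""
    replicate_id: str = ""
    genome: GenomeSpec | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("coordinate arrays have mismatched lengths")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum()) if len(self) else 0

    def sorted(self) -> "FragmentSet":
        """Fragments ordered by (chrom, start, end); chrom order follows the
        genome when one is attached, lexicographic otherwise."""
        if self.genome is not None:
            order_map = {c: i for i, c in enumerate(self.genome.chroms)}
            ckey = np.array([order_map[c] for c in self.chroms])
        else:
            ckey = self.chroms.astype(str)
        order = np.lexsort((self.ends, self.starts, ckey))
        return replace(
            self, chroms=self.chroms[order], starts=self.starts[order], ends=self.ends[order]
        )

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c, s, e in zip(self.chroms, self.starts, self.ends):
                fh.write(f"{c}\t{s}\t{e}\n")


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    n_fragments: int
    total_fragment_bp: int
    passed: bool


def read_fragments(
    path: str | Path,
    genome: GenomeSpec,
    sample_id: str | None = None,
    condition: str = "na",
    pair_id: str = "",
) -> FragmentSet:
    """Read a BED3(+) file of mapped fragments and validate against the genome.

    Extra columns are ignored; input order is preserved. Raises ``ValueError``
    naming the offending line on unknown chromosomes or bad coordinates.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({"chrom": [], "start": [], "end": []})
    chroms = df["chrom"].to_numpy(dtype=object)
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)
    for chrom in pd.unique(df["chrom"]) if len(df) else []:
        if chrom not in genome:
            line = int(np.flatnonzero(chroms == chrom)[0]) + 1
            raise ValueError(f"{path}:{line}: unknown chromosome {chrom!r}")
    bad = np.flatnonzero(starts >= ends)
    if bad.size:
        raise ValueError(f"{path}:{bad[0] + 1}: start >= end")
    if len(df):
        limits = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
        bad = np.flatnonzero((starts < 0) | (ends > limits))
        if bad.size:
            raise ValueError(f"{path}:{bad[0] + 1}: coordinate outside chromosome")
    return FragmentSet(
        sample_id=sample_id, chroms=chroms, starts=starts, ends=ends,
        condition=condition, pair_id=pair_id, genome=genome,
    )


def deduplicate(fs: FragmentSet) -> tuple[FragmentSet, int]:
    """Remove exact-coordinate duplicates, keeping the first occurrence."""
    if len(fs) == 0:
        return fs, 0
    df = pd.DataFrame({"c": fs.chroms, "s": fs.starts, "e": fs.ends})
    keep = (~df.duplicated()).to_numpy()
    n_removed = int((~keep).sum())
    out = replace(fs, chroms=fs.chroms[keep], starts=fs.starts[keep], ends=fs.ends[keep])
    return out, n_removed


def downsample_equalize(
    a: FragmentSet, b: FragmentSet, seed: int
) -> tuple[FragmentSet, FragmentSet]:
    """Downsample the larger of the two sets to the size of the smaller.

    Uniform sampling without replacement, deterministic under ``seed``; the
    smaller set is returned unchanged and retained fragments keep input order.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("downsample_equalize requires two non-empty fragment sets")
    if len(a) == len(b):
        return a, b
    rng = np.random.default_rng(seed)

    def _take(fs: FragmentSet, n: int) -> FragmentSet:
        idx = np.sort(rng.choice(len(fs), size=n, replace=False))
        return replace(fs, chroms=fs.chroms[idx], starts=fs.starts[idx], ends=fs.ends[idx])

    n = min(len(a), len(b))
    if len(a) > n:
        return _take(a, n), b
    return a, _take(b, n)


def merge_fragmentsets(sets: list[FragmentSet], sample_id: str | None = None) -> FragmentSet:
    """Concatenate fragment sets from the same genome."""
    if not sets:
        raise ValueError("nothing to merge")
    genomes = [s.genome for s in sets if s.genome is not None]
    if any(g != genomes[0] for g in genomes[1:]):
        raise ValueError("cannot merge fragment sets from different genomes")
    first = sets[0]
    return FragmentSet(
        sample_id=sample_id or first.sample_id,
        chroms=np.concatenate([s.chroms for s in sets]),
        starts=np.concatenate([s.starts for s in sets]),
        ends=np.concatenate([s.ends for s in sets]),
        condition=first.condition,
        pair_id=first.pair_id,
        genome=first.genome,
    )


def qc_filter(
    sets: list[FragmentSet],
    min_fragments: int = QC_MIN_FRAGMENTS,
    min_total_bp: int = QC_MIN_TOTAL_BP,
) -> list[QCReport]:
    """One pass/fail report per sample.

    A sample passes iff it has at least ``min_fragments`` fragments and at
    least ``min_total_bp`` bp of total fragment length.
    """
    reports = []
    for fs in sets:
        n = len(fs)
        bp = fs.total_bp
        reports.append(
            QCReport(
                sample_id=fs.sample_id,
                n_fragments=n,
                total_fragment_bp=bp,
                passed=(n >= min_fragments and bp >= min_total_bp),
            )
        )
    return reports


def chrM_fraction(fs: FragmentSet, genome: GenomeSpec) -> float:
    """Percentage of per-bp coverage mass on the mitochondrial chromosome.

    Equals 100 x (sum of fragment lengths on chrM) / (sum of all fragment
    lengths) because normalization rescales both numerator and denominator
    by the same constant.
    """
    if genome.mito is None:
        raise ValueError("genome does not designate a mitochondrial chromosome")
    total = fs.total_bp
    if total == 0:
        raise ValueError("zero total coverage")
    on_m = int(fs.lengths[fs.chroms == genome.mito].sum())
    return 100.0 * on_m / total
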