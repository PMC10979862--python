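"""Tumor-minus-normal hypertranscription statistics over annotated regions.

Per-region difference/average tables (Bland-Altman and MA coordinates),
rankings and rank-ordered difference curves, cross-pair composites, the
histone-cluster excess with a paired t-test, and mitochondrial comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import RegionSignal, make_track, region_sum
from .fragments import FragmentSet, chrM_fraction
from .genome import GenomeSpec
from .regions import Region, RegionSet

EPS = 1e-6  # pseudo-value guarding log transforms of zero-signal regions

RANK_MODES = ("absdiff", "tumor_minus_normal", "normal_minus_tumor")


@dataclass
class PairResult:
    """Per-region tumor/normal comparison for one pair."""

    pair_id: str
    regions: RegionSet
    table: pd.DataFrame  # region_id, T, N, diff, avg, log10_avg, log2_fc, rank_by_absdiff

    @property
    def diff(self) -> np.ndarray:
        return self.table["diff"].to_numpy()

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class HistoneStat:
    pair_ids: list[str]
    tumor_sums: np.ndarray
    normal_sums: np.ndarray
    excess: np.ndarray  # tumor_sum - normal_sum per replicate pair
    mean_excess: float
    sd_excess: float
    t_statistic: float | None
    p_value: float | None  # two-sided; None for a single replicate


def pair_diff(tumor: RegionSignal, normal: RegionSignal,
              regions: RegionSet, pair_id: str = "") -> PairResult:
    """Region-wise T - N differences with Bland-Altman and MA coordinates."""
    if tumor.region_ids != normal.region_ids:
        raise ValueError("tumor and normal signals cover different regions")
    if tumor.region_ids != regions.ids:
        raise ValueError("signals do not match the supplied region set")
    T = np.asarray(tumor.values, dtype=np.float64)
    N = np.asarray(normal.values, dtype=np.float64)
    diff = T - N
    avg = 0.5 * (T + N)
    with np.errstate(invalid="ignore", divide="ignore"):
        log10_avg = np.log10(avg + EPS)
        log2_fc = np.log2((T + EPS) / (N + EPS))
    table = pd.DataFrame(
        {
            "region_id": tumor.region_ids,
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "region_class": [r.region_class for r in regions],
            "T": T,
            "N": N,
            "diff": diff,
            "avg": avg,
            "log10_avg": log10_avg,
            "log2_fc": log2_fc,
        }
    )
    order = np.lexsort((table["start"], table["chrom"], -np.abs(diff)))
    ranks = np.empty(len(table), dtype=np.int64)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank_by_absdiff"] = ranks
    return PairResult(pair_id=pair_id, regions=regions, table=table)


def rank_regions(pr: PairResult, mode: str = "absdiff") -> list[Region]:
    """Regions in stable descending order of the chosen difference key.

    Ties are broken by (chrom, start) so output is reproducible.
    """
    if mode not in RANK_MODES:
        raise ValueError(f"mode must be one of {RANK_MODES}")
    diff = pr.diff
    key = {
        "absdiff": np.abs(diff),
        "tumor_minus_normal": diff,
        "normal_minus_tumor": -diff,
    }[mode]
    chroms = pr.table["chrom"].to_numpy()
    starts = pr.table["start"].to_numpy()
    order = np.lexsort((starts, chroms, -key))
    return [pr.regions[i] for i in order]


def rank_curve(pr: PairResult) -> tuple[np.ndarray, np.ndarray]:
    """Rank-ordered positive difference series for both directions.

    Returns (T - N sorted descending, N - T sorted descending), each keeping
    only strictly positive values so the curves can be drawn on a log scale.
    """
    diff = pr.diff
    up = np.sort(diff[diff > 0])[::-1]
    down = np.sort(-diff[diff < 0])[::-1]
    return up, down


def max_diff_composite(prs: list[PairResult]) -> pd.DataFrame:
    """Per-region maximum of T - N across pairs."""
    if not prs:
        raise ValueError("no pair results")
    ids = prs[0].table["region_id"].tolist()
    for pr in prs[1:]:
        if pr.table["region_id"].tolist() != ids:
            raise ValueError("pair results cover different region sets")
    diffs = np.stack([pr.diff for pr in prs])
    out = prs[0].table[["region_id", "chrom", "start", "end", "region_class"]].copy()
    out["max_diff"] = diffs.max(axis=0)
    return out


def histone_excess(
    pairs: list[tuple[FragmentSet, FragmentSet]],
    histones: RegionSet,
    genome: GenomeSpec,
) -> HistoneStat:
    """Summed-normalized-count excess over histone regions per replicate pair.

    ``pairs`` is a list of (tumor, normal) fragment sets. The excess for each
    pair is the difference of region sums over the histone region set; a
    two-sided paired t-test across replicates is reported for >= 2 pairs.
    """
    if len(histones) == 0:
        raise ValueError("empty histone region set")
    if not pairs:
        raise ValueError("need at least one replicate pair")
    t_sums, n_sums, ids = [], [], []
    for tumor_fs, normal_fs in pairs:
        t_track = make_track(tumor_fs, genome)
        n_track = make_track(normal_fs, genome)
        t_sums.append(float(region_sum(t_track, histones).values.sum()))
        n_sums.append(float(region_sum(n_track, histones).values.sum()))
        ids.append(tumor_fs.pair_id or tumor_fs.sample_id)
    t_sums = np.array(t_sums)
    n_sums = np.array(n_sums)
    excess = t_sums - n_sums
    if len(pairs) >= 2:
        t_stat, p = stats.ttest_1samp(excess, 0.0)
        t_stat, p = float(t_stat), float(p)
        sd = float(excess.std(ddof=1))
    else:
        t_stat = p = None
        sd = float("nan")
    return HistoneStat(
        pair_ids=ids, tumor_sums=t_sums, normal_sums=n_sums, excess=excess,
        mean_excess=float(excess.mean()), sd_excess=sd, t_statistic=t_stat, p_value=p,
    )


def mito_compare(
    pairs: list[tuple[FragmentSet, FragmentSet]], genome: GenomeSpec
) -> pd.DataFrame:
    """Per-pair mitochondrial signal percentages and tumor/normal ratio.

    The ratio is NaN (flagged in the ``ratio_defined`` column) when the
    normal percentage is zero.
    """
    rows = []
    for tumor_fs, normal_fs in pairs:
        t_pct = chrM_fraction(tumor_fs, genome)
        n_pct = chrM_fraction(normal_fs, genome)
        defined = n_pct > 0
        rows.append(
            {
                "pair_id": tumor_fs.pair_id or tumor_fs.sample_id,
                "tumor_chrM_pct": t_pct,
                "normal_chrM_pct": n_pct,
                "ratio": t_pct / n_pct if defined else float("nan"),
                "ratio_defined": defined,
            }
        )
    return pd.DataFrame(rows)
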