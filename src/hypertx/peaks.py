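"""Paired-control sparse-enrichment peak calling.

Signal blocks are maximal runs of strictly positive normalized coverage; each
block's AUC (summed signal) is the thresholded statistic. The threshold is
chosen to maximize the difference between the fraction of target blocks and
the fraction of (depth-scaled) control blocks exceeding it; "relaxed" mode
takes the smallest threshold reaching 90% of that maximum gain.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .coverage import CoverageTrack
from .regions import Region, RegionSet

RELAXED_GAIN_FRACTION = 0.9


@dataclass(frozen=True)
class SignalBlock:
    chrom: str
    start: int
    end: int
    auc: float
    max_height: float


@dataclass
class PeakCallResult:
    peaks: list[SignalBlock]
    threshold_auc: float
    control_scale: float
    n_target_blocks: int
    n_control_blocks: int
    mode: str = "relaxed"

    def write_bed(self, path: str | Path) -> None:
        """BED6-style output with the block AUC as score."""
        with open(path, "w") as fh:
            for i, p in enumerate(self.peaks, 1):
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{float(p.auc)!r}\t.\n")

    def write_meta(self, path: str | Path) -> None:
        meta = {
            "n_peaks": len(self.peaks),
            "threshold_auc": self.threshold_auc,
            "control_scale": self.control_scale,
            "n_target_blocks": self.n_target_blocks,
            "n_control_blocks": self.n_control_blocks,
            "mode": self.mode,
        }
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=1)


def find_blocks(track: CoverageTrack) -> list[SignalBlock]:
    """Maximal runs of strictly positive signal, sorted by (chrom, start)."""
    blocks: list[SignalBlock] = []
    for chrom in track.genome.chroms:
        arr = track.data[chrom]
        pos = arr > 0
        if not pos.any():
            continue
        # run starts: transitions 0->1 (plus index 0 if positive there)
        rise = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
        fall = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1
        starts = np.concatenate(([0], rise)) if pos[0] else rise
        ends = np.concatenate((fall, [arr.size])) if pos[-1] else fall
        # direct per-block segment sums: identical signal segments yield
        # bitwise-identical AUCs (prefix-sum differences would not)
        bounds = np.empty(2 * starts.size, dtype=np.int64)
        bounds[0::2] = starts
        bounds[1::2] = ends
        trailing = bounds[-1] == arr.size
        if trailing:
            bounds = bounds[:-1]
        sums = np.add.reduceat(arr, bounds)
        aucs = sums[0::2]
        maxima = np.maximum.reduceat(arr, bounds)[0::2]
        for s, e, a, h in zip(starts, ends, aucs, maxima):
            blocks.append(SignalBlock(chrom, int(s), int(e), float(a), float(h)))
    return blocks


def call_peaks(
    target: CoverageTrack,
    control: CoverageTrack,
    mode: str = "relaxed",
    relaxed_fraction: float = RELAXED_GAIN_FRACTION,
) -> PeakCallResult:
    """Call target-over-control enriched blocks.

    The control track is depth-scaled by ``s = sum(target) / sum(control)``.
    Candidate thresholds are the merged block AUCs of both samples; the gain
    at ``t`` is the fraction of target blocks minus the fraction of scaled
    control blocks with AUC above ``t``. "stringent" picks the smallest
    threshold attaining the maximum gain; "relaxed" the smallest threshold
    with gain >= ``relaxed_fraction`` of the maximum. A non-positive maximum
    gain yields zero peaks.
    """
    if mode not in ("relaxed", "stringent"):
        raise ValueError("mode must be 'relaxed' or 'stringent'")
    if target.genome is not control.genome and target.genome != control.genome:
        raise ValueError("target and control tracks are on different genomes")
    control_sum = control.sum()
    if control_sum <= 0:
        raise ValueError("empty control track: a paired control is mandatory")
    target_sum = target.sum()
    if target_sum <= 0:
        raise ValueError("empty target track")
    s = target_sum / control_sum
    if abs(s - 1.0) < 1e-9:
        s = 1.0  # tracks normalized to the same total; avoid epsilon rescaling

    target_blocks = find_blocks(target)
    control_blocks = find_blocks(control)
    t_aucs = np.array([b.auc for b in target_blocks])
    c_aucs = np.array([b.auc * s for b in control_blocks])
    if t_aucs.size == 0:
        return PeakCallResult([], float("inf"), s, 0, len(control_blocks), mode)

    candidates = np.unique(np.concatenate([t_aucs, c_aucs]))
    t_sorted = np.sort(t_aucs)
    c_sorted = np.sort(c_aucs)
    frac_t = 1.0 - np.searchsorted(t_sorted, candidates, side="right") / t_sorted.size
    frac_c = (
        1.0 - np.searchsorted(c_sorted, candidates, side="right") / c_sorted.size
        if c_sorted.size
        else np.zeros_like(candidates)
    )
    gain = frac_t - frac_c
    max_gain = gain.max()
    if max_gain <= 0:
        return PeakCallResult([], float("inf"), s, len(target_blocks), len(control_blocks), mode)
    if mode == "stringent":
        t_star = float(candidates[int(np.argmax(gain))])  # argmax takes smallest on ties
    else:
        ok = np.flatnonzero(gain >= relaxed_fraction * max_gain)
        t_star = float(candidates[ok[0]])
    peaks = [b for b in target_blocks if b.auc > t_star]
    return PeakCallResult(peaks, t_star, s, len(target_blocks), len(control_blocks), mode)


def overlap_top_regions(
    ranked: list[Region],
    peakcalls: dict[str, PeakCallResult],
    K: int,
) -> tuple[list[tuple[Region, int]], float]:
    """For the top-K ranked regions, count pairs with >= 1 bp peak overlap.

    Returns the per-region (region, n_overlapping_pairs) list and the mean
    count over the K regions.
    """
    if K > len(ranked):
        raise ValueError(f"K={K} exceeds the {len(ranked)} ranked regions")
    top = ranked[:K]
    # sorted peak intervals per pair and chromosome, with prefix-max of ends
    indexed: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for pair_id, call in peakcalls.items():
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in call.peaks:
            per_chrom.setdefault(p.chrom, []).append((p.start, p.end))
        indexed[pair_id] = {}
        for chrom, iv in per_chrom.items():
            iv.sort()
            starts = np.array([x[0] for x in iv], dtype=np.int64)
            ends = np.maximum.accumulate(np.array([x[1] for x in iv], dtype=np.int64))
            indexed[pair_id][chrom] = (starts, ends)
    counts = []
    for r in top:
        n = 0
        for pair_id in peakcalls:
            idx = indexed[pair_id].get(r.chrom)
            if idx is None:
                continue
            starts, ends_max = idx
            k = int(np.searchsorted(starts, r.end, side="left"))
            if k > 0 and ends_max[k - 1] > r.start:
                n += 1
        counts.append((r, n))
    mean = float(np.mean([c for _, c in counts])) if counts else 0.0
    return counts, mean
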