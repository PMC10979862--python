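"""Amplified-segment analysis: tiled signal, local-regression smoothing,
broad-summit detection and windowed fold change."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .coverage import CoverageTrack
from .regions import RegionSet

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 1000
SPAN_CHOICES = (0.2, 0.5)


@dataclass
class TileCurve:
    chrom: str
    start: int
    end: int
    bin_size: int
    tumor: np.ndarray  # per-bin summed normalized counts
    normal: np.ndarray
    span: float | None = None
    tumor_smooth: np.ndarray | None = None
    normal_smooth: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.tumor)

    def bin_centers(self) -> np.ndarray:
        return self.start + (np.arange(self.n_bins) + 0.5) * self.bin_size

    @property
    def excess_smooth(self) -> np.ndarray:
        if self.tumor_smooth is None or self.normal_smooth is None:
            raise ValueError("curve has not been smoothed; call smooth_curve first")
        return self.tumor_smooth - self.normal_smooth

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            header = "chrom\tstart\tend\ttumor\tnormal"
            smoothed = self.tumor_smooth is not None
            if smoothed:
                header += "\ttumor_smooth\tnormal_smooth"
            fh.write(header + "\n")
            for i in range(self.n_bins):
                s = self.start + i * self.bin_size
                e = min(s + self.bin_size, self.end)
                row = f"{self.chrom}\t{s}\t{e}\t{float(self.tumor[i])!r}\t{float(self.normal[i])!r}"
                if smoothed:
                    row += f"\t{float(self.tumor_smooth[i])!r}\t{float(self.normal_smooth[i])!r}"
                fh.write(row + "\n")


@dataclass(frozen=True)
class Summit:
    chrom: str
    center: float  # bp
    height: float  # smoothed tumor - normal at the summit
    prominence: float
    width_at_half_prominence: float  # bp
    anchor_offset: float | None  # distance to nearest anchor center, if anchors given


def tile_counts(
    tumor: CoverageTrack,
    normal: CoverageTrack,
    window: tuple[str, int, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> TileCurve:
    """Sum normalized counts of both samples in fixed-size bins over a window.

    The last bin may be partial.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chrom, start, end = window
    for track in (tumor, normal):
        if chrom not in track.genome or not 0 <= start < end <= track.genome.lengths[chrom]:
            raise ValueError(f"window {window} outside genome bounds")
    n_bins = int(np.ceil((end - start) / bin_size))
    edges = np.minimum(start + np.arange(n_bins + 1) * bin_size, end)

    def _bin(track: CoverageTrack) -> np.ndarray:
        p = track.prefix(chrom)
        return (p[edges[1:]] - p[edges[:-1]]).astype(np.float64)

    return TileCurve(chrom=chrom, start=start, end=end, bin_size=bin_size,
                     tumor=_bin(tumor), normal=_bin(normal))


def loess_fit(y: np.ndarray, span: float, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each point the ``ceil(span * n)`` nearest neighbours (contiguous in
    index space) are fit with a weighted polynomial of the given degree and
    the fitted value at the point is returned. Falls back to degree 1 (with a
    log message) when the neighbourhood is too small for a quadratic fit.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if n < 10:
        raise ValueError("need at least 10 points to smooth")
    k = max(int(np.ceil(span * n)), 2)
    if k < degree + 2:
        logger.info("loess window of %d points too small for degree %d; using degree 1",
                    k, degree)
        degree = 1
    out = np.empty(n)
    x = np.arange(n, dtype=np.float64)
    for i in range(n):
        lo = min(max(i - (k - 1) // 2, 0), n - k)
        xs = x[lo:lo + k] - i
        ys = y[lo:lo + k]
        dmax = np.abs(xs).max()
        if dmax == 0:
            out[i] = ys[0]
            continue
        w = (1.0 - np.minimum(np.abs(xs) / dmax, 1.0) ** 3) ** 3
        w[np.abs(xs) >= dmax] = 0.0
        if np.count_nonzero(w) < degree + 1:
            w = np.maximum(w, 1e-12)
        # weighted least squares on the Vandermonde basis, evaluated at xs=0
        V = np.vander(xs, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], ys * sw, rcond=None)
        out[i] = coef[0]
    return out


def smooth_curve(tc: TileCurve, span: float = 0.2) -> TileCurve:
    """Return a copy of the curve with LOESS-smoothed tumor/normal series."""
    return replace(
        tc,
        span=span,
        tumor_smooth=loess_fit(tc.tumor, span),
        normal_smooth=loess_fit(tc.normal, span),
    )


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def detect_summits(
    tc: TileCurve,
    min_prominence: float | None = None,
    anchors: RegionSet | None = None,
) -> list[Summit]:
    """Local maxima of the smoothed tumor excess with sufficient prominence.

    Prominence is measured against the lower of the two flanking minima
    (walking outward until a higher value or the series edge). The default
    threshold is twice the median absolute deviation of the excess series.
    Width is measured at half prominence. If anchors are given, the distance
    from each summit to the nearest anchor center is reported.
    """
    e = tc.excess_smooth
    n = e.size
    if min_prominence is None:
        min_prominence = 2.0 * _mad(e)
    # local maxima (plateau-aware: first index of each maximal plateau)
    candidates = []
    i = 1
    while i < n - 1:
        if e[i] > e[i - 1]:
            j = i
            while j + 1 < n and e[j + 1] == e[j]:
                j += 1
            if j + 1 >= n or e[j + 1] < e[j]:
                candidates.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    summits: list[Summit] = []
    anchor_centers = None
    if anchors is not None and len(anchors):
        anchor_centers = np.array(
            [r.center for r in anchors if r.chrom == tc.chrom], dtype=np.float64
        )
    centers_bp = tc.bin_centers()
    for idx in candidates:
        h = e[idx]
        left_min = h
        j = idx - 1
        while j >= 0 and e[j] <= h:
            left_min = min(left_min, e[j])
            j -= 1
        right_min = h
        j = idx + 1
        while j < n and e[j] <= h:
            right_min = min(right_min, e[j])
            j += 1
        prominence = h - min(left_min, right_min)
        if prominence <= 0 or prominence < min_prominence:
            continue
        half = h - prominence / 2.0
        lo = idx
        while lo > 0 and e[lo - 1] >= half:
            lo -= 1
        hi = idx
        while hi < n - 1 and e[hi + 1] >= half:
            hi += 1
        width = (hi - lo + 1) * tc.bin_size
        center = float(centers_bp[idx])
        offset = None
        if anchor_centers is not None and anchor_centers.size:
            offset = float(np.min(np.abs(anchor_centers - center)))
        summits.append(Summit(chrom=tc.chrom, center=center, height=float(h),
                              prominence=float(prominence),
                              width_at_half_prominence=float(width),
                              anchor_offset=offset))
    summits.sort(key=lambda s: -s.prominence)
    return summits


def window_fold_change(
    tumor: CoverageTrack, normal: CoverageTrack, window: tuple[str, int, int]
) -> float:
    """Ratio of summed normalized counts (tumor / normal) within a window.

    Returns NaN (with a log warning) when the normal window sum is zero.
    """
    chrom, start, end = window
    for track in (tumor, normal):
        if chrom not in track.genome or not 0 <= start < end <= track.genome.lengths[chrom]:
            raise ValueError(f"window {window} outside genome bounds")
    t = tumor.interval_sum(chrom, start, end)
    n = normal.interval_sum(chrom, start, end)
    if n == 0:
        logger.warning("window %s has zero normal signal; fold change undefined", window)
        return float("nan")
    return t / n


def write_summits_bed(summits: list[Summit], path: str | Path, bin_size: int) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(summits, 1):
            lo = int(s.center - bin_size / 2)
            hi = int(s.center + bin_size / 2)
            fh.write(f"{s.chrom}\t{lo}\t{hi}\tsummit_{i}\t{s.prominence!r}\t.\n")
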