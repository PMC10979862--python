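"""Region x sample count matrix, TF-IDF normalization, and sample embedding."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse

from .fragments import FragmentSet
from .regions import RegionSet

TFIDF_SCALE = 1e4
SCALE_CAP = 10.0
DEFAULT_N_PCS = 50
DEFAULT_MAX_FEATURES = 25_000


@dataclass
class CountMatrix:
    """Raw fragment counts overlapping each region (rows) per sample (columns)."""

    matrix: np.ndarray  # (n_regions, n_samples) non-negative ints
    region_ids: list[str]
    sample_ids: list[str]

    def write_mtx(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(self.matrix))
        prefix.with_suffix(".rows.txt").write_text("\n".join(self.region_ids) + "\n")
        prefix.with_suffix(".cols.txt").write_text("\n".join(self.sample_ids) + "\n")

    @classmethod
    def read_mtx(cls, prefix: str | Path) -> "CountMatrix":
        prefix = Path(prefix)
        m = np.asarray(spio.mmread(str(prefix.with_suffix(".mtx"))).todense())
        rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
        cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
        return cls(matrix=m.astype(np.int64), region_ids=rows, sample_ids=cols)


@dataclass
class Embedding:
    sample_ids: list[str]
    coords: np.ndarray  # (n_samples, 2)
    pcs: np.ndarray  # (n_samples, n_pcs) principal-component scores
    components: np.ndarray  # (n_pcs, n_features) orthonormal loadings
    feature_ids: list[str]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tx\ty\n")
            for sid, (x, y) in zip(self.sample_ids, self.coords):
                fh.write(f"{sid}\t{float(x)!r}\t{float(y)!r}\n")


def build_matrix(samples: list[FragmentSet], regions: RegionSet) -> CountMatrix:
    """Count fragments overlapping each region by >= 1 bp.

    A fragment overlapping k regions is counted once in each of the k rows.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if not samples:
        raise ValueError("no samples")
    n_r, n_s = len(regions), len(samples)
    out = np.zeros((n_r, n_s), dtype=np.int64)
    by_chrom = regions.by_chrom()
    disjoint = all(
        (s[1:] >= np.maximum.accumulate(e)[:-1]).all() if s.size > 1 else True
        for s, e, _ in by_chrom.values()
    )
    for j, fs in enumerate(samples):
        for chrom, (rs, re, ridx) in by_chrom.items():
            sel = fs.chroms == chrom
            if not sel.any():
                continue
            fstart = fs.starts[sel]
            fend = fs.ends[sel]
            if disjoint:
                # fragment overlaps regions [lo, hi): lo = first region ending
                # after frag start, hi = first region starting at/after frag end
                lo = np.searchsorted(re, fstart, side="right")
                hi = np.searchsorted(rs, fend, side="left")
                valid = hi > lo
                delta = np.zeros(rs.size + 1, dtype=np.int64)
                np.add.at(delta, lo[valid], 1)
                np.add.at(delta, hi[valid], -1)
                out[ridx, j] += np.cumsum(delta[:-1])
            else:
                for s, e, i in zip(rs, re, ridx):
                    out[i, j] += int(((fstart < e) & (fend > s)).sum())
    return CountMatrix(matrix=out, region_ids=regions.ids,
                       sample_ids=[fs.sample_id for fs in samples])


def tfidf_normalize(m: CountMatrix) -> CountMatrix:
    """TF-IDF transform: ``ln(1 + 1e4 * tf * idf)``.

    ``tf`` is the count divided by the sample's column sum; ``idf`` is the
    number of samples over the number of samples in which the region occurs.
    Rows with no occurrences anywhere are dropped with a warning. Raises on
    all-zero columns.
    """
    counts = m.matrix.astype(np.float64)
    col_sums = counts.sum(axis=0)
    if (col_sums == 0).any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(col_sums == 0)]
        raise ValueError(f"all-zero sample columns: {bad}")
    df = (counts > 0).sum(axis=1)
    keep = df > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} regions with zero occurrences")
        counts = counts[keep]
        df = df[keep]
    n_samples = counts.shape[1]
    tf = counts / col_sums
    idf = n_samples / df
    x = np.log1p(TFIDF_SCALE * tf * idf[:, None])
    return CountMatrix(matrix=x, region_ids=[r for r, k in zip(m.region_ids, keep) if k],
                       sample_ids=list(m.sample_ids))


def reduce_and_embed(
    x: CountMatrix,
    n_features: int | None = None,
    n_pcs: int = DEFAULT_N_PCS,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> Embedding:
    """Top-feature selection, row scaling, PCA and 2-D UMAP embedding.

    Features (rows) are ranked by total signal; the selected rows are centered
    and scaled to unit variance with values capped at ``|z| <= 10``; PCA runs
    on samples; the 2-D embedding is seeded for determinism. ``n_pcs`` is
    lowered (with a warning) when it exceeds what the data supports.
    """
    from sklearn.decomposition import PCA

    mat = np.asarray(x.matrix, dtype=np.float64)
    n_r, n_s = mat.shape
    if n_features is None:
        n_features = min(DEFAULT_MAX_FEATURES, n_r)
    n_features = min(n_features, n_r)
    order = np.argsort(-mat.sum(axis=1), kind="stable")[:n_features]
    order = np.sort(order)
    sub = mat[order]
    feature_ids = [x.region_ids[i] for i in order]

    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = np.clip((sub - mean) / sd, -SCALE_CAP, SCALE_CAP)

    max_pcs = min(n_s - 1, n_features)
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} exceeds the data rank; using {max_pcs}")
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full")
    pcs = pca.fit_transform(z.T)  # samples are observations

    import umap

    # embed unique points only so identical samples get identical coordinates
    uniq, inverse = np.unique(np.round(pcs, 12), axis=0, return_inverse=True)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=max(2, min(n_neighbors, uniq.shape[0] - 1)),
        min_dist=min_dist,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about small n / forced determinism
        coords = np.asarray(reducer.fit_transform(uniq))[inverse]
    return Embedding(
        sample_ids=list(x.sample_ids),
        coords=np.asarray(coords, dtype=np.float64),
        pcs=pcs,
        components=pca.components_,
        feature_ids=feature_ids,
    )
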