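"""Synthetic paired tumor/normal fragment data with a planted-effect ledger.

Fragments are drawn from a finite mixture over emission components:
a uniform nuclear background, annotated regions (regulatory elements and
histone-cluster genes, midpoints Gaussian around region centers), and the
mitochondrial chromosome. The tumor sample applies planted multipliers —
a hypertranscription factor ``h`` on selected regions, a histone-cluster
factor, a copy-number factor ``a`` with optional Gaussian summits inside an
amplified segment — and a mitochondrial depletion factor ``d`` that fixes
the tumor chrM emission probability at ``d`` times the normal one.

The returned :class:`SimTruth` records exactly what was planted so that
downstream statistics can be validated against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fragments import FragmentSet
from .genome import GenomeSpec
from .regions import Region, RegionSet

_DEFAULT_CLASS_MIX = {
    "promoter": 0.25,
    "H3K4me3": 0.10,
    "proximal_enhancer": 0.20,
    "distal_enhancer": 0.35,
    "CTCF": 0.10,
}

HISTONE_CLASS = "histone"


class SizingError(ValueError):
    """Requested region layout does not fit in the declared genome."""


@dataclass(frozen=True)
class SimConfig:
    # genome layout
    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000)
    chrM_length: int = 16_000
    # region annotation
    n_ccres: int = 1000
    ccre_class_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CLASS_MIX))
    ccre_width: int = 300
    class_weights: dict[str, float] = field(default_factory=dict)  # emission weight per class
    histone_cluster: tuple[str, int, int, int] | None = ("chr2", 600_000, 680_000, 16)
    # emission mixture
    p_background: float = 0.30
    p_chrM_normal: float = 0.05
    chrM_depletion_factor: float = 1.0  # d, tumor chrM probability = d * p_chrM_normal
    matched_background: bool = False  # share background fragments between the pair
    # planted effects
    hyper_fraction: float = 0.0  # f
    hyper_factor: float = 1.0  # h
    hyper_ids: tuple[str, ...] | None = None  # explicit planted set overrides hyper_fraction
    histone_factor: float = 1.0
    amplicon: tuple[str, int, int, float] | None = None  # (chrom, start, end, a)
    summits: tuple[tuple[float, float, float], ...] = ()  # (center, width_sd, multiplier)
    # fragments
    frag_len_mean: float = 150.0
    frag_len_sd: float = 25.0
    frag_len_min: int = 50
    frag_len_max: int = 400
    duplicate_rate: float = 0.0  # q
    n_fragments: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        for name, p in (("p_background", self.p_background),
                        ("p_chrM_normal", self.p_chrM_normal),
                        ("duplicate_rate", self.duplicate_rate),
                        ("hyper_fraction", self.hyper_fraction)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_background + self.p_chrM_normal > 1.0 + 1e-12:
            raise ValueError("p_background + p_chrM_normal exceeds 1")
        if not 0.0 < self.chrM_depletion_factor <= 1.0:
            raise ValueError("chrM depletion factor d must satisfy 0 < d <= 1")
        if self.hyper_factor < 1.0:
            raise ValueError("hyper factor h must be >= 1")
        if self.histone_factor <= 0:
            raise ValueError("histone_factor must be positive")
        if any(l <= 0 for l in self.chrom_lengths) or self.chrM_length <= 0:
            raise ValueError("chromosome lengths must be positive")
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        if not 0 < self.frag_len_min <= self.frag_len_max:
            raise ValueError("invalid fragment length bounds")
        if sum(self.ccre_class_mix.values()) <= 0:
            raise ValueError("ccre_class_mix must have positive total weight")
        lengths = self._chrom_length_map()
        if self.amplicon is not None:
            chrom, s, e, a = self.amplicon
            if chrom not in lengths or not 0 <= s < e <= lengths[chrom]:
                raise ValueError("amplicon outside declared chromosomes")
            if a < 1.0:
                raise ValueError("amplicon copy number a must be >= 1")
            for c, _sd, _m in self.summits:
                if not s <= c < e:
                    raise ValueError("summit center outside the amplicon")
        elif self.summits:
            raise ValueError("summits require an amplicon")
        if self.histone_cluster is not None:
            chrom, s, e, n_genes = self.histone_cluster
            if chrom not in lengths or not 0 <= s < e <= lengths[chrom]:
                raise ValueError("histone cluster outside declared chromosomes")
            if n_genes <= 0:
                raise ValueError("histone cluster needs at least one gene")

    def _chrom_length_map(self) -> dict[str, int]:
        lengths = {f"chr{i + 1}": L for i, L in enumerate(self.chrom_lengths)}
        lengths["chrM"] = self.chrM_length
        return lengths

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("chrom_lengths", "summits", "hyper_ids", "amplicon", "histone_cluster"):
            if raw.get(key) is not None:
                val = raw[key]
                if key == "summits":
                    val = tuple(tuple(x) for x in val)
                else:
                    val = tuple(val)
                raw[key] = val
        return cls(**raw)


@dataclass
class SimTruth:
    """Ledger of planted effects, in the units the simulator actually used."""

    hyper_ccre_ids: list[str]
    region_ids: list[str]
    weight_normal: dict[str, float]  # per-region emission probability, normal
    weight_tumor: dict[str, float]  # per-region emission probability, tumor
    multiplier: dict[str, float]  # planted multiplier product per region
    amplicon: tuple[str, int, int, float] | None
    summits: tuple[tuple[float, float, float], ...]
    expected_chrM_fraction: tuple[float, float]  # (normal, tumor) emission probability
    histone_factor: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonable(asdict(self)), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["amplicon"] = tuple(raw["amplicon"]) if raw["amplicon"] is not None else None
        raw["summits"] = tuple(tuple(s) for s in raw["summits"])
        raw["expected_chrM_fraction"] = tuple(raw["expected_chrM_fraction"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def make_genome(config: SimConfig) -> tuple[GenomeSpec, RegionSet]:
    """Build the genome and a non-overlapping annotated region set.

    Regulatory elements are placed by sampling disjoint slots of twice the
    element width on the nuclear chromosomes (never on chrM, never inside the
    histone cluster), guaranteeing disjointness by construction. Histone genes
    are laid out evenly inside the declared cluster. Deterministic under the
    config seed.
    """
    config.validate()
    lengths = config._chrom_length_map()
    genome = GenomeSpec(lengths=lengths, mito="chrM")
    rng = np.random.default_rng([config.seed, 0])

    slot = 2 * config.ccre_width
    slots: list[tuple[str, int]] = []  # (chrom, slot start)
    hist = config.histone_cluster
    for chrom in genome.chroms:
        if chrom == genome.mito:
            continue
        for k in range(lengths[chrom] // slot):
            s0 = k * slot
            if hist is not None and chrom == hist[0] and s0 < hist[2] and s0 + slot > hist[1]:
                continue
            slots.append((chrom, s0))
    if config.n_ccres > len(slots):
        raise SizingError(
            f"cannot place {config.n_ccres} elements of width {config.ccre_width} "
            f"on {sum(config.chrom_lengths)} bp of nuclear genome"
        )

    chosen = sorted(rng.choice(len(slots), size=config.n_ccres, replace=False))
    jitter = rng.integers(0, slot - config.ccre_width + 1, size=config.n_ccres)
    class_names = list(config.ccre_class_mix)
    mix = np.array([config.ccre_class_mix[c] for c in class_names], dtype=np.float64)
    classes = rng.choice(class_names, size=config.n_ccres, p=mix / mix.sum())

    regions: list[Region] = []
    width = int(np.ceil(np.log10(max(config.n_ccres, 10))))
    for i, (slot_i, off, cls) in enumerate(zip(chosen, jitter, classes)):
        chrom, s0 = slots[slot_i]
        start = int(s0 + off)
        regions.append(Region(chrom, start, start + config.ccre_width,
                              f"ccre_{i:0{width}d}", str(cls)))
    if hist is not None:
        chrom, s, e, n_genes = hist
        step = (e - s) / n_genes
        for g in range(n_genes):
            gs = int(s + g * step + step / 4)
            ge = int(s + g * step + 3 * step / 4)
            regions.append(Region(chrom, gs, ge, f"hist_{g:03d}", HISTONE_CLASS))
    rs = RegionSet(regions)
    rs.validate(genome)
    return genome, rs


def _amp_factor(config: SimConfig, chrom: str, x: np.ndarray | float):
    """Emission multiplier a * summit(x) inside the amplicon, 1 elsewhere."""
    if config.amplicon is None:
        return np.ones_like(np.asarray(x, dtype=np.float64))
    achrom, s, e, a = config.amplicon
    x = np.asarray(x, dtype=np.float64)
    f = np.ones_like(x)
    if chrom != achrom:
        return f
    inside = (x >= s) & (x < e)
    bump = np.ones_like(x)
    for c, sd, mult in config.summits:
        bump *= 1.0 + (mult - 1.0) * np.exp(-0.5 * ((x - c) / sd) ** 2)
    f[inside] = a * bump[inside]
    return f


class _Components:
    """Precomputed emission layout shared between the two samples."""

    def __init__(self, config: SimConfig, genome: GenomeSpec, regions: RegionSet):
        self.config = config
        self.genome = genome
        self.regions = regions
        self.r_chrom = np.array([r.chrom for r in regions], dtype=object)
        self.r_center = np.array([r.center for r in regions], dtype=np.float64)
        self.r_width = np.array([r.width for r in regions], dtype=np.float64)
        self.r_class = np.array([r.region_class for r in regions], dtype=object)
        self.base_w = np.array(
            [config.class_weights.get(r.region_class, 1.0) for r in regions], dtype=np.float64
        )
        # nuclear segments for uniform background (chrM excluded by design so
        # that the chrM emission probability is exactly the configured one)
        self.bg_segments = [
            (c, 0, genome.lengths[c]) for c in genome.chroms if c != genome.mito
        ]
        self.nuclear_len = sum(e - s for _, s, e in self.bg_segments)


def _sample_background(comp: _Components, n: int, rng: np.random.Generator,
                       amplified: bool) -> tuple[np.ndarray, np.ndarray]:
    """Uniform nuclear midpoints; inside an amplified segment the density is
    multiplied by a * summit(x) when ``amplified`` is set."""
    config = comp.config
    seg_chrom = np.array([c for c, _, _ in comp.bg_segments], dtype=object)
    seg_start = np.array([s for _, s, _ in comp.bg_segments], dtype=np.float64)
    seg_len = np.array([e - s for _, s, e in comp.bg_segments], dtype=np.float64)

    if not amplified or config.amplicon is None:
        which = rng.choice(len(seg_len), size=n, p=seg_len / seg_len.sum())
        mids = seg_start[which] + rng.random(n) * seg_len[which]
        return seg_chrom[which], mids

    achrom, as_, ae, _a = config.amplicon
    amp_len = ae - as_
    grid = 100  # bp; fine enough for summits tens of kb wide
    edges = np.arange(as_, ae + grid, grid, dtype=np.float64)
    edges[-1] = ae
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_w = np.diff(edges)
    bin_mass = _amp_factor(config, achrom, centers) * bin_w
    w_in = float(bin_mass.sum())
    w_out = float(comp.nuclear_len - amp_len)
    n_in = rng.binomial(n, w_in / (w_in + w_out))
    # inside: inverse-CDF over the grid
    bins = rng.choice(len(centers), size=n_in, p=bin_mass / w_in)
    mids_in = edges[bins] + rng.random(n_in) * bin_w[bins]
    chrom_in = np.full(n_in, achrom, dtype=object)
    # outside: uniform over nuclear segments minus the amplicon
    segs = []
    for c, s, e in comp.bg_segments:
        if c == achrom:
            if s < as_:
                segs.append((c, s, as_))
            if ae < e:
                segs.append((c, ae, e))
        else:
            segs.append((c, s, e))
    sc = np.array([c for c, _, _ in segs], dtype=object)
    ss = np.array([s for _, s, _ in segs], dtype=np.float64)
    sl = np.array([e - s for _, s, e in segs], dtype=np.float64)
    n_out = n - n_in
    which = rng.choice(len(sl), size=n_out, p=sl / sl.sum())
    mids_out = ss[which] + rng.random(n_out) * sl[which]
    return (np.concatenate([chrom_in, sc[which]]),
            np.concatenate([mids_in, mids_out]))


def _emit(comp: _Components, probs_bg: float, probs_regions: np.ndarray, probs_chrM: float,
          n: int, rng: np.random.Generator, amplified: bool,
          shared_bg: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one sample's fragments. Returns (chroms, starts, ends)."""
    config = comp.config
    genome = comp.genome
    q = config.duplicate_rate
    dup = rng.random(n) < q
    dup[0] = False
    n_dup = int(dup.sum())
    n_fresh = n - n_dup

    chrom_parts: list[np.ndarray] = []
    mid_parts: list[np.ndarray] = []
    pre_built: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    if shared_bg is not None:
        n_bg = len(shared_bg[0])
        if n_bg > n_fresh:
            raise ValueError("matched background larger than fresh fragment budget")
        pre_built.append(shared_bg)
        rest = np.concatenate([probs_regions, [probs_chrM]])
        total = rest.sum()
        counts = rng.multinomial(n_fresh - n_bg, rest / total) if total > 0 else \
            np.zeros(len(rest), dtype=np.int64)
        region_counts, n_chrM = counts[:-1], int(counts[-1])
    else:
        vec = np.concatenate([[probs_bg], probs_regions, [probs_chrM]])
        counts = rng.multinomial(n_fresh, vec / vec.sum())
        n_bg, region_counts, n_chrM = int(counts[0]), counts[1:-1], int(counts[-1])
        if n_bg:
            bgc, bgm = _sample_background(comp, n_bg, rng, amplified)
            chrom_parts.append(bgc)
            mid_parts.append(bgm)

    total_region = int(region_counts.sum())
    if total_region:
        rep = np.repeat(np.arange(len(region_counts)), region_counts)
        mids = comp.r_center[rep] + rng.standard_normal(total_region) * (comp.r_width[rep] / 4.0)
        limits = np.array([genome.lengths[c] for c in comp.r_chrom[rep]], dtype=np.float64)
        mids = np.clip(mids, 0.0, limits - 1.0)
        chrom_parts.append(comp.r_chrom[rep])
        mid_parts.append(mids)
    if n_chrM:
        chrom_parts.append(np.full(n_chrM, genome.mito, dtype=object))
        mid_parts.append(rng.random(n_chrM) * genome.lengths[genome.mito])

    if chrom_parts:
        chroms = np.concatenate(chrom_parts)
        mids = np.concatenate(mid_parts)
        m = len(chroms)
        lens = rng.normal(config.frag_len_mean, config.frag_len_sd, m)
        lens = np.clip(np.rint(lens), config.frag_len_min, config.frag_len_max).astype(np.int64)
        limits = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
        lens = np.minimum(lens, limits)
        starts = np.rint(mids - lens / 2.0).astype(np.int64)
        starts = np.clip(starts, 0, limits - lens)
        ends = starts + lens
    else:
        chroms = np.empty(0, dtype=object)
        starts = ends = np.empty(0, dtype=np.int64)

    if pre_built:
        chroms = np.concatenate([pre_built[0][0], chroms])
        starts = np.concatenate([pre_built[0][1], starts])
        ends = np.concatenate([pre_built[0][2], ends])

    if n_dup:
        idx = rng.integers(0, n_fresh, size=n_dup)
        chroms = np.concatenate([chroms, chroms[idx]])
        starts = np.concatenate([starts, starts[idx]])
        ends = np.concatenate([ends, ends[idx]])
    return chroms, starts, ends


def simulate_pair(
    config: SimConfig, genome: GenomeSpec, regions: RegionSet, seed: int | None = None
) -> tuple[FragmentSet, FragmentSet, SimTruth]:
    """Draw a paired tumor/normal fragment set plus the planted-effect ledger.

    Both samples contain exactly ``config.n_fragments`` fragments, sorted by
    (chrom, start, end), byte-identical across runs with the same config.
    ``seed`` overrides ``config.seed`` for the fragment draw (replicates share
    one genome/region layout but need independent draws).
    """
    config.validate()
    if len(regions) == 0:
        raise ValueError("empty region set")
    comp = _Components(config, genome, regions)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, 1])

    is_ccre = comp.r_class != HISTONE_CLASS
    ccre_ids = [r.region_id for r, c in zip(regions, is_ccre) if c]
    if config.hyper_ids is not None:
        hyper_ids = set(config.hyper_ids)
        unknown = hyper_ids - set(ccre_ids)
        if unknown:
            raise ValueError(f"hyper_ids not in region set: {sorted(unknown)[:5]}")
    else:
        n_hyper = int(round(config.hyper_fraction * len(ccre_ids)))
        hyper_ids = set(rng.choice(ccre_ids, size=n_hyper, replace=False)) if n_hyper else set()
    is_hyper = np.array([r.region_id in hyper_ids for r in regions])

    # normal emission probabilities
    p_bg, p_chrM = config.p_background, config.p_chrM_normal
    p_regions_total = 1.0 - p_bg - p_chrM
    w = comp.base_w.copy()
    probs_n = p_regions_total * w / w.sum() if w.sum() > 0 else np.zeros_like(w)

    # tumor: planted multipliers, chrM probability pinned at d * p_chrM
    mult = np.ones(len(regions))
    mult[is_hyper] *= config.hyper_factor
    mult[comp.r_class == HISTONE_CLASS] *= config.histone_factor
    amp_mult = np.ones(len(regions))
    if config.amplicon is not None:
        achrom = config.amplicon[0]
        on_amp = comp.r_chrom == achrom
        amp_mult[on_amp] = _amp_factor(config, achrom, comp.r_center[on_amp])
    mult *= amp_mult
    d = config.chrM_depletion_factor
    p_chrM_t = d * p_chrM

    if config.amplicon is not None and not config.matched_background:
        achrom, as_, ae, _a = config.amplicon
        grid = 100
        edges = np.arange(as_, ae + grid, grid, dtype=np.float64)
        edges[-1] = ae
        centers = 0.5 * (edges[:-1] + edges[1:])
        amp_integral = float((_amp_factor(config, achrom, centers) * np.diff(edges)).sum())
        bg_scale = (comp.nuclear_len - (ae - as_) + amp_integral) / comp.nuclear_len
    else:
        bg_scale = 1.0
    w_bg_t = p_bg * bg_scale
    w_reg_t = probs_n * mult
    z = w_bg_t + w_reg_t.sum()
    scale_t = (1.0 - p_chrM_t) / z if z > 0 else 0.0
    p_bg_t = w_bg_t * scale_t
    probs_t = w_reg_t * scale_t

    if config.matched_background:
        n_bg = int(round(config.n_fragments * p_bg))
        bg_rng = np.random.default_rng([seed, 2])
        bgc, bgm = _sample_background(comp, n_bg, bg_rng, amplified=False)
        lens = np.clip(
            np.rint(bg_rng.normal(config.frag_len_mean, config.frag_len_sd, n_bg)),
            config.frag_len_min, config.frag_len_max,
        ).astype(np.int64)
        limits = np.array([genome.lengths[c] for c in bgc], dtype=np.int64)
        lens = np.minimum(lens, limits)
        bgs = np.clip(np.rint(bgm - lens / 2.0).astype(np.int64), 0, limits - lens)
        shared = (bgc, bgs, bgs + lens)
    else:
        shared = None

    out = []
    for condition, pbg, preg, pm in (
        ("normal", p_bg, probs_n, p_chrM),
        ("tumor", p_bg_t, probs_t, p_chrM_t),
    ):
        chroms, starts, ends = _emit(
            comp, pbg, preg, pm, config.n_fragments, rng,
            amplified=(condition == "tumor"), shared_bg=shared,
        )
        fs = FragmentSet(
            sample_id=f"{condition}_{seed}", chroms=chroms, starts=starts,
            ends=ends, condition=condition, pair_id=f"pair_{seed}", genome=genome,
        ).sorted()
        out.append(fs)
    normal_fs, tumor_fs = out

    truth = SimTruth(
        hyper_ccre_ids=sorted(hyper_ids),
        region_ids=[r.region_id for r in regions],
        weight_normal={r.region_id: float(v) for r, v in zip(regions, probs_n)},
        weight_tumor={r.region_id: float(v) for r, v in zip(regions, probs_t)},
        multiplier={r.region_id: float(v) for r, v in zip(regions, mult)},
        amplicon=config.amplicon,
        summits=config.summits,
        expected_chrM_fraction=(p_chrM, p_chrM_t),
        histone_factor=config.histone_factor,
    )
    return tumor_fs, normal_fs, truth
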