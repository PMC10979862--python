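"""End-to-end pipeline orchestration with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .amplicon import detect_summits, smooth_curve, tile_counts, write_summits_bed
from .cluster import build_matrix, reduce_and_embed, tfidf_normalize
from .coverage import make_track, region_signal, write_bedgraph, write_region_signal
from .fragments import (
    QC_MIN_FRAGMENTS,
    QC_MIN_TOTAL_BP,
    deduplicate,
    downsample_equalize,
    qc_filter,
    read_fragments,
)
from .genome import GenomeSpec
from .hyper_stats import histone_excess, mito_compare, pair_diff, rank_regions
from .peaks import call_peaks
from .regions import RegionSet, subtract_regions

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome_path: str
    regions_path: str
    pairs: list[dict]  # [{pair_id, tumor, normal}] paths to fragment BED files
    histone_regions_path: str | None = None
    mask_regions_path: str | None = None
    output_dir: str = "hypertx_run"
    dedup: bool = True
    equalize_seed: int = 0
    peak_mode: str = "relaxed"
    bin_size: int = 1000
    span: float = 0.2
    n_pcs: int = 50
    embed_seed: int = 0
    qc_min_fragments: int = QC_MIN_FRAGMENTS
    qc_min_total_bp: int = QC_MIN_TOTAL_BP

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate_paths(self) -> None:
        paths = [self.genome_path, self.regions_path]
        if self.histone_regions_path:
            paths.append(self.histone_regions_path)
        if self.mask_regions_path:
            paths.append(self.mask_regions_path)
        for pair in self.pairs:
            paths += [pair["tumor"], pair["normal"]]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute qc -> (dedup) -> equalize -> tracks -> signal -> statistics ->
    peaks -> amplicon -> cluster, writing outputs and a manifest under the
    configured output directory."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        genome = GenomeSpec.read_chrom_sizes(config.genome_path)
        regions = RegionSet.read_bed(config.regions_path)
        regions.validate(genome)
        if config.mask_regions_path:
            before = len(regions)
            regions = subtract_regions(regions, RegionSet.read_bed(config.mask_regions_path))
            logger.info("region mask removed %d of %d regions", before - len(regions), before)
        histones = (
            RegionSet.read_bed(config.histone_regions_path)
            if config.histone_regions_path
            else regions.select("histone")
        )

        stage = "load"
        pairs = []
        for spec in config.pairs:
            t = read_fragments(spec["tumor"], genome, condition="tumor",
                               pair_id=spec["pair_id"])
            n = read_fragments(spec["normal"], genome, condition="normal",
                               pair_id=spec["pair_id"])
            pairs.append((spec["pair_id"], t, n))

        stage = "qc"
        all_sets = [fs for _, t, n in pairs for fs in (t, n)]
        reports = qc_filter(all_sets, config.qc_min_fragments, config.qc_min_total_bp)
        with open(outdir / "qc.tsv", "w") as fh:
            fh.write("sample_id\tn_fragments\ttotal_fragment_bp\tpassed\n")
            for r in reports:
                fh.write(f"{r.sample_id}\t{r.n_fragments}\t{r.total_fragment_bp}\t{r.passed}\n")

        stage = "prepare"
        prepared = []
        for pair_id, t, n in pairs:
            if config.dedup:
                t, t_removed = deduplicate(t)
                n, n_removed = deduplicate(n)
                logger.info("%s: removed %d/%d duplicate fragments",
                            pair_id, t_removed, n_removed)
            t, n = downsample_equalize(t, n, seed=config.equalize_seed)
            prepared.append((pair_id, t, n))

        stage = "tracks"
        tracks = {}
        for pair_id, t, n in prepared:
            tt = make_track(t, genome)
            nt = make_track(n, genome)
            write_bedgraph(tt, outdir / f"{pair_id}.tumor.bedgraph")
            write_bedgraph(nt, outdir / f"{pair_id}.normal.bedgraph")
            tracks[pair_id] = (tt, nt)

        stage = "signal"
        pair_results = {}
        for pair_id, (tt, nt) in tracks.items():
            ts = region_signal(tt, regions, sample_id=f"{pair_id}_tumor")
            ns = region_signal(nt, regions, sample_id=f"{pair_id}_normal")
            write_region_signal(ts, regions, outdir / f"{pair_id}.tumor.signal.tsv")
            write_region_signal(ns, regions, outdir / f"{pair_id}.normal.signal.tsv")
            pr = pair_diff(ts, ns, regions, pair_id=pair_id)
            pr.write_tsv(outdir / f"{pair_id}.pairdiff.tsv")
            pair_results[pair_id] = pr

        stage = "histone"
        if len(histones):
            hs = histone_excess([(t, n) for _, t, n in prepared], histones, genome)
            with open(outdir / "histone_excess.json", "w") as fh:
                json.dump(
                    {
                        "pair_ids": hs.pair_ids,
                        "excess": list(map(float, hs.excess)),
                        "mean_excess": hs.mean_excess,
                        "sd_excess": hs.sd_excess,
                        "t_statistic": hs.t_statistic,
                        "p_value": hs.p_value,
                    },
                    fh, indent=1,
                )

        stage = "mito"
        mito = mito_compare([(t, n) for _, t, n in prepared], genome)
        mito.to_csv(outdir / "mito.tsv", sep="\t", index=False)

        stage = "peaks"
        for pair_id, (tt, nt) in tracks.items():
            call = call_peaks(tt, nt, mode=config.peak_mode)
            call.write_bed(outdir / f"{pair_id}.peaks.bed")
            call.write_meta(outdir / f"{pair_id}.peaks.json")
            logger.info("%s: %d peaks at threshold %.3g", pair_id, len(call.peaks),
                        call.threshold_auc)

        stage = "amplicon"
        for pair_id, (tt, nt) in tracks.items():
            ranked = rank_regions(pair_results[pair_id], mode="tumor_minus_normal")
            top = ranked[0]
            half = 500_000
            lo = max(0, int(top.center) - half)
            hi = min(genome.lengths[top.chrom], int(top.center) + half)
            tc = smooth_curve(
                tile_counts(tt, nt, (top.chrom, lo, hi), config.bin_size), config.span
            )
            tc.write_tsv(outdir / f"{pair_id}.tiles.tsv")
            summits = detect_summits(tc, anchors=regions.select("promoter"))
            write_summits_bed(summits, outdir / f"{pair_id}.summits.bed", config.bin_size)

        stage = "cluster"
        passed = {r.sample_id for r in reports if r.passed}
        usable = [fs for fs in all_sets if fs.sample_id in passed]
        if len(usable) >= 3:
            cm = build_matrix(usable, regions)
            emb = reduce_and_embed(tfidf_normalize(cm), n_pcs=config.n_pcs,
                                   seed=config.embed_seed)
            emb.write_tsv(outdir / "embedding.tsv")
        else:
            logger.info("fewer than 3 QC-passed samples; skipping embedding")

    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    stage = "manifest"
    outputs = sorted(p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
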