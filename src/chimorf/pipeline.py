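"""End-to-end orchestration: coverage segmentation -> breakpoints -> ORF
discovery -> chimera scoring -> candidate report.

Every stage threshold is a named config key carrying the study's constant
as its default (">1 kb" regions, ">60%" read support, ">100 codons",
">=95%" identity over ">=16 bp", 0-4 score with >=3 retention).  Outputs
are deterministic: rerunning an identical config on identical inputs
reproduces every file byte for byte.

:func:`analyze` is the in-memory engine; :func:`run_pipeline` adds file
I/O, validation, per-stage reports and a run manifest around it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .chimera import (SelfHomologySearcher, annotate_hit_feature,
                      build_candidate_report, find_self_homology,
                      nearest_gene, predict_tm_helices, score_candidate)
from .coverage import (find_no_coverage_regions, region_summary,
                       regions_to_bed, regions_to_frame)
from .orfs import exclude_known_genes, filter_candidate_orfs, orfs_to_frame, scan_orfs
from .rearrange import (breakpoints_to_frame, build_anchor_index,
                        call_breakpoints, chain_anchors, filter_by_read_support)
from .seqio import (CoverageTrack, GeneFeature, GenomeSequence,
                    read_annotation, read_coverage, read_fasta, write_tsv)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reference: str = ""
    annotation: str = ""
    annotation_format: str = "gff3"
    coverage: dict[str, str] = field(default_factory=dict)   # comparator -> path
    scaffolds: dict[str, str] = field(default_factory=dict)  # comparator -> path
    reads: dict[str, str] = field(default_factory=dict)      # comparator -> path
    circular: bool = True
    min_region_length: int = 1001
    max_region_depth: int = 1
    k: int = 21
    max_gap: int = 500
    min_support: float = 0.6
    min_codons: int = 101
    min_identity: int = 95
    min_chimera_len: int = 16
    proximity_dist: int = 1000
    flank: int = 5000
    tm_window: int = 19
    tm_threshold: float = 1.6
    known_gene_overlap: float = 0.5
    seed: int = 0
    outdir: str = "chimorf_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Coordinate-bound and length-consistency checks before running."""
    rep = ValidationReport()
    try:
        genome = read_fasta(config.reference, circular=config.circular)[0]
    except Exception as exc:  # noqa: BLE001 - report, don't crash
        rep.errors.append(f"reference: {exc}")
        return rep
    L = genome.length
    try:
        features = read_annotation(config.annotation, config.annotation_format)
    except Exception as exc:  # noqa: BLE001
        rep.errors.append(f"annotation: {exc}")
        features = []
    for f in features:
        if f.stop > L or f.start > L:
            rep.errors.append(f"feature {f.name} beyond genome end ({L} bp)")
        elif f.start > f.stop and not config.circular:
            rep.errors.append(f"feature {f.name} wraps origin of linear genome")
    for cid, path in config.coverage.items():
        try:
            read_coverage(path, L, cid)
        except Exception as exc:  # noqa: BLE001
            rep.errors.append(f"coverage {cid}: {exc}")
    if not features:
        rep.warnings.append("no annotated features")
    return rep


def analyze(genome: GenomeSequence, features: list[GeneFeature],
            tracks: dict[str, CoverageTrack] | None = None,
            scaffolds: dict[str, list[GenomeSequence]] | None = None,
            read_sets: dict[str, list[GenomeSequence]] | None = None,
            config: PipelineConfig | None = None) -> dict:
    """Run every analysis stage in memory and return the stage products."""
    cfg = config or PipelineConfig()
    L = genome.length

    regions = []
    for cid in sorted(tracks or {}):
        rs = find_no_coverage_regions((tracks or {})[cid],
                                      cfg.min_region_length,
                                      cfg.max_region_depth, cfg.circular)
        logger.info("regions[%s]: %d regions, %d bp", cid, len(rs),
                    region_summary(rs)["total_bp"])
        regions.extend(rs)

    breakpoints = []
    if scaffolds:
        index = build_anchor_index(genome, cfg.k)
        for cid in sorted(scaffolds):
            bps = []
            for scaf in scaffolds[cid]:
                chains = chain_anchors(scaf, index, cfg.max_gap)
                bps += call_breakpoints(chains, cid, L, cfg.max_gap,
                                        cfg.circular)
            if read_sets and cid in read_sets:
                bps = filter_by_read_support(bps, read_sets[cid], index,
                                             cfg.min_support, cfg.max_gap)
            logger.info("breakpoints[%s]: %d retained", cid, len(bps))
            breakpoints.extend(bps)

    all_orfs = scan_orfs(genome, cfg.min_codons)
    near_orfs = filter_candidate_orfs(all_orfs, regions, breakpoints, L,
                                      cfg.flank, cfg.circular)
    candidates = exclude_known_genes(near_orfs, features, L,
                                     cfg.known_gene_overlap, cfg.circular)
    logger.info("orfs: %d scanned, %d in vicinity, %d after known-gene "
                "exclusion", len(all_orfs), len(near_orfs), len(candidates))

    searcher = SelfHomologySearcher(genome)
    scores, hits_by_orf, tm_by_orf = [], {}, {}
    for orf in candidates:
        hits = find_self_homology(orf, genome, cfg.min_identity,
                                  cfg.min_chimera_len, searcher=searcher)
        for h in hits:
            annotate_hit_feature(h, features, L, all_orfs, cfg.circular)
        tm = predict_tm_helices(orf.peptide, cfg.tm_window, cfg.tm_threshold)
        near = nearest_gene(orf, features, L, cfg.proximity_dist, cfg.circular)
        scores.append(score_candidate(orf, hits, tm, near))
        hits_by_orf[orf.orf_id] = hits
        tm_by_orf[orf.orf_id] = tm
    table = build_candidate_report(scores, candidates, hits_by_orf, tm_by_orf)
    retained = [s for s in scores if s.retained]
    logger.info("candidates: %d scored, %d retained (score >= 3)",
                len(scores), len(retained))
    return {"regions": regions, "breakpoints": breakpoints,
            "all_orfs": all_orfs, "orfs": candidates, "scores": scores,
            "hits": hits_by_orf, "tm": tm_by_orf, "report": table,
            "retained": retained}


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based front end: read inputs, analyze, write stage artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(config)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.errors))

    genome = read_fasta(config.reference, circular=config.circular)[0]
    features = read_annotation(config.annotation, config.annotation_format)
    L = genome.length
    tracks = {cid: read_coverage(path, L, cid)
              for cid, path in config.coverage.items()}
    scaffolds = {cid: read_fasta(path, circular=False)
                 for cid, path in config.scaffolds.items()}
    read_sets = {cid: read_fasta(path, circular=False)
                 for cid, path in config.reads.items()}

    results = analyze(genome, features, tracks, scaffolds, read_sets, config)

    if tracks:
        import pandas as pd
        frames = []
        for cid in sorted(tracks):
            rs = find_no_coverage_regions(tracks[cid],
                                          config.min_region_length,
                                          config.max_region_depth,
                                          config.circular)
            frames.append(regions_to_frame(rs, cid))
        write_tsv(pd.concat(frames, ignore_index=True), outdir / "regions.tsv")
        (outdir / "regions.bed").write_text(
            regions_to_bed(results["regions"], genome.id, L))
    write_tsv(breakpoints_to_frame(results["breakpoints"]),
              outdir / "breakpoints.tsv")
    write_tsv(orfs_to_frame(results["orfs"]), outdir / "orfs.tsv")
    write_tsv(results["report"], outdir / "candidate_report.tsv")
    retained_ids = {s.orf_id for s in results["retained"]}
    peptides = {o.orf_id: o.peptide for o in results["orfs"]
                if o.orf_id in retained_ids}
    from .seqio import write_fasta
    write_fasta(peptides, outdir / "candidates.faa")

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "counts": {
            "no_coverage_regions": len(results["regions"]),
            "breakpoints": len(results["breakpoints"]),
            "orfs_scanned": len(results["all_orfs"]),
            "orfs_candidate": len(results["orfs"]),
            "retained": len(results["retained"]),
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
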