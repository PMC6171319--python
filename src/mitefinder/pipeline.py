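"""End-to-end pipeline: segmentation → TIR search → assembly → nesting →
clustering → flank filter → reports.

Segments are independent work units distributed over a process pool; hits
are re-sorted after collection, so the result is identical for any worker
count and any processing order.  A run writes its candidate table
(``candidates.tsv``) before clustering, which enables the split mode:
chromosomes can be discovered in separate runs and their candidate tables
merged and finalized later, with results identical to a joint run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import multiprocessing
import os
import time
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import family_output, flank_filter
from .family_clustering import Family, greedy_cluster
from .segmentation import make_segments
from .sequence_core import lcc_score, read_fasta
from .tir_search import (
    InvertedRepeatHit,
    MiteCandidate,
    assemble_candidate,
    find_inverted_repeats,
    resolve_nested,
)

logger = logging.getLogger("mitefinder")


@dataclass
class PipelineConfig:
    """All tunable parameters of a discovery run (defaults are the
    published operating point)."""

    genome: Optional[str] = None
    jobname: str = "job"
    out_root: str = "results"
    workers: int = 1
    mite_min_len: int = 50
    mite_max_len: int = 800
    tir_min_len: int = 10
    tir_min_identity: float = 0.8
    lcc_threshold: float = 1.0
    gc_min: float = 0.15
    gc_max: float = 0.95
    gc_on_element: bool = False
    tsd_min_len: int = 2
    tsd_max_len: int = 10
    require_tsd: bool = True
    boundary_trim_window: int = 60
    flank_len: int = 50
    flank_similarity_cutoff: float = 0.5
    cluster_identity: float = 0.80
    min_copy_number: int = 3
    best_match_clustering: bool = False
    include_shared_members: bool = False
    max_family_pairwise: int = 2000
    flank_subsample: int = 200
    seed_len: int = 8
    xdrop: int = 6
    band: int = 5
    max_kmer_hits: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.mite_min_len <= self.mite_max_len):
            raise ValueError("require 1 <= mite_min_len <= mite_max_len")
        if not (0.0 <= self.gc_min < self.gc_max <= 1.0):
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if not (0.0 < self.cluster_identity <= 1.0):
            raise ValueError("cluster_identity must be in (0, 1]")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if not (1 <= self.tsd_min_len <= self.tsd_max_len):
            raise ValueError("require 1 <= tsd_min_len <= tsd_max_len")


@dataclass
class PipelineResult:
    candidates: List[MiteCandidate]
    families: List[Family]
    surviving: List[Family]
    reported: List[Tuple[str, int, int, str]]
    summary: Dict
    paths: Dict[str, str]
    outdir: str


def _search_segment(args) -> List[InvertedRepeatHit]:
    segment, params = args
    return find_inverted_repeats(segment, **params)


def _search_params(cfg: PipelineConfig) -> Dict:
    return dict(
        tir_min_len=cfg.tir_min_len,
        min_identity=cfg.tir_min_identity,
        mite_max_len=cfg.mite_max_len,
        seed_len=cfg.seed_len,
        band=cfg.band,
        xdrop=cfg.xdrop,
        max_kmer_hits=cfg.max_kmer_hits,
    )


def discover_candidates(
    records: Iterable[Tuple[str, str]],
    cfg: PipelineConfig,
) -> Tuple[List[MiteCandidate], Dict]:
    """Run segmentation, TIR search, assembly and nesting resolution.

    ``records`` is an iterable of ``(chrom, sequence)`` pairs; one
    chromosome is held in memory at a time.  Returns the nesting-resolved
    candidate list (sorted by coordinates) and a stage-count dictionary.
    """
    stats: Dict = {
        "chromosomes": 0,
        "segments": 0,
        "segments_searched": 0,
        "raw_hits": 0,
        "rejections": Counter(),
        "candidates_pre_nesting": 0,
    }
    params = _search_params(cfg)
    pool = None
    if cfg.workers > 1:
        pool = multiprocessing.get_context("fork").Pool(cfg.workers)
    all_candidates: List[MiteCandidate] = []
    try:
        for chrom, seq in records:
            stats["chromosomes"] += 1
            if len(seq) < cfg.mite_min_len:
                logger.info(
                    "skipping %s: shorter than mite_min_len (%d < %d)",
                    chrom, len(seq), cfg.mite_min_len,
                )
                continue
            segments = make_segments(
                chrom, seq, cfg.mite_max_len, cfg.mite_min_len
            )
            stats["segments"] += len(segments)
            searchable = [
                s for s in segments if lcc_score(s.seq) >= cfg.lcc_threshold
            ]
            stats["segments_searched"] += len(searchable)
            tasks = [(s, params) for s in searchable]
            if pool is not None:
                hit_lists = pool.map(_search_segment, tasks, chunksize=4)
            else:
                hit_lists = [_search_segment(t) for t in tasks]
            hits = sorted(
                (h for hl in hit_lists for h in hl),
                key=lambda h: (
                    h.left_start, h.left_end, h.right_start, h.right_end
                ),
            )
            stats["raw_hits"] += len(hits)
            for hit in hits:
                cand, reason = assemble_candidate(
                    hit,
                    seq,
                    mite_min_len=cfg.mite_min_len,
                    mite_max_len=cfg.mite_max_len,
                    gc_min=cfg.gc_min,
                    gc_max=cfg.gc_max,
                    gc_on_element=cfg.gc_on_element,
                    lcc_threshold=cfg.lcc_threshold,
                    tsd_min_len=cfg.tsd_min_len,
                    tsd_max_len=cfg.tsd_max_len,
                    require_tsd=cfg.require_tsd,
                    boundary_trim_window=cfg.boundary_trim_window,
                    tir_min_len=cfg.tir_min_len,
                    flank_len=cfg.flank_len,
                )
                if cand is None:
                    stats["rejections"][reason] += 1
                else:
                    all_candidates.append(cand)
    finally:
        if pool is not None:
            pool.close()
            pool.join()
    stats["candidates_pre_nesting"] = len(all_candidates)
    resolved = resolve_nested(all_candidates)
    stats["candidates"] = len(resolved)
    stats["rejections"] = dict(stats["rejections"])
    return resolved, stats


def finalize_candidates(
    candidates: Sequence[MiteCandidate],
    cfg: PipelineConfig,
    outdir: str,
) -> Tuple[List[Family], List[Family], List[Tuple[str, int, int, str]], Dict[str, str]]:
    """Cluster, flank-filter and write all result files.

    Returns (families, surviving_families, reported_rows, paths).
    """
    os.makedirs(outdir, exist_ok=True)
    candidates_by_id = {c.candidate_id: c for c in candidates}
    families = greedy_cluster(
        candidates, cfg.cluster_identity, cfg.best_match_clustering
    )
    audit: List[flank_filter.FlankComparisonResult] = []
    for fam in families:
        flank_filter.count_distinct_individuals(
            fam,
            candidates_by_id,
            flank_len=cfg.flank_len,
            cutoff=cfg.flank_similarity_cutoff,
            max_members=cfg.max_family_pairwise,
            subsample=cfg.flank_subsample,
            seed=cfg.seed,
            audit=audit,
        )
        fam.representative_id = family_output.select_representative(fam)
        fam.common_tsd = family_output.most_common_tsd(fam, candidates_by_id)
    surviving = flank_filter.filter_families(families, cfg.min_copy_number)
    paths = family_output.write_outputs(
        surviving, candidates_by_id, outdir, cfg.include_shared_members
    )
    audit_path = os.path.join(outdir, "audit_flanks.tsv")
    with open(audit_path, "w") as fh:
        cols = [f"score{i + 1}" for i in range(12)]
        fh.write("candidate_a\tcandidate_b\t" + "\t".join(cols) + "\tverdict\n")
        for rec in audit:
            scores = list(rec.scores) + [float("nan")] * (12 - len(rec.scores))
            fh.write(
                "\t".join(
                    [rec.pair[0], rec.pair[1]]
                    + [f"{s:.4f}" for s in scores]
                    + [rec.verdict]
                )
                + "\n"
            )
    paths["audit_flanks"] = audit_path

    reported: List[Tuple[str, int, int, str]] = []
    for fam in surviving:
        for mid in family_output.reported_members(
            fam, cfg.include_shared_members
        ):
            c = candidates_by_id[mid]
            reported.append((c.chrom, c.start, c.end, f"family{fam.family_id}"))
    reported.sort()
    return families, surviving, reported, paths


# ---------------------------------------------------------------------------
# candidate table I/O (split mode)

_TSV_HEADER = (
    "chrom\tstart\tend\ttir_len\tleft_tir_start\tleft_tir_end\t"
    "right_tir_start\tright_tir_end\ttsd\tseq\tflank_left\tflank_right"
)


def write_candidates_tsv(
    candidates: Sequence[MiteCandidate], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for c in candidates:
            fh.write(
                "\t".join(
                    [
                        c.chrom, str(c.start), str(c.end), str(c.tir_len),
                        str(c.left_tir[0]), str(c.left_tir[1]),
                        str(c.right_tir[0]), str(c.right_tir[1]),
                        c.tsd or ".", c.seq, c.flank_left, c.flank_right,
                    ]
                )
                + "\n"
            )


def read_candidates_tsv(path: str) -> List[MiteCandidate]:
    out: List[MiteCandidate] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"{path}: not a candidate table")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                MiteCandidate(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    tir_len=int(f[3]),
                    left_tir=(int(f[4]), int(f[5])),
                    right_tir=(int(f[6]), int(f[7])),
                    tsd=None if f[8] == "." else f[8],
                    seq=f[9],
                    flank_left=f[10],
                    flank_right=f[11],
                )
            )
    return out


def merge_candidates(
    candidate_lists: Sequence[Sequence[MiteCandidate]],
) -> List[MiteCandidate]:
    """Concatenate candidate sets from independent runs.

    Duplicate candidate ids across shards indicate overlapping inputs and
    raise ``ValueError``.
    """
    merged: List[MiteCandidate] = []
    seen: Dict[str, str] = {}
    for li, cands in enumerate(candidate_lists):
        for c in cands:
            if c.candidate_id in seen:
                raise ValueError(
                    f"duplicate candidate id {c.candidate_id} across shards"
                )
            seen[c.candidate_id] = str(li)
            merged.append(c)
    merged.sort(key=lambda c: (c.chrom, c.start, c.end))
    return merged


# ---------------------------------------------------------------------------
# top-level runs


def _echo_config(cfg: PipelineConfig, outdir: str) -> None:
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, default=str)
        fh.write("\n")


def run_pipeline(
    cfg: PipelineConfig,
    records: Optional[Sequence[Tuple[str, str]]] = None,
) -> PipelineResult:
    """Execute every stage and write all outputs under out_root/jobname.

    ``records`` may supply the genome in memory; otherwise ``cfg.genome``
    is read as FASTA (validated before any stage runs).
    """
    outdir = os.path.join(cfg.out_root, cfg.jobname)
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "log.txt"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        t0 = time.time()
        if records is None:
            if cfg.genome is None:
                raise ValueError("no genome given (cfg.genome is None)")
            records = read_fasta(cfg.genome)
        candidates, stats = discover_candidates(records, cfg)
        if stats["chromosomes"] == 0:
            logger.warning("empty genome: no sequences found")
        logger.info(
            "discovery: segments=%d searched=%d raw_hits=%d candidates=%d "
            "rejections=%s elapsed=%.1fs",
            stats["segments"], stats["segments_searched"], stats["raw_hits"],
            stats["candidates"], stats["rejections"], time.time() - t0,
        )
        write_candidates_tsv(
            candidates, os.path.join(outdir, "candidates.tsv")
        )
        t1 = time.time()
        families, surviving, reported, paths = finalize_candidates(
            candidates, cfg, outdir
        )
        logger.info(
            "families: clusters=%d surviving=%d elements_reported=%d "
            "elapsed=%.1fs",
            len(families), len(surviving), len(reported), time.time() - t1,
        )
        _echo_config(cfg, outdir)
        summary = dict(stats)
        summary.update(
            families=len(families),
            surviving_families=len(surviving),
            elements_reported=len(reported),
        )
        paths["candidates_tsv"] = os.path.join(outdir, "candidates.tsv")
        return PipelineResult(
            candidates=list(candidates),
            families=families,
            surviving=surviving,
            reported=reported,
            summary=summary,
            paths=paths,
            outdir=outdir,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_merge(
    candidate_files: Sequence[str],
    cfg: PipelineConfig,
) -> PipelineResult:
    """Finalize merged candidate tables from independent discovery runs."""
    outdir = os.path.join(cfg.out_root, cfg.jobname)
    os.makedirs(outdir, exist_ok=True)
    merged = merge_candidates(
        [read_candidates_tsv(p) for p in candidate_files]
    )
    write_candidates_tsv(merged, os.path.join(outdir, "candidates.tsv"))
    families, surviving, reported, paths = finalize_candidates(
        merged, cfg, outdir
    )
    _echo_config(cfg, outdir)
    paths["candidates_tsv"] = os.path.join(outdir, "candidates.tsv")
    summary = dict(
        candidates=len(merged),
        families=len(families),
        surviving_families=len(surviving),
        elements_reported=len(reported),
    )
    return PipelineResult(
        candidates=merged,
        families=families,
        surviving=surviving,
        reported=reported,
        summary=summary,
        paths=paths,
        outdir=outdir,
    )
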