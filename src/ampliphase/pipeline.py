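"""Full-workflow orchestration.

The pipeline runs: sample-specific reference (short-read consensus against
the generic reference) -> re-mapping of both read sets -> optional coverage
subsampling -> HP detection -> long-read genotyping -> linkage-based
artefact-HP exclusion -> PSDM clustering and chimera-robust read pruning ->
iterative per-haplotype draft consensus -> short-read partitioning and
polishing -> homopolymer and problem reporting -> final FASTA. Every stage
writes its artifacts into the run directory and appends to a structured
log; the whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import align, cluster as _cluster, consensus as _consensus, linkage as _linkage
from . import polish as _polish, variants as _variants
from .seqio import (
    LONG,
    SHORT,
    ReadSet,
    ReferenceSeq,
    read_fasta,
    read_fastq,
    write_fasta,
    write_fastq,
)


@dataclass
class RunConfig:
    """Run configuration; defaults follow the workflow's standard
    parametrisation (MAF 0.2, 90%/30% read/HP coverage filters, two mapping
    iterations)."""

    reference: Optional[str] = None
    short_fastq: Optional[str] = None
    long_fastq: Optional[str] = None
    outdir: str = "ampliphase_run"
    expected_haplotypes: int = 2
    maf: float = 0.2
    min_read_cov: float = 0.9
    min_hp_cov: float = 0.3
    min_depth_hp: int = 20
    linkage_gap: float = 0.4
    retain_quantile: float = 0.25
    coef_floor: float = 0.2
    tie_ratio: float = 0.75
    min_depth_consensus: int = 3
    min_hp_len: int = 8
    target_coverage: Optional[int] = None
    n_iter: int = 2
    pwm_min_score: Optional[float] = None
    mapper: str = "builtin"  # "builtin" (edlib) or "sam:<path prefix>"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        )
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunResult:
    outdir: Path
    config: RunConfig
    haplotypes: dict[str, _polish.HaplotypeResult]
    final_sequences: list[ReferenceSeq]
    hps: Optional[_variants.HPSet] = None
    excluded_hps: list[int] = field(default_factory=list)
    clustering: Optional[_cluster.HaplotypeClustering] = None
    homopolymer_reports: dict[str, _polish.HomopolymerReport] = field(default_factory=dict)
    homozygous: bool = False
    log: list[dict] = field(default_factory=list)

    @property
    def problems(self) -> dict[str, list[_polish.Problem]]:
        return {h: r.problem_positions for h, r in self.haplotypes.items()}

    @property
    def blocking_problems(self) -> dict[str, list[_polish.Problem]]:
        return {
            h: r.blocking_problems
            for h, r in self.haplotypes.items()
            if r.blocking_problems
        }


def _log(result_log: list[dict], outdir: Path, stage: str, **info) -> None:
    entry = {"stage": stage, **info}
    result_log.append(entry)
    with open(outdir / "run_log.json", "wt") as out:
        json.dump(result_log, out, indent=1, default=str)


def _load_alignments(cfg: RunConfig, reads: ReadSet, ref: ReferenceSeq, tag: str):
    """Mapper dispatch: built-in edlib mapping, or SAM import from an
    external mapper (``mapper: sam:<dir>`` with <dir>/<tag>.sam files)."""
    if cfg.mapper.startswith("sam:"):
        from .seqio import read_sam

        sam_path = Path(cfg.mapper[4:]) / f"{tag}.sam"
        return read_sam(sam_path, ref)
    return align.map_reads(reads, ref)


def run_pipeline(
    cfg: RunConfig,
    reference: Optional[ReferenceSeq] = None,
    short_reads: Optional[ReadSet] = None,
    long_reads: Optional[ReadSet] = None,
) -> RunResult:
    """Execute the full workflow; inputs may be given in memory or read from
    the paths in ``cfg``. Long-read-only mode is used when no short reads
    are supplied (lower-confidence: repeats and homopolymers may not be
    resolvable at reference quality)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    if reference is None:
        if cfg.reference is None:
            raise ValueError("no reference sequence given")
        reference = read_fasta(cfg.reference)[0]
    if long_reads is None:
        if cfg.long_fastq is None:
            raise ValueError("no long reads given")
        long_reads = read_fastq(cfg.long_fastq, platform=LONG)
    if short_reads is None and cfg.short_fastq is not None:
        short_reads = read_fastq(cfg.short_fastq, platform=SHORT)
    long_only = short_reads is None or len(short_reads) == 0
    if len(long_reads) == 0:
        raise ValueError("stage initial_mapping: empty long-read set")

    # --- stage 1: sample-specific reference -------------------------------
    base_reads = long_reads if long_only else short_reads
    initial = _load_alignments(cfg, base_reads, reference, "initial")
    if cfg.target_coverage is not None:
        before = len(initial)
        initial = align.subsample_by_coverage(initial, cfg.target_coverage, cfg.seed)
        _log(log, outdir, "subsample", kept=len(initial), of=before,
             target_coverage=cfg.target_coverage)
    pile0 = align.build_pileup(initial, len(reference.bases))
    sample_ref = _consensus.call_consensus(
        pile0, tie_ratio=cfg.tie_ratio, min_depth=cfg.min_depth_consensus,
        emit_ambiguity=False,
    ).as_reference("sample_ref")
    write_fasta([sample_ref], outdir / "sample_ref.fasta")
    _log(log, outdir, "sample_reference", length=len(sample_ref.bases),
         n_reads=len(base_reads), long_only=long_only)

    # --- stage 2: re-mapping ----------------------------------------------
    long_alns = _load_alignments(cfg, long_reads, sample_ref, "long_remap")
    if cfg.pwm_min_score is not None:
        pwm = _variants.pwm_from_pileup(
            align.build_pileup(long_alns, len(sample_ref.bases))
        )
        before = len(long_alns)
        long_alns = _variants.filter_longreads_by_pwm(long_alns, pwm, cfg.pwm_min_score)
        _log(log, outdir, "pwm_filter", kept=len(long_alns), of=before)
    if long_only:
        short_alns = []
        hp_pile = align.build_pileup(long_alns, len(sample_ref.bases))
    else:
        short_alns = _load_alignments(cfg, short_reads, sample_ref, "short_remap")
        hp_pile = align.build_pileup(short_alns, len(sample_ref.bases))
    _log(log, outdir, "remap", n_long=len(long_alns), n_short=len(short_alns))

    # --- stage 3: HP detection --------------------------------------------
    hps = _variants.detect_hps(hp_pile, maf=cfg.maf, min_depth=cfg.min_depth_hp)
    if len(hps):
        hps.to_bed(outdir / "hps.bed", name=sample_ref.id)
        hps.to_tsv(outdir / "hps.tsv")
    _log(log, outdir, "hp_detection", n_hps=len(hps), maf=cfg.maf)

    if len(hps) == 0:
        return _homozygous_fallback(
            cfg, outdir, log, sample_ref, long_reads, short_reads, long_only
        )

    # --- stage 4: long-read genotyping + 90%/30% filters ------------------
    gmatrix = _variants.genotype_reads(
        long_alns, hps, reference_bases=sample_ref.bases
    )
    gmatrix = _variants.filter_genotype_matrix(
        gmatrix, min_read_cov=cfg.min_read_cov, min_hp_cov=cfg.min_hp_cov
    )
    _log(log, outdir, "genotype_filter", n_reads=gmatrix.n_reads, n_hps=gmatrix.n_hps)

    # --- stage 5: linkage exclusion ---------------------------------------
    excluded: list[int] = []
    if gmatrix.n_hps >= 2:
        lm = _linkage.linkage_matrix(gmatrix)
        lm.to_tsv(outdir / "linkage.tsv")
        kept, excluded = _linkage.exclude_artefact_hps(lm, cfg.linkage_gap)
        if excluded:
            keep_mask = np.array([p in set(kept) for p in gmatrix.positions])
            gmatrix = gmatrix.select(
                np.ones(gmatrix.n_reads, dtype=bool), keep_mask
            )
    _log(log, outdir, "linkage_exclusion", excluded=excluded, n_hps=gmatrix.n_hps)

    # --- stage 6: clustering and pruning ----------------------------------
    psdm = _cluster.build_psdm(gmatrix)
    clustering = _cluster.cluster_reads(psdm, expected_n=cfg.expected_haplotypes)
    scores = _cluster.membership_coefficients(gmatrix, clustering)
    scores.to_frame().to_csv(outdir / "clustering.tsv", sep="\t")
    retained = _cluster.prune_reads(
        scores,
        retain_quantile=cfg.retain_quantile,
        coef_floor=cfg.coef_floor,
        min_cluster_size=_cluster.default_min_cluster_size(gmatrix.n_reads),
    )
    hap_names = {
        c: f"hap_{chr(ord('A') + i)}"
        for i, c in enumerate(scores.cluster_ids)
    }
    long_by_hap: dict[str, ReadSet] = {}
    long_aln_by_hap: dict[str, list] = {}
    aln_by_id = {a.read.id: a for a in long_alns}
    for c, ids in retained.items():
        name = hap_names[c]
        long_by_hap[name] = long_reads.subset(ids)
        long_aln_by_hap[name] = [aln_by_id[i] for i in ids]
        write_fastq(long_by_hap[name], outdir / f"{name}.fastq")
    _log(log, outdir, "clustering",
         clusters={hap_names[c]: len(ids) for c, ids in retained.items()},
         pruned=len(scores.read_ids) - sum(len(v) for v in retained.values()))

    # --- stage 7: iterative drafts ----------------------------------------
    drafts: dict[str, ReferenceSeq] = {}
    for name, alns in long_aln_by_hap.items():
        seed_pile = align.build_pileup(alns, len(sample_ref.bases))
        seed = _consensus.call_consensus(
            seed_pile, tie_ratio=cfg.tie_ratio,
            min_depth=min(cfg.min_depth_consensus, max(1, len(alns) // 3)),
            emit_ambiguity=False,
        ).as_reference(name)
        res = _consensus.map_iter(
            long_by_hap[name], seed, n_iter=cfg.n_iter,
            tie_ratio=cfg.tie_ratio, min_depth=cfg.min_depth_consensus,
            artifact_writer=lambda k, ref, _n=name: write_fasta(
                [ref], outdir / f"{_n}.mapIter{k}.fasta"
            ),
        )
        drafts[name] = ReferenceSeq(name, res.reference.bases)
        _log(log, outdir, "map_iter", haplotype=name,
             changed=res.changed_per_iteration)

    # --- stage 8: short-read partitioning and polishing -------------------
    results: dict[str, _polish.HaplotypeResult] = {}
    hp_reports: dict[str, _polish.HomopolymerReport] = {}
    # partition against the pruned clusters: chimeras and noise reads no
    # longer shape the per-haplotype HP genotypes
    cluster_genotypes = _cluster.cluster_pwms(gmatrix, clustering, members=retained)
    kept_hps = _variants.HPSet(
        positions=list(gmatrix.positions),
        allele_freqs=hps.allele_freqs[
            [hps.positions.index(p) for p in gmatrix.positions]
        ],
        maf_threshold=hps.maf_threshold,
    )
    if long_only:
        partitions = {c: [] for c in scores.cluster_ids}
        unique_ids: dict[int, set] = {c: set() for c in scores.cluster_ids}
    else:
        part = _polish.partition_short_reads(short_alns, kept_hps, cluster_genotypes)
        partitions = part.by_cluster
        unique_ids = part.unique_by_cluster
        _log(log, outdir, "short_partition",
             sizes={hap_names[c]: len(v) for c, v in partitions.items()},
             unique={hap_names[c]: len(v) for c, v in unique_ids.items()},
             ambiguous=len(part.ambiguous_reads), hp_free=part.hp_free_count)
    active = [c for c in scores.cluster_ids if hap_names[c] in drafts]
    short_by_hap = {
        hap_names[c]: ReadSet([a.read for a in partitions.get(c, [])], SHORT)
        for c in active
    }
    unique_by_hap = {hap_names[c]: unique_ids.get(c, set()) for c in active}
    hap_long_alns = {
        hap_names[c]: align.map_reads(long_by_hap[hap_names[c]], drafts[hap_names[c]])
        for c in active
    }
    if len(active) == 2 and not long_only:
        polished = _polish.polish_haplotype_pair(
            short_by_hap, drafts, unique_by_hap, hap_long_alns,
            tie_ratio=cfg.tie_ratio, min_depth=cfg.min_depth_consensus,
            long_read_counts={n: len(long_by_hap[n]) for n in drafts},
        )
    else:
        polished = {}
        for c in active:
            name = hap_names[c]
            polished[name] = _polish.polish_haplotype(
                short_by_hap[name], drafts[name],
                tie_ratio=cfg.tie_ratio, min_depth=cfg.min_depth_consensus,
                long_read_count=len(long_by_hap.get(name, [])),
                long_alignments=hap_long_alns[name],
                unique_ids=unique_by_hap[name],
            )
    for c in active:
        name = hap_names[c]
        hap_result = polished[name]
        hap_result.haplotype_id = name
        short_set = short_by_hap[name]
        # homopolymer mode check on the final sequence
        final_ref = ReferenceSeq(name, hap_result.final_sequence)
        if hap_result.final_alignments and hap_result.final_sequence != hap_result.draft_sequence:
            check_alns = align.map_reads(short_set, final_ref)
        else:
            check_alns = hap_result.final_alignments or long_aln_by_hap[name]
        report = _polish.homopolymer_check(
            check_alns, final_ref, cfg.min_hp_len,
            prefer_ids=unique_by_hap[name],
        )
        hap_result.problem_positions.extend(report.problems())
        hp_reports[name] = report
        results[name] = hap_result
        if not long_only:
            write_fastq(short_set, outdir / f"{name}.short.fastq")
    return _finalize(cfg, outdir, log, results, hp_reports, hps, excluded,
                     clustering, homozygous=False)


def _homozygous_fallback(cfg, outdir, log, sample_ref, long_reads, short_reads,
                         long_only) -> RunResult:
    """No heterozygous positions: emit a single consensus with a notice."""
    _log(log, outdir, "homozygous_fallback",
         notice="no heterozygous positions above the MAF threshold; "
                "emitting a single consensus")
    res = _consensus.map_iter(
        long_reads, ReferenceSeq("hap_A", sample_ref.bases), n_iter=cfg.n_iter,
        tie_ratio=cfg.tie_ratio, min_depth=cfg.min_depth_consensus,
    )
    draft = ReferenceSeq("hap_A", res.reference.bases)
    short_set = short_reads if not long_only else ReadSet([], SHORT)
    hap_result = _polish.polish_haplotype(
        short_set, draft, tie_ratio=cfg.tie_ratio,
        min_depth=cfg.min_depth_consensus, long_read_count=len(long_reads),
    )
    hap_result.haplotype_id = "hap_A"
    final_ref = ReferenceSeq("hap_A", hap_result.final_sequence)
    check_alns = hap_result.final_alignments
    if check_alns and hap_result.final_sequence != hap_result.draft_sequence:
        check_alns = align.map_reads(short_set, final_ref)
    report = _polish.homopolymer_check(
        check_alns if check_alns else [], final_ref, cfg.min_hp_len
    )
    hap_result.problem_positions.extend(report.problems())
    return _finalize(cfg, outdir, log, {"hap_A": hap_result},
                     {"hap_A": report}, None, [], None, homozygous=True)


def _finalize(cfg, outdir, log, results, hp_reports, hps, excluded, clustering,
              homozygous) -> RunResult:
    finals = [
        ReferenceSeq(name, r.final_sequence) for name, r in sorted(results.items())
    ]
    write_fasta(finals, outdir / "final.fasta")
    if len(finals) > 1:
        rows = _polish.haplotype_alignment(finals)
        with open(outdir / "haplotypes.aln.fasta", "wt") as out:
            for row in rows:
                out.write(f">{row.id}\n{row.bases}\n")
    problems_payload = {
        name: [p.to_dict() for p in r.problem_positions]
        for name, r in sorted(results.items())
    }
    with open(outdir / "problems.json", "wt") as out:
        json.dump(problems_payload, out, indent=1, default=str)
    with open(outdir / "problems.bed", "wt") as out:
        for name, r in sorted(results.items()):
            for p in r.problem_positions:
                out.write(f"{name}\t{p.position}\t{p.position + 1}\t{p.kind}\n")
    with open(outdir / "homopolymers.json", "wt") as out:
        json.dump(
            {
                name: [r.to_dict() for r in rep.runs]
                for name, rep in hp_reports.items()
            },
            out, indent=1,
        )
    with open(outdir / "config.json", "wt") as out:
        json.dump({**cfg.to_dict(), "config_hash": cfg.config_hash()}, out, indent=1)
    result = RunResult(
        outdir=outdir, config=cfg, haplotypes=results, final_sequences=finals,
        hps=hps, excluded_hps=excluded, clustering=clustering,
        homopolymer_reports=hp_reports, homozygous=homozygous, log=log,
    )
    _log(log, outdir, "done",
         haplotypes={n: len(r.final_sequence) for n, r in results.items()},
         blocking_problems={
             n: len(v) for n, v in result.blocking_problems.items()
         })
    return result


def checkout(run_dir, out: Optional[str] = None, force: bool = False) -> Path:
    """Check a completed run out into a final FASTA.

    Refused when blocking problems remain, unless ``force``; the output
    carries a provenance header (run directory and config hash)."""
    run_dir = Path(run_dir)
    with open(run_dir / "problems.json") as fh:
        problems = json.load(fh)
    with open(run_dir / "config.json") as fh:
        config = json.load(fh)
    blocking = {
        hap: [
            p for p in plist
            if p["kind"] != "deletion_signal" or p.get("dropped", False)
        ]
        for hap, plist in problems.items()
    }
    blocking = {h: v for h, v in blocking.items() if v}
    if blocking and not force:
        lines = [
            f"  {h}: {len(v)} unresolved problem(s) at "
            + ", ".join(str(p['position']) for p in v[:10])
            for h, v in blocking.items()
        ]
        raise ValueError(
            "checkout refused; unresolved problems remain "
            "(use force to override):\n" + "\n".join(lines)
        )
    finals = read_fasta(run_dir / "final.fasta")
    out_path = Path(out) if out else run_dir / "checkout.fasta"
    with open(out_path, "wt") as fh:
        for s in finals:
            fh.write(
                f">{s.id} run={run_dir.name} config={config.get('config_hash')}\n"
            )
            for i in range(0, len(s.bases), 60):
                fh.write(s.bases[i : i + 60] + "\n")
    return out_path
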