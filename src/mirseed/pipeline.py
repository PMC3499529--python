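"""Stage orchestration: YAML config, artifacts on disk, JSON manifests.

Each stage reads the previous stage's artifacts, writes versioned outputs
plus a manifest (input hashes, parameters, counts), and is idempotent:
rerunning with identical inputs and config reproduces byte-identical
outputs.  Reports round exactly as the printed tables do (integer
percentages for read accounting, two decimals elsewhere) so diffs between
runs are textual.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import annotation, conserved, discovery, preprocess, synthetic, targets
from .sequtils import to_dna

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "annotate", "conserved", "discover",
          "targets", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "out"
    seed: int = 1
    adapter3p: str = synthetic.DEFAULT_ADAPTER_3P
    # preprocessing / annotation thresholds
    min_q: int = 13
    len_lo: int = 18
    len_hi: int = 25
    min_overlap: int = 7
    # discovery thresholds
    max_block_span: int = 30
    flank: int = 20
    max_pair_distance: int = 700
    singleton_flank: int = 120
    min_paired_frac: float = 0.6
    # target prediction
    expectation: float = 4.0
    min_unigene_len: int = 600
    # synthetic scenario
    n_conserved: int = 10
    n_novel: int = 10
    n_decoys: int = 200
    background_reads: int = 600
    low_quality_fraction: float = 0.1
    # optional external inputs (simulate fills these when absent)
    fastq: str | None = None
    contigs: str | None = None
    mature_ref: str | None = None
    refs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.len_lo >= self.len_hi:
            raise ValueError("length window must be ordered")
        for name in ("min_q", "max_block_span", "flank", "min_paired_frac",
                     "expectation", "min_unigene_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat = {}
        for k, v in data.items():
            if isinstance(v, dict) and k in ("thresholds", "scenario", "paths"):
                flat.update(v)
            else:
                flat[k] = v
        return cls(**flat)

    @property
    def out(self) -> Path:
        return Path(self.outdir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(cfg: PipelineConfig, stage: str, inputs: list[Path],
                    outputs: list[Path], counts: dict) -> None:
    mdir = cfg.out / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "params": {k: v for k, v in asdict(cfg).items()
                   if not isinstance(v, dict)},
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p): _sha256(p) for p in outputs},
        "counts": counts,
    }
    (mdir / f"{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path}; run the '{producer}' stage first")
    return path


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> None:
    sim = cfg.out / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    truth = synthetic.make_scenario(cfg.seed, n_conserved=cfg.n_conserved,
                                    n_novel=cfg.n_novel, n_decoys=cfg.n_decoys)
    records, ledger = synthetic.simulate_library(
        truth, background_reads=cfg.background_reads, adapter3p=cfg.adapter3p,
        rng_seed=cfg.seed + 1, low_quality_fraction=cfg.low_quality_fraction)
    synthetic.write_fasta(truth.contigs, sim / "contigs.fasta")
    synthetic.write_fastq(records, sim / "reads.fastq")
    synthetic.write_fasta([(n, s) for n, _, s in truth.mature_reference],
                          sim / "mature_ref.fasta")
    for cat, seqs in truth.references.items():
        synthetic.write_fasta(seqs, sim / f"ref_{cat}.fasta")
    synthetic.write_ledger(ledger, sim / "truth_ledger.tsv")
    outputs = sorted(sim.glob("*"))
    _write_manifest(cfg, "simulate", [], outputs, {
        "planted": len(truth.planted), "decoys": len(truth.decoy_contigs),
        "reads": len(records)})


def _input_paths(cfg: PipelineConfig) -> dict[str, Path]:
    sim = cfg.out / "sim"
    return {
        "fastq": Path(cfg.fastq) if cfg.fastq else sim / "reads.fastq",
        "contigs": Path(cfg.contigs) if cfg.contigs else sim / "contigs.fasta",
        "mature_ref": (Path(cfg.mature_ref) if cfg.mature_ref
                       else sim / "mature_ref.fasta"),
    }


def _ref_sets(cfg: PipelineConfig) -> list[annotation.ReferenceSet]:
    sets = []
    for cat in annotation.CATEGORY_PRECEDENCE[1:]:
        path = (Path(cfg.refs[cat]) if cat in cfg.refs
                else cfg.out / "sim" / f"ref_{cat}.fasta")
        if path.exists():
            seqs = tuple(_read_fasta(path).items())
            sets.append(annotation.ReferenceSet(category=cat, sequences=seqs))
    if not sets:
        raise PipelineError("no reference sets found; run 'simulate' or set paths")
    return sets


def stage_preprocess(cfg: PipelineConfig) -> None:
    fastq = _need(_input_paths(cfg)["fastq"], "simulate")
    pre = cfg.out / "preprocess"
    pre.mkdir(parents=True, exist_ok=True)
    lib, summary = preprocess.preprocess_fastq(
        fastq, adapter3p=cfg.adapter3p, min_q=cfg.min_q, lo=cfg.len_lo,
        hi=cfg.len_hi, min_overlap=cfg.min_overlap)
    preprocess.write_collapsed_fasta(lib, pre / "collapsed.fasta")
    preprocess.summary_table(summary, cfg.len_lo, cfg.len_hi).to_csv(
        pre / "summary.tsv", sep="\t", index=False)
    preprocess.length_distribution_table(summary).to_csv(
        pre / "length_distribution.tsv", sep="\t", index=False)
    _write_manifest(cfg, "preprocess", [fastq], sorted(pre.glob("*")), {
        "total_inserts": summary.total_reads, "in_window": summary.in_window,
        "unique": len(lib)})


def _load_library(cfg: PipelineConfig) -> list[preprocess.CollapsedRead]:
    path = _need(cfg.out / "preprocess" / "collapsed.fasta", "preprocess")
    return preprocess.read_collapsed_fasta(path)


def stage_conserved(cfg: PipelineConfig) -> None:
    lib = _load_library(cfg)
    ref = conserved.MatureReference.from_fasta(
        _need(_input_paths(cfg)["mature_ref"], "simulate"))
    matches = conserved.match_conserved(lib, ref)
    profiles = conserved.family_profiles(matches, lib)
    out = cfg.out / "conserved"
    out.mkdir(parents=True, exist_ok=True)
    conserved.profiles_table(profiles).to_csv(out / "families.tsv", sep="\t",
                                              index=False)
    conserved.matches_table(matches, lib).to_csv(out / "matches.tsv", sep="\t",
                                                 index=False)
    _write_manifest(cfg, "conserved",
                    [cfg.out / "preprocess" / "collapsed.fasta"],
                    sorted(out.glob("*")),
                    {"matched_reads": len(matches), "families": len(profiles)})


def stage_annotate(cfg: PipelineConfig) -> None:
    lib = _load_library(cfg)
    refs = _ref_sets(cfg)
    index = annotation.build_match_index(refs, cfg.len_lo, cfg.len_hi)
    ref = conserved.MatureReference.from_fasta(
        _need(_input_paths(cfg)["mature_ref"], "simulate"))
    hits = conserved.mirna_hit_seqs(conserved.match_conserved(lib, ref))
    report = annotation.classify_library(lib, index, hits)
    out = cfg.out / "annotate"
    out.mkdir(parents=True, exist_ok=True)
    report.to_table().to_csv(out / "categories.tsv", sep="\t", index=False)
    _write_manifest(cfg, "annotate",
                    [cfg.out / "preprocess" / "collapsed.fasta"],
                    sorted(out.glob("*")),
                    {"denominator": report.denominator, **report.counts})


def stage_discover(cfg: PipelineConfig) -> None:
    lib = _load_library(cfg)
    contigs = _read_fasta(_need(_input_paths(cfg)["contigs"], "simulate"))
    ref = conserved.MatureReference.from_fasta(
        _need(_input_paths(cfg)["mature_ref"], "simulate"))
    dcfg = discovery.DiscoveryConfig(
        max_block_span=cfg.max_block_span, flank=cfg.flank,
        max_pair_distance=cfg.max_pair_distance,
        singleton_flank=cfg.singleton_flank,
        min_paired_frac=cfg.min_paired_frac)
    cands = discovery.discover_precursors(lib, contigs, ref, dcfg)
    out = cfg.out / "discover"
    out.mkdir(parents=True, exist_ok=True)
    discovery.candidates_table(cands).to_csv(out / "precursors.tsv", sep="\t",
                                             index=False)
    synthetic.write_fasta([(c.locus_name, c.seq) for c in cands],
                          out / "precursors.fasta")
    (out / "structures.txt").write_text(
        discovery.candidates_dotbracket(cands) if cands else "")
    (out / "loci.gff3").write_text(discovery.candidates_gff3(cands))
    _write_manifest(cfg, "discover",
                    [cfg.out / "preprocess" / "collapsed.fasta"],
                    sorted(out.glob("*")), {
                        "candidates": len(cands),
                        "conserved": sum(c.classification == "conserved"
                                         for c in cands),
                        "novel": sum(c.classification == "novel"
                                     for c in cands)})


def stage_targets(cfg: PipelineConfig) -> None:
    prec = _need(cfg.out / "discover" / "precursors.tsv", "discover")
    contigs = _read_fasta(_need(_input_paths(cfg)["contigs"], "simulate"))
    unigenes = targets.filter_unigenes(list(contigs.items()),
                                       min_len=cfg.min_unigene_len)
    df = pd.read_csv(prec, sep="\t")
    hits: list[targets.TargetHit] = []
    for _, row in df.iterrows():
        arms = [(row["seq_5p"], row["count_5p"]), (row["seq_3p"], row["count_3p"])]
        arms = [(s, int(c)) for s, c in arms if s != "ND"]
        if not arms:
            continue
        mature = max(arms, key=lambda sc: sc[1])[0]
        hits.extend(targets.find_targets(row["name"], mature, unigenes,
                                         expectation=cfg.expectation))
    out = cfg.out / "targets"
    out.mkdir(parents=True, exist_ok=True)
    targets.targets_table(hits).to_csv(out / "targets.tsv", sep="\t",
                                       index=False)
    _write_manifest(cfg, "targets", [prec], sorted(out.glob("*")),
                    {"hits": len(hits), "unigenes": len(unigenes)})


def stage_report(cfg: PipelineConfig) -> None:
    mdir = cfg.out / "manifests"
    counts = {}
    for stage in STAGES[:-1]:
        p = mdir / f"{stage}.json"
        if p.exists():
            counts[stage] = json.loads(p.read_text())["counts"]
    _need(mdir / "preprocess.json", "preprocess")
    out = cfg.out / "report"
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_summary.json").write_text(
        json.dumps(counts, indent=2, sort_keys=True) + "\n")
    _write_manifest(cfg, "report", [], [out / "run_summary.json"], {})


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "annotate": stage_annotate,
    "conserved": stage_conserved,
    "discover": stage_discover,
    "targets": stage_targets,
    "report": stage_report,
}


def run_stage(stage: str, cfg: PipelineConfig) -> None:
    if stage not in _STAGE_FN:
        raise PipelineError(f"unknown stage {stage!r}; one of {STAGES}")
    logger.info("running stage %s (outdir=%s, seed=%d)", stage, cfg.outdir,
                cfg.seed)
    _STAGE_FN[stage](cfg)


def run_all(cfg: PipelineConfig) -> None:
    for stage in STAGES:
        run_stage(stage, cfg)
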