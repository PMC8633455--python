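"""End-to-end orchestration: QC -> annotation -> discovery -> DE -> targets ->
integration -> enrichment, with a run manifest and a ground-truth evaluator.

The pipeline consumes a bundle directory (as written by
:func:`mirwood.simulate.simulate_dataset`, or assembled by hand in the same
layout) and writes per-stage tables plus a manifest that records every count
a rerun must reproduce.  Reruns with identical inputs and configuration are
bit-identical in all recorded counts.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import annotate, discovery, enrich, expression, integrate, qc, targets
from ._seq import transcribe
from .simulate import GroundTruth

log = logging.getLogger(__name__)

__version__ = "0.1.0"

COMPARISONS = (("PS", "TS"), ("PS", "SS"), ("TS", "SS"))


@dataclass
class PipelineConfig:
    adapter_3p: str = "AGATCGGAAGAGCACACGTCT"
    adapter_5p: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    focal_prefix: str = "ptc"
    stages: tuple[str, ...] = ("PS", "TS", "SS")
    de: expression.DEOptions = field(default_factory=expression.DEOptions)
    rules: targets.RuleConfig = field(default_factory=targets.RuleConfig)
    discovery: discovery.DiscoveryConfig = field(default_factory=discovery.DiscoveryConfig)
    correlation: integrate.CorrelationConfig = field(
        default_factory=integrate.CorrelationConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kw = dict(d)
        for key, sub in (("de", expression.DEOptions),
                         ("rules", targets.RuleConfig),
                         ("discovery", discovery.DiscoveryConfig),
                         ("correlation", integrate.CorrelationConfig)):
            if key in kw and isinstance(kw[key], dict):
                extra = set(kw[key]) - set(sub.__dataclass_fields__)
                if extra:
                    raise ValueError(f"unknown keys under {key!r}: {sorted(extra)}")
                kw[key] = sub(**kw[key])
        if "stages" in kw:
            kw["stages"] = tuple(kw["stages"])
        return cls(**kw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_checksums: dict[str, str]
    counts: dict
    started: float = 0.0
    finished: float = 0.0

    def signature(self) -> str:
        """Deterministic digest of everything a rerun must reproduce."""
        blob = json.dumps({"version": self.version, "config": self.config_hash,
                           "inputs": self.input_checksums, "counts": self.counts},
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


@dataclass
class PipelineResult:
    qc_reports: dict
    tags: list
    annotations: list
    known_records: list
    novel_records: list
    candidates: list
    mirna_matrix: expression.ExpressionMatrix
    mirna_tpm: pd.DataFrame
    de_mirnas: dict[str, pd.DataFrame]
    gene_matrix: expression.ExpressionMatrix
    gene_fpkm: pd.DataFrame
    degs: dict[str, pd.DataFrame]
    hits: list
    pair_records: dict[str, pd.DataFrame]
    pair_summaries: dict[str, dict]
    networks: dict[str, dict]
    enrichments: dict[str, pd.DataFrame]
    manifest: RunManifest


def read_fastq_counted(path: str | Path) -> dict[tuple[str, str], int]:
    """Collapse a (gzipped) FASTQ into (seq, qual) -> count."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4:
        raise ValueError(f"truncated FASTQ: {path}")
    counts: Counter = Counter(zip(lines[1::4], lines[3::4]))
    return dict(counts)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(bundle_dir: str | Path, outdir: str | Path,
                 config: PipelineConfig | None = None) -> PipelineResult:
    cfg = config or PipelineConfig()
    bundle = Path(bundle_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    counts: dict = {}

    fastqs = sorted(bundle.glob("srna_*.fastq.gz"))
    if not fastqs:
        raise FileNotFoundError(f"no srna_*.fastq.gz libraries under {bundle}")
    checksums = {p.name: _sha256(p) for p in fastqs}
    for name in ("genome.fa", "genes.gff3", "mature.fa", "mrna_counts.tsv"):
        p = bundle / name
        if p.exists():
            checksums[name] = _sha256(p)

    # --- stage 1: QC -------------------------------------------------------
    qc_reports = {}
    clean_per_lib: dict[str, dict[str, int]] = {}
    for path in fastqs:
        lib = path.name[len("srna_"):-len(".fastq.gz")]
        records = read_fastq_counted(path)
        clean, report = qc.clean_srna_counted(records, cfg.adapter_3p, cfg.adapter_5p)
        if not report.conserved():
            raise RuntimeError(f"QC accounting violated for library {lib}")
        qc_reports[lib] = report
        clean_per_lib[lib] = clean
        log.info("qc %s: %d raw -> %d clean", lib, report.total_raw, report.clean)
    libraries = sorted(clean_per_lib)
    counts["qc"] = {lib: r.as_dict() for lib, r in qc_reports.items()}
    pd.DataFrame({lib: r.as_dict() for lib, r in qc_reports.items()}
                 ).to_csv(out / "qc_report.tsv", sep="\t")

    # --- stage 2: collapse + annotate -------------------------------------
    tags = annotate.collapse_tags(clean_per_lib)
    refs = annotate.load_reference_bundle(bundle)
    annotations = annotate.annotate_tags(tags, refs)
    dist = annotate.category_distribution(annotations)
    dist.to_csv(out / "category_distribution.tsv", sep="\t")
    lengths = annotate.length_distribution(tags)
    lengths.to_csv(out / "length_distribution.tsv", sep="\t")
    counts["n_tags"] = len(tags)
    counts["category_totals"] = {
        cat: int(sum(sum(a.tag.counts.values()) for a in annotations
                     if a.category == cat))
        for cat in annotate.CATEGORIES}

    # --- stage 3: known + novel miRNAs -------------------------------------
    catalogue = discovery.Catalogue.load(bundle / "mature.fa", bundle / "hairpin.fa",
                                         cfg.focal_prefix)
    mirna_tags = [a.tag for a in annotations if a.category == "miRNA"]
    known = discovery.assign_known(mirna_tags, catalogue)
    unannotated = [a.tag for a in annotations if a.category == "unannotated"]
    cands = discovery.predict_novel(unannotated, refs.genome, cfg.discovery,
                                    index=refs.index)
    novel = discovery.dedupe_candidates(cands)
    discovery.write_discovery_outputs(cands, novel, out)
    counts["n_existing"] = sum(1 for r in known if r.status == "existing")
    counts["n_conserved"] = sum(1 for r in known if r.status == "conserved")
    counts["n_novel"] = len(novel)

    # --- stage 4: expression + DE ------------------------------------------
    records = known + novel
    mirna_counts = pd.DataFrame(
        {lib: [r.counts.get(lib, 0) for r in records] for lib in libraries},
        index=[r.name for r in records])
    clean_totals = pd.Series({lib: qc_reports[lib].clean for lib in libraries})
    mirna_matrix = expression.ExpressionMatrix(mirna_counts, library_totals=clean_totals)
    mirna_tpm = expression.tpm_normalize(mirna_matrix)
    mirna_tpm.to_csv(out / "mirna_tpm.tsv", sep="\t")
    groups = {lib: lib[:-1] for lib in libraries}
    de_mirnas = {}
    for a, b in COMPARISONS:
        de = expression.call_de_mirnas(mirna_matrix, (a, b), groups, opts=cfg.de)
        de_mirnas[f"{a}_vs_{b}"] = de
    pd.concat(de_mirnas.values()).to_csv(out / "de_mirnas.tsv", sep="\t")

    gene_counts = pd.read_csv(bundle / "mrna_counts.tsv", sep="\t", index_col=0)
    lengths_s = pd.Series({g.gene_id: g.transcript_length for g in refs.genes})
    gene_matrix = expression.ExpressionMatrix(gene_counts,
                                              feature_lengths=lengths_s)
    gene_fpkm = expression.fpkm_normalize(gene_matrix)
    degs = {}
    for a, b in COMPARISONS:
        degs[f"{a}_vs_{b}"] = expression.call_degs(gene_matrix, (a, b), groups,
                                                   opts=cfg.de)
    pd.concat(degs.values()).to_csv(out / "degs.tsv", sep="\t")
    for comp in de_mirnas:
        counts[f"n_de_mirnas_{comp}"] = int(de_mirnas[comp]["called"].sum())
        counts[f"n_degs_{comp}"] = int(degs[comp]["called"].sum())

    # --- stage 5: target prediction ----------------------------------------
    de_union = sorted({f for comp in de_mirnas.values()
                       for f in comp.index[comp["called"]]})
    seq_of = {r.name: r.mature_seq for r in records}
    transcripts = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(bundle / "transcripts.fa"), "fasta")}
    hits = targets.scan_transcriptome({m: seq_of[m] for m in de_union},
                                      transcripts, cfg.rules)
    targets.hits_table(hits).to_csv(out / "target_hits.tsv", sep="\t", index=False)
    counts["n_target_hits"] = len(hits)

    # --- stage 6: integration ----------------------------------------------
    pair_records, pair_summaries, networks, enrichments = {}, {}, {}, {}
    annotation_map = None
    ann_path = bundle / "annotation.tsv"
    if ann_path.exists():
        annotation_map = pd.read_csv(ann_path, sep="\t")
    population = set(gene_counts.index)
    for a, b in COMPARISONS:
        comp = f"{a}_vs_{b}"
        pairs = integrate.build_pairs(de_mirnas[comp], hits, degs[comp])
        libs = [l for l in libraries if groups[l] in (a, b)]
        recs, summary = integrate.classify_pairs(pairs, mirna_tpm, gene_fpkm,
                                                 libs, comp, cfg.correlation)
        pair_records[comp] = recs
        pair_summaries[comp] = summary
        networks[comp] = integrate.dedupe_network(recs)
        counts[f"n_pairs_{comp}"] = summary["n_pairs"]
        counts[f"n_negative_{comp}"] = summary["n_negative"]
        counts[f"n_positive_{comp}"] = summary["n_positive"]
        counts[f"n_none_{comp}"] = summary["n_none"]
        counts[f"n_unique_mirnas_{comp}"] = networks[comp]["n_unique_mirnas"]
        counts[f"n_unique_ctgs_{comp}"] = networks[comp]["n_unique_ctgs"]
        ctgs = set(recs["ctg"])
        if annotation_map is not None and ctgs:
            try:
                enrichments[comp] = enrich.enrich(ctgs, population, annotation_map)
            except ValueError as exc:
                log.warning("enrichment skipped for %s: %s", comp, exc)
    if pair_records:
        pd.concat(pair_records.values()).to_csv(out / "pairs.tsv", sep="\t",
                                                index=False)
    for comp, e in enrichments.items():
        e.to_csv(out / f"enrichment_{comp}.tsv", sep="\t", index=False)

    manifest = RunManifest(version=__version__, config_hash=cfg.hash(),
                           input_checksums=checksums, counts=counts,
                           started=started, finished=time.time())
    manifest.save(out / "manifest.json")
    return PipelineResult(
        qc_reports=qc_reports, tags=tags, annotations=annotations,
        known_records=known, novel_records=novel, candidates=cands,
        mirna_matrix=mirna_matrix, mirna_tpm=mirna_tpm, de_mirnas=de_mirnas,
        gene_matrix=gene_matrix, gene_fpkm=gene_fpkm, degs=degs, hits=hits,
        pair_records=pair_records, pair_summaries=pair_summaries,
        networks=networks, enrichments=enrichments, manifest=manifest)


def evaluate_against_truth(result: PipelineResult, truth: GroundTruth,
                           ) -> pd.DataFrame:
    """Per-stage sensitivity/precision against the planted ground truth."""
    rows = []

    planted_matures = {transcribe(h["mature"]) for h in truth.planted_hairpins}
    found_matures = {r.mature_seq for r in result.novel_records}
    if planted_matures:
        rows.append({"stage": "hairpin_discovery", "metric": "sensitivity",
                     "value": len(planted_matures & found_matures) / len(planted_matures)})

    seq_of = {r.name: r.mature_seq for r in (result.known_records
                                             + result.novel_records)}
    for comp, de in result.de_mirnas.items():
        planted = {m for m, lfcs in truth.planted_de_mirnas.items()
                   if abs(lfcs.get(comp, 0.0)) >= 1.0}
        in_matrix = {n for n, s in seq_of.items() if s in planted}
        called = {n for n in de.index[de["called"]]}
        if in_matrix:
            tp = sum(1 for n in in_matrix if n in called)
            rows.append({"stage": f"de_mirna_{comp}", "metric": "sensitivity",
                         "value": tp / len(in_matrix)})
        if called:
            fp = sum(1 for n in called
                     if truth.planted_de_mirnas.get(seq_of.get(n, ""), {})
                     .get(comp, 0.0) == 0.0)
            rows.append({"stage": f"de_mirna_{comp}", "metric": "fdp",
                         "value": fp / len(called)})

    # planted target sites among predicted hits (only DE miRNAs are scanned)
    name_of = {s: n for n, s in seq_of.items()}
    hit_pairs = {(h.mirna, h.transcript) for h in result.hits}
    planted_sites = [(name_of.get(m), g) for m, sites in truth.planted_targets.items()
                     for (g, _pos, _w) in sites if name_of.get(m) is not None]
    scanned = {h.mirna for h in result.hits} | {
        n for de in result.de_mirnas.values() for n in de.index[de["called"]]}
    relevant = [(n, g) for n, g in planted_sites if n in scanned]
    if relevant:
        tp = sum(1 for p in relevant if p in hit_pairs)
        rows.append({"stage": "target_prediction", "metric": "sensitivity",
                     "value": tp / len(relevant)})

    neg_found = set()
    n_pos = n_all = 0
    for comp, recs in result.pair_records.items():
        for _, r in recs.iterrows():
            n_all += 1
            if r["cls"] == "positive":
                n_pos += 1
            if r["cls"] == "negative":
                neg_found.add((seq_of.get(r["mirna"], ""), r["ctg"]))
    planted_neg = set(map(tuple, truth.planted_negative_pairs))
    if planted_neg:
        rows.append({"stage": "integration", "metric": "negative_sensitivity",
                     "value": len(planted_neg & neg_found) / len(planted_neg)})
    if n_all:
        rows.append({"stage": "integration", "metric": "positive_rate",
                     "value": n_pos / n_all})
    return pd.DataFrame(rows)
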