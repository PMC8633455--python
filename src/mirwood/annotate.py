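"""Tag collapsing and the reference annotation cascade.

Clean reads are collapsed to unique tags (one record per distinct sequence,
with per-library counts), and every tag is assigned exactly one category by a
fixed precedence order:

    rRNA > snRNA > snoRNA > tRNA > repeat > miRNA (catalogue) >
    exon_sense > exon_antisense > intron_sense > intron_antisense >
    unannotated

Class references (rRNA/tRNA/snRNA/snoRNA) match by exact sense-strand
substring; the genome by exact full-length match on either strand; the
miRNA catalogue by exact full-length identity with a mature sequence.
Exon/intron sense is decided by the tag's alignment strand against the gene
strand.  Distribution tables are tag-abundance weighted, so per-library
category counts sum to the library's clean-read total.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import revcomp_dna

log = logging.getLogger(__name__)

CATEGORIES = ("rRNA", "snRNA", "snoRNA", "tRNA", "repeat", "miRNA",
              "exon_sense", "exon_antisense", "intron_sense",
              "intron_antisense", "unannotated")

ANCHOR = 18  # k-mer length anchoring genome lookups (minimum tag length)


@dataclass
class CleanTag:
    """A distinct clean-read sequence with per-library counts."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class TagAnnotation:
    tag: CleanTag
    category: str
    evidence: str = ""


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int       # 1-based inclusive
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


class GenomeIndex:
    """Exact-match lookup of >=18-nt tags against a genome, both strands.

    Indexes every 18-mer start position of the forward strand as a 36-bit
    integer key; a query verifies the full tag at each anchored position.
    """

    _CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self._keys: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        for chrom, seq in genome.items():
            codes = np.frombuffer(seq.encode(), dtype=np.uint8)
            lut = np.full(256, 255, dtype=np.uint64)
            for b, v in self._CODE.items():
                lut[ord(b)] = v
            c = lut[codes]
            n = len(seq) - ANCHOR + 1
            if n <= 0:
                self._keys[chrom] = np.empty(0, dtype=np.uint64)
                self._order[chrom] = np.empty(0, dtype=np.int64)
                continue
            mult = (4 ** np.arange(ANCHOR - 1, -1, -1)).astype(np.uint64)
            win = np.lib.stride_tricks.sliding_window_view(c, ANCHOR)
            keys = (win * mult).sum(axis=1)
            keys[np.any(win == 255, axis=1)] = np.uint64(2**63)  # windows with N etc.
            order = np.argsort(keys, kind="stable").astype(np.int64)
            self._keys[chrom] = keys[order]
            self._order[chrom] = order

    def _encode(self, kmer: str) -> int | None:
        v = 0
        for ch in kmer:
            b = self._CODE.get(ch)
            if b is None:
                return None
            v = (v << 2) | b
        return v

    def _anchor_hits(self, chrom: str, seq: str) -> list[int]:
        key = self._encode(seq[:ANCHOR])
        if key is None:
            return []
        keys = self._keys[chrom]
        lo = np.searchsorted(keys, np.uint64(key), side="left")
        hi = np.searchsorted(keys, np.uint64(key), side="right")
        g = self.genome[chrom]
        out = []
        for pos in self._order[chrom][lo:hi]:
            pos = int(pos)
            if g[pos: pos + len(seq)] == seq:
                out.append(pos)
        return sorted(out)

    def find_hits(self, tag: str, max_hits: int | None = None,
                  ) -> list[tuple[str, int, str]]:
        """All exact full-length hits as (chrom, 0-based start, strand).

        Minus-strand hits report the forward-strand interval that the tag's
        reverse complement occupies.  Results are ordered by (chrom, pos),
        plus strand first — the first entry is the canonical reported locus.
        """
        if len(tag) < ANCHOR:
            return []
        rc = revcomp_dna(tag)
        hits = []
        for chrom in sorted(self.genome):
            for pos in self._anchor_hits(chrom, tag):
                hits.append((chrom, pos, "+"))
            if rc != tag:
                for pos in self._anchor_hits(chrom, rc):
                    hits.append((chrom, pos, "-"))
        hits.sort(key=lambda h: (h[0], h[1], h[2]))
        if max_hits is not None:
            hits = hits[:max_hits]
        return hits


@dataclass
class ReferenceBundle:
    """Everything the cascade needs, loaded once."""

    genome: dict[str, str]
    class_refs: dict[str, list[tuple[str, str]]]   # class -> [(id, seq)]
    repeats: list[tuple[str, int, int]]            # 0-based half-open
    genes: list[GeneModel]
    mature_catalogue: dict[str, str]               # mature seq (DNA) -> name
    index: GenomeIndex = None

    def __post_init__(self):
        if self.index is None:
            self.index = GenomeIndex(self.genome)
        self._genes_by_chrom: dict[str, list[GeneModel]] = {}
        for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
            self._genes_by_chrom.setdefault(g.chrom, []).append(g)
        self._gene_starts = {c: [g.start for g in gs]
                             for c, gs in self._genes_by_chrom.items()}
        self._repeats_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in sorted(self.repeats):
            self._repeats_by_chrom.setdefault(c, []).append((s, e))

    def genes_overlapping(self, chrom: str, start0: int, end0: int) -> list[GeneModel]:
        """Genes overlapping [start0, end0) (0-based half-open)."""
        gs = self._genes_by_chrom.get(chrom, [])
        starts = self._gene_starts.get(chrom, [])
        i = bisect_right(starts, end0)  # genes with 1-based start <= end0
        out = []
        for g in gs[:i]:
            if g.end >= start0 + 1:
                out.append(g)
        return out

    def in_repeat(self, chrom: str, start0: int, end0: int) -> bool:
        for s, e in self._repeats_by_chrom.get(chrom, []):
            if s < end0 and e > start0:
                return True
        return False


def load_reference_bundle(directory: str | Path) -> ReferenceBundle:
    """Load the standard reference directory layout.

    Expects genome.fa, genes.gff3, repeats.bed, mature.fa, and per-class
    FASTAs rRNA.fa / tRNA.fa / snRNA.fa / snoRNA.fa.
    """
    d = Path(directory)
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(d / "genome.fa", "fasta")}
    class_refs = {}
    for cls in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        path = d / f"{cls}.fa"
        if not path.exists():
            raise FileNotFoundError(f"missing reference class FASTA: {path.name}")
        class_refs[cls] = [(rec.id, str(rec.seq).upper())
                           for rec in SeqIO.parse(path, "fasta")]
    repeats = []
    bed = d / "repeats.bed"
    if bed.exists():
        for line in bed.read_text().splitlines():
            if line.strip():
                c, s, e = line.split("\t")[:3]
                repeats.append((c, int(s), int(e)))
    genes = read_gff3(d / "genes.gff3")
    mature = {}
    for rec in SeqIO.parse(d / "mature.fa", "fasta"):
        mature[str(rec.seq).upper().replace("U", "T")] = rec.id
    return ReferenceBundle(genome=genome, class_refs=class_refs, repeats=repeats,
                           genes=genes, mature_catalogue=mature)


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = line.split("\t")
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "gene":
            gid = attr["ID"]
            genes[gid] = GeneModel(gene_id=gid, chrom=chrom, start=int(start),
                                   end=int(end), strand=strand)
        elif ftype == "exon":
            gid = attr.get("Parent", "")
            if gid in genes:
                genes[gid].exons.append((int(start), int(end)))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values())


def collapse_tags(reads_per_library: dict[str, Iterable[str]]) -> list[CleanTag]:
    """One CleanTag per distinct sequence, counts per library.

    Accepts either iterables of sequences or {sequence: count} mappings per
    library.  Output order is deterministic (by sequence).
    """
    tags: dict[str, dict[str, int]] = {}
    for lib in sorted(reads_per_library):
        src = reads_per_library[lib]
        items = src.items() if hasattr(src, "items") else ((s, 1) for s in src)
        for seq, n in items:
            tags.setdefault(seq, {})
            tags[seq][lib] = tags[seq].get(lib, 0) + n
    return [CleanTag(seq=s, counts=c) for s, c in sorted(tags.items())]


def classify_tag(tag: CleanTag, refs: ReferenceBundle) -> TagAnnotation:
    """First matching category in precedence order wins."""
    seq = tag.seq
    for cls in ("rRNA", "snRNA", "snoRNA", "tRNA"):
        for rid, ref in refs.class_refs[cls]:
            if seq in ref:
                return TagAnnotation(tag, cls, rid)
    hits = refs.index.find_hits(seq)
    for chrom, pos, strand in hits:
        if refs.in_repeat(chrom, pos, pos + len(seq)):
            return TagAnnotation(tag, "repeat", f"{chrom}:{pos + 1}")
    if seq in refs.mature_catalogue:
        return TagAnnotation(tag, "miRNA", refs.mature_catalogue[seq])
    best: tuple[int, TagAnnotation] | None = None
    order = {"exon_sense": 0, "exon_antisense": 1, "intron_sense": 2,
             "intron_antisense": 3}
    for chrom, pos, strand in hits:
        for gene in refs.genes_overlapping(chrom, pos, pos + len(seq)):
            in_exon = any(s - 1 < pos + len(seq) and e > pos for s, e in gene.exons)
            sense = "sense" if strand == gene.strand else "antisense"
            cat = f"{'exon' if in_exon else 'intron'}_{sense}"
            cand = TagAnnotation(tag, cat, f"{gene.gene_id}@{chrom}:{pos + 1}")
            if best is None or order[cat] < best[0]:
                best = (order[cat], cand)
    if best is not None:
        return best[1]
    return TagAnnotation(tag, "unannotated",
                         f"{hits[0][0]}:{hits[0][1] + 1}" if hits else "")


def annotate_tags(tags: list[CleanTag], refs: ReferenceBundle) -> list[TagAnnotation]:
    return [classify_tag(t, refs) for t in tags]


def category_distribution(annotations: list[TagAnnotation]) -> pd.DataFrame:
    """Abundance-weighted per-library category table (counts and percent).

    Row order follows the cascade's category list; per-library percents sum
    to 100.
    """
    libs = sorted({lib for a in annotations for lib in a.tag.counts})
    acc = {cat: {lib: 0 for lib in libs} for cat in CATEGORIES}
    for a in annotations:
        row = acc[a.category]
        for lib, n in a.tag.counts.items():
            row[lib] += n
    counts = pd.DataFrame(acc).T.reindex(index=list(CATEGORIES), columns=libs)
    out = {}
    for lib in libs:
        total = counts[lib].sum()
        out[(lib, "count")] = counts[lib]
        out[(lib, "percent")] = (100.0 * counts[lib] / total) if total else 0.0
    return pd.DataFrame(out)


def length_distribution(tags: list[CleanTag], lo: int = 18, hi: int = 30,
                        ) -> pd.DataFrame:
    """Abundance-weighted per-library length fractions over [lo, hi] nt."""
    libs = sorted({lib for t in tags for lib in t.counts})
    lengths = range(lo, hi + 1)
    acc = {L: {lib: 0.0 for lib in libs} for L in lengths}
    for t in tags:
        L = len(t.seq)
        if lo <= L <= hi:
            row = acc[L]
            for lib, n in t.counts.items():
                row[lib] += n
    table = pd.DataFrame(acc).T.reindex(index=list(lengths), columns=libs).astype(float)
    for lib in libs:
        total = table[lib].sum()
        if total > 0:
            table[lib] /= total
        else:
            log.warning("library %s has no tags in [%d, %d] nt", lib, lo, hi)
    return table
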