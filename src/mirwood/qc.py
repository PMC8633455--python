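"""Raw read cleaning for small-RNA and mRNA libraries.

Small-RNA reads are filtered in a fixed order: malformed records, then
low-quality reads (any N, or two or more bases at Phred <= 20), then adapter
classification — a read must contain a locatable 3' adapter; reads that are
5'-adapter contaminated, adapter-only, or adapter-free are artifacts — then
poly(A) inserts, then inserts shorter than 18 nt.  Survivors are trimmed to
their insert.  Adapter location uses an exact 8-nt seed of the adapter's
5' end extended with at most one mismatch; poly(A) means an insert that is at
least 90% A.  Reads longer than 30 nt after trimming are retained (length
histograms downstream report 18-30 nt).

mRNA read pairs are cleaned by the transcriptome rules: adapter-trimmed
length >= 50 nt, at most 10% N, at most 50% of bases at Phred <= 20; a pair
is dropped when either mate fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

SEED_LEN = 8
MAX_EXTEND_MISMATCH = 1
LOWQ_PHRED = 20
MIN_INSERT = 18
POLYA_FRACTION = 0.9


@dataclass
class SmallRNARead:
    id: str
    seq: str
    qual: str  # Phred+33


@dataclass
class QCReport:
    """Per-category removal accounting; categories partition the input."""

    total_raw: int = 0
    removed_low_quality: int = 0
    adapter_3p_only: int = 0       # 3' adapter with empty insert
    adapter_5p_only: int = 0       # 5'-adapter contamination
    adapter_no_insert: int = 0     # both adapters back to back
    adapter_none: int = 0          # no locatable 3' adapter
    removed_polyA: int = 0
    removed_short: int = 0
    malformed: int = 0
    clean: int = 0

    @property
    def removed_adapter_artifact(self) -> int:
        return (self.adapter_3p_only + self.adapter_5p_only
                + self.adapter_no_insert + self.adapter_none)

    def conserved(self) -> bool:
        return self.total_raw == (self.clean + self.removed_low_quality
                                  + self.removed_adapter_artifact
                                  + self.removed_polyA + self.removed_short
                                  + self.malformed)

    def as_dict(self) -> dict:
        return {
            "total_raw": self.total_raw,
            "removed_low_quality": self.removed_low_quality,
            "removed_adapter_artifact": self.removed_adapter_artifact,
            "adapter_3p_only": self.adapter_3p_only,
            "adapter_5p_only": self.adapter_5p_only,
            "adapter_no_insert": self.adapter_no_insert,
            "adapter_none": self.adapter_none,
            "removed_polyA": self.removed_polyA,
            "removed_short": self.removed_short,
            "malformed": self.malformed,
            "clean": self.clean,
        }


def _find_adapter(seq: str, adapter: str, start: int = 0) -> int:
    """Leftmost adapter start via exact 8-nt seed + <=1-mismatch extension; -1 if absent."""
    seed = adapter[:SEED_LEN]
    pos = seq.find(seed, start)
    while pos >= 0:
        rest = adapter[SEED_LEN:]
        tail = seq[pos + SEED_LEN: pos + SEED_LEN + len(rest)]
        mism = sum(1 for a, b in zip(rest, tail) if a != b)
        if mism <= MAX_EXTEND_MISMATCH:
            return pos
        pos = seq.find(seed, pos + 1)
    return pos


def _is_polya(insert: str) -> bool:
    return len(insert) > 0 and insert.count("A") / len(insert) >= POLYA_FRACTION


def detect_adapter(seq: str, adapter_3p: str, adapter_5p: str = "",
                   ) -> tuple[str, str]:
    """Classify a read's adapter content.

    Returns (class, insert) with class in {"3p_only", "5p_only",
    "both_no_insert", "none", "polyA"}.  "3p_only" with a non-empty insert is
    the normal case (insert followed by the 3' adapter); an empty insert
    marks an adapter-only artifact.
    """
    five_end = -1
    if adapter_5p and len(seq) >= SEED_LEN and seq.startswith(adapter_5p[:SEED_LEN]):
        overlap = min(len(adapter_5p), len(seq))
        mism = sum(1 for a, b in zip(adapter_5p[:overlap], seq[:overlap]) if a != b)
        if mism <= MAX_EXTEND_MISMATCH:
            five_end = overlap
    three_pos = _find_adapter(seq, adapter_3p, start=max(0, five_end))
    if five_end >= 0:
        if three_pos == five_end:
            return "both_no_insert", ""
        return "5p_only", ""
    if three_pos < 0:
        return "none", ""
    insert = seq[:three_pos]
    if _is_polya(insert):
        return "polyA", insert
    return "3p_only", insert


def _lowq_count(qual: str) -> int:
    cutoff = chr(LOWQ_PHRED + 33)
    return sum(1 for c in qual if c <= cutoff)


def clean_srna_reads(reads: Iterable[SmallRNARead | tuple], adapter_3p: str,
                     adapter_5p: str) -> tuple[list[SmallRNARead], QCReport]:
    """Clean a small-RNA library read by read.  Returns survivors + report."""
    if not adapter_3p or not adapter_5p:
        raise ValueError("both adapters must be non-empty")
    out: list[SmallRNARead] = []
    report = QCReport()
    for r in reads:
        if not isinstance(r, SmallRNARead):
            r = SmallRNARead(*r)
        verdict, insert, qtrim = judge_srna(r.seq, r.qual, adapter_3p, adapter_5p)
        _count(report, verdict)
        if verdict == "clean":
            out.append(SmallRNARead(r.id, insert, qtrim))
    return out, report


def clean_srna_counted(records: Mapping[tuple[str, str], int], adapter_3p: str,
                       adapter_5p: str) -> tuple[dict[str, int], QCReport]:
    """Clean collapsed (seq, qual) -> count records; returns insert -> count.

    Identical records share one QC verdict, so collapsed cleaning is exactly
    equivalent to per-read cleaning but much faster on deep libraries.
    """
    report = QCReport()
    clean: dict[str, int] = {}
    for (seq, qual), n in records.items():
        verdict, insert, _ = judge_srna(seq, qual, adapter_3p, adapter_5p)
        _count(report, verdict, n)
        if verdict == "clean":
            clean[insert] = clean.get(insert, 0) + n
    return clean, report


def judge_srna(seq: str, qual: str, adapter_3p: str, adapter_5p: str,
               ) -> tuple[str, str, str]:
    """Verdict for one read: (category, insert, trimmed qual)."""
    if len(seq) != len(qual):
        log.warning("malformed record: seq/qual length mismatch")
        return "malformed", "", ""
    if "N" in seq or _lowq_count(qual) > 1:
        return "low_quality", "", ""
    cls, insert = detect_adapter(seq, adapter_3p, adapter_5p)
    if cls == "none":
        return "adapter_none", "", ""
    if cls == "5p_only":
        return "adapter_5p_only", "", ""
    if cls == "both_no_insert":
        return "adapter_no_insert", "", ""
    if cls == "3p_only" and not insert:
        return "adapter_3p_only", "", ""
    if cls == "polyA":
        return "polyA", "", ""
    if len(insert) < MIN_INSERT:
        return "short", "", ""
    return "clean", insert, qual[:len(insert)]


def _count(report: QCReport, verdict: str, n: int = 1) -> None:
    report.total_raw += n
    attr = {
        "malformed": "malformed",
        "low_quality": "removed_low_quality",
        "adapter_none": "adapter_none",
        "adapter_5p_only": "adapter_5p_only",
        "adapter_no_insert": "adapter_no_insert",
        "adapter_3p_only": "adapter_3p_only",
        "polyA": "removed_polyA",
        "short": "removed_short",
        "clean": "clean",
    }[verdict]
    setattr(report, attr, getattr(report, attr) + n)


# -- mRNA ------------------------------------------------------------------

MRNA_MIN_LEN = 50
MRNA_MAX_N_FRACTION = 0.10
MRNA_MAX_LOWQ_FRACTION = 0.50


def _judge_mrna_mate(seq: str, qual: str, adapter: str) -> tuple[str, str, str]:
    if len(seq) != len(qual):
        return "malformed", "", ""
    pos = _find_adapter(seq, adapter)
    if pos >= 0:
        seq, qual = seq[:pos], qual[:pos]
    if len(seq) < MRNA_MIN_LEN:
        return "short", "", ""
    if seq.count("N") / len(seq) > MRNA_MAX_N_FRACTION:
        return "low_quality", "", ""
    if _lowq_count(qual) / len(qual) > MRNA_MAX_LOWQ_FRACTION:
        return "low_quality", "", ""
    return "clean", seq, qual


def clean_mrna_reads(read_pairs: Iterable[tuple], adapter: str,
                     ) -> tuple[list[tuple], QCReport]:
    """Clean paired mRNA reads; a pair survives only if both mates pass.

    ``read_pairs`` yields (id, seq1, qual1, seq2, qual2).  The report counts
    pairs, attributing each dropped pair to the first failing rule in the
    order: malformed, length, N-fraction / quality.
    """
    out = []
    report = QCReport()
    for rid, s1, q1, s2, q2 in read_pairs:
        v1 = _judge_mrna_mate(s1, q1, adapter)
        v2 = _judge_mrna_mate(s2, q2, adapter)
        verdicts = [v1[0], v2[0]]
        report.total_raw += 1
        if "malformed" in verdicts:
            report.malformed += 1
        elif "short" in verdicts:
            report.removed_short += 1
        elif "low_quality" in verdicts:
            report.removed_low_quality += 1
        else:
            out.append((rid, v1[1], v1[2], v2[1], v2[2]))
            report.clean += 1
    return out, report
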