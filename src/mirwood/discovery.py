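"""Known-miRNA assignment and novel-miRNA (hairpin) prediction.

Known assignment: a tag identical to a focal-species catalogue mature is an
*existing* miRNA (named with the catalogue's -5p/-3p arm suffix); a tag
matching only another species' mature is a *conserved* miRNA, renamed with
the -x/-y convention (x = 5' arm, y = 3' arm of its precursor).

Novel prediction follows the classic plant hairpin-screen recipe: every
unannotated tag with a perfect genome match is tested as the mature arm of a
candidate precursor.  A partner (miRNA*) region is sought within a bounded
distance, the excised window (with 20-nt flanks) is folded, and the candidate
must satisfy all structural criteria: mature length 18-25 nt, star length
20-23 nt, at most 20 genome copies, precursor MFE at or below the stability
threshold (default -18 kcal/mol), miRNA/miRNA* spacing 16-300 nt, duplex
bulges at most 4 nt, duplex asymmetry at most 4 nt, and a single stem-loop
with the mature wholly on one arm.  The star is delimited by the partner
span of the mature plus a 2-nt 3' overhang (Dicer geometry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from . import structure
from ._seq import encode, revcomp_dna, transcribe
from .annotate import CleanTag, GenomeIndex

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscoveryConfig:
    mature_len_min: int = 18
    mature_len_max: int = 25
    star_len_min: int = 20
    star_len_max: int = 23
    max_copies: int = 20
    precursor_mfe_max: float = -18.0   # "at least this stable"; see docs
    spacing_min: int = 16
    spacing_max: int = 300
    max_bulge: int = 4
    max_asymmetry: int = 4
    flank: int = 20
    partner_min_identity: float = 0.6  # complementarity prefilter for star search


DEFAULT_DISCOVERY = DiscoveryConfig()

CRITERIA = ("mature_min_len", "mature_max_len", "star_min_len", "star_max_len",
            "max_copies", "precursor_mfe", "spacing_max", "spacing_min",
            "max_bulge", "max_asymmetry", "flank_excised", "single_stemloop")


@dataclass
class MiRNARecord:
    name: str
    status: str                 # existing | conserved | novel
    arm_label: str              # 5p | 3p | x | y
    mature_seq: str             # RNA
    precursor: str | None = None
    counts: dict[str, int] = field(default_factory=dict)
    copies_on_reference: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class HairpinCandidate:
    locus: tuple[str, int, int, str]    # 1-based inclusive
    precursor_seq: str                  # RNA, strand-oriented
    fold: structure.FoldResult
    mature_tag: CleanTag
    mature_offset: int                  # 0-based within precursor
    star_seq: str
    spacing: int
    bulge_max: int
    asymmetry: int
    copies_on_reference: int
    arm: str
    criteria: dict[str, tuple[float, bool]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(ok for _, ok in self.criteria.values())


@dataclass
class CatalogueEntry:
    name: str
    mature: str    # RNA
    arm: str       # 5p | 3p


class Catalogue:
    """Known mature miRNAs, split into focal-species and other-species tiers."""

    def __init__(self, focal: list[CatalogueEntry], other: list[CatalogueEntry]):
        if not focal and not other:
            raise ValueError("empty miRNA catalogue")
        self.focal = sorted(focal, key=lambda e: e.name)
        self.other = sorted(other, key=lambda e: e.name)
        self.by_seq: dict[str, list[tuple[str, CatalogueEntry]]] = {}
        for tier, entries in (("focal", self.focal), ("other", self.other)):
            for e in entries:
                self.by_seq.setdefault(e.mature, []).append((tier, e))

    @classmethod
    def load(cls, mature_fa: str | Path, hairpin_fa: str | Path,
             focal_prefix: str = "ptc") -> "Catalogue":
        hairpins = {rec.id: transcribe(str(rec.seq).upper())
                    for rec in SeqIO.parse(str(hairpin_fa), "fasta")}
        focal, other = [], []
        for rec in SeqIO.parse(str(mature_fa), "fasta"):
            mat = transcribe(str(rec.seq).upper())
            hp_id = _hairpin_id(rec.id)
            arm = "5p"
            if hp_id in hairpins:
                arm = _arm_of(mat, hairpins[hp_id])
            elif rec.id.endswith("-3p"):
                arm = "3p"
            entry = CatalogueEntry(name=rec.id, mature=mat, arm=arm)
            (focal if rec.id.startswith(focal_prefix + "-") else other).append(entry)
        return cls(focal, other)


def _hairpin_id(mature_id: str) -> str:
    base = mature_id
    for suf in ("-5p", "-3p"):
        if base.endswith(suf):
            base = base[: -len(suf)]
    return base.replace("miR", "MIR")


def _arm_of(mature: str, hairpin: str) -> str:
    pos = hairpin.find(mature)
    if pos < 0:
        return "5p"
    centre = pos + len(mature) / 2
    return "5p" if centre <= len(hairpin) / 2 else "3p"


def _conserved_name(entry: CatalogueEntry) -> str:
    base = entry.name
    if "-" in base and not base.startswith("miR"):
        base = base.split("-", 1)[1]          # strip species prefix
    for suf in ("-5p", "-3p", "-x", "-y"):
        if base.endswith(suf):
            base = base[: -len(suf)]
    return f"{base}-{'x' if entry.arm == '5p' else 'y'}"


def assign_known(tags: list[CleanTag], catalogue: Catalogue) -> list[MiRNARecord]:
    """Match tags against the catalogue; focal tier wins, then name order."""
    records = []
    for tag in sorted(tags, key=lambda t: t.seq):
        matches = catalogue.by_seq.get(transcribe(tag.seq), [])
        if not matches:
            continue
        focal = [e for tier, e in matches if tier == "focal"]
        if focal:
            e = focal[0]
            name = e.name if e.name.endswith(("-5p", "-3p")) else f"{e.name}-{e.arm}"
            records.append(MiRNARecord(name=name, status="existing", arm_label=e.arm,
                                       mature_seq=e.mature, counts=dict(tag.counts)))
        else:
            e = matches[0][1]
            records.append(MiRNARecord(name=_conserved_name(e), status="conserved",
                                       arm_label="x" if e.arm == "5p" else "y",
                                       mature_seq=e.mature, counts=dict(tag.counts)))
    return records


def _complement_scan(mature_arr: np.ndarray, region_arr: np.ndarray) -> np.ndarray:
    """Fraction of complementary positions for each alignment of the reversed
    mature against the region (star candidates pair antiparallel)."""
    L = len(mature_arr)
    if len(region_arr) < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(region_arr, L)
    comp = structure.PAIR_TYPE[mature_arr[::-1][None, :], win] >= 0
    return comp.mean(axis=1)


def predict_novel(unannotated: list[CleanTag], genome: dict[str, str],
                  config: DiscoveryConfig = DEFAULT_DISCOVERY,
                  model: structure.EnergyModel = structure.DEFAULT_MODEL,
                  index: GenomeIndex | None = None) -> list[HairpinCandidate]:
    """Hairpin candidates passing all structural criteria, one per locus."""
    if index is None:
        index = GenomeIndex(genome)
    out: list[HairpinCandidate] = []
    for tag in sorted(unannotated, key=lambda t: t.seq):
        L = len(tag.seq)
        if not config.mature_len_min <= L <= config.mature_len_max:
            continue
        hits = index.find_hits(tag.seq)
        if not hits or len(hits) > config.max_copies:
            continue
        for chrom, pos, strand in hits:
            cand = _test_locus(tag, chrom, pos, strand, len(hits), genome,
                               config, model)
            if cand is not None:
                out.append(cand)
                break   # first passing window/locus per tag is kept per locus;
                        # additional loci collapse in dedupe via copy count
    return out


def _test_locus(tag: CleanTag, chrom: str, pos: int, strand: str, n_copies: int,
                genome: dict[str, str], config: DiscoveryConfig,
                model: structure.EnergyModel) -> HairpinCandidate | None:
    """Try the tag as a mature arm at one genome locus; return a passing candidate.

    Works in a strand-oriented local window W (5'->3' along the tag's strand)
    so both strands and both arm hypotheses share one code path.  Coordinates
    map back to the forward strand when the locus is reported.
    """
    g = genome[chrom]
    L = len(tag.seq)
    fl = config.flank
    reach = config.spacing_max + L + 2 + fl
    w_lo = max(0, pos - reach)
    w_hi = min(len(g), pos + L + reach)
    window = g[w_lo:w_hi]
    if strand == "-":
        window = revcomp_dna(window)
        moff = len(window) - (pos + L - w_lo)
    else:
        moff = pos - w_lo
    mature_dna = tag.seq
    if window[moff:moff + L] != mature_dna:
        moff = window.find(mature_dna)
        if moff < 0:
            return None
    mat_arr = encode(transcribe(mature_dna))
    win_arr = encode(transcribe(window))

    def to_forward(a: int, b: int) -> tuple[int, int]:
        # local [a, b) -> forward-strand 1-based inclusive
        if strand == "+":
            return w_lo + a + 1, w_lo + b
        return w_lo + (len(window) - b) + 1, w_lo + (len(window) - a)

    for arm in ("5p", "3p"):
        if arm == "5p":
            rs = moff + L               # region of possible star starts
            region = win_arr[rs: rs + config.spacing_max + L]
            frac = _complement_scan(mat_arr, region)
            if len(frac) == 0:
                continue
            ks = [int(k) for k in np.nonzero(frac >= config.partner_min_identity)[0]
                  if config.spacing_min <= int(k) <= config.spacing_max]
            ks.sort()                   # nearest partner first
            for k in ks[:5]:
                star_end = rs + k + L - 1 + 2
                a, b = max(0, moff - fl), min(len(window), star_end + 1 + fl)
                s1, e1 = to_forward(a, b)
                cand = _fold_window(tag, window[a:b], moff - a,
                                    (chrom, s1, e1, strand), n_copies,
                                    config, model, arm)
                if cand is not None and cand.passed:
                    return cand
        else:
            re_hi = moff                # star must end before the mature
            rs = max(0, re_hi - config.spacing_max - L - 2)
            region = win_arr[rs: re_hi]
            frac = _complement_scan(mat_arr, region)
            if len(frac) == 0:
                continue
            ks = []
            for k in np.nonzero(frac >= config.partner_min_identity)[0]:
                star_hi = rs + int(k) + L - 1 + 2
                spacing = moff - star_hi - 1
                if config.spacing_min <= spacing <= config.spacing_max:
                    ks.append((spacing, int(k)))
            ks.sort()                   # nearest partner first
            for _sp, k in ks[:5]:
                a = max(0, rs + k - fl)
                b = min(len(window), moff + L + fl)
                s1, e1 = to_forward(a, b)
                cand = _fold_window(tag, window[a:b], moff - a,
                                    (chrom, s1, e1, strand), n_copies,
                                    config, model, arm)
                if cand is not None and cand.passed:
                    return cand
    return None


def _fold_window(tag, pre_dna: str, mature_offset: int, locus, n_copies,
                 config, model, arm_hypothesis: str) -> HairpinCandidate | None:
    pre_rna = transcribe(pre_dna)
    if not 10 <= len(pre_rna) <= 500:
        return None
    mature_rna = transcribe(tag.seq)
    if pre_rna[mature_offset:mature_offset + len(mature_rna)] != mature_rna:
        mature_offset = pre_rna.find(mature_rna)
        if mature_offset < 0:
            return None
    fr = structure.fold(pre_rna, model)
    return evaluate_candidate(tag, fr, mature_offset, locus, n_copies, config,
                              arm_hypothesis)


def evaluate_candidate(tag: CleanTag, fr: structure.FoldResult, mature_offset: int,
                       locus, n_copies: int, config: DiscoveryConfig,
                       arm_hypothesis: str) -> HairpinCandidate | None:
    """Derive star/spacing/bulge/asymmetry from a fold and record all criteria."""
    L = len(tag.seq)
    mstart, mend = mature_offset, mature_offset + L - 1
    partner: dict[int, int] = {}
    for i, j in fr.pairs():
        partner[i], partner[j] = j, i
    paired_m = [p for p in range(mstart, mend + 1) if p in partner]
    if not paired_m:
        return None
    partners = [partner[p] for p in paired_m]
    star_lo, star_hi = min(partners), min(max(partners) + 2, len(fr.seq) - 1)
    star_len = star_hi - star_lo + 1
    ok_arm, arm = structure.is_stemloop(fr, tag.seq)
    if arm == "none":
        arm = arm_hypothesis
    if arm == "5p":
        spacing = star_lo - mend - 1
    else:
        spacing = mstart - star_hi - 1
    bulge_max = 0
    for a, b in zip(paired_m, paired_m[1:]):
        bulge_max = max(bulge_max, b - a - 1, abs(partner[a] - partner[b]) - 1)
    unp_m = (paired_m[-1] - paired_m[0] + 1) - len(paired_m)
    unp_s = (max(partners) - min(partners) + 1) - len(partners)
    asym = abs(unp_m - unp_s)
    crit = {
        "mature_min_len": (L, L >= config.mature_len_min),
        "mature_max_len": (L, L <= config.mature_len_max),
        "star_min_len": (star_len, star_len >= config.star_len_min),
        "star_max_len": (star_len, star_len <= config.star_len_max),
        "max_copies": (n_copies, n_copies <= config.max_copies),
        "precursor_mfe": (fr.mfe, fr.mfe <= config.precursor_mfe_max + 1e-9),
        "spacing_max": (spacing, spacing <= config.spacing_max),
        "spacing_min": (spacing, spacing >= config.spacing_min),
        "max_bulge": (bulge_max, bulge_max <= config.max_bulge),
        "max_asymmetry": (asym, asym <= config.max_asymmetry),
        "flank_excised": (config.flank, True),
        "single_stemloop": (1.0 if ok_arm else 0.0, ok_arm),
    }
    return HairpinCandidate(
        locus=tuple(locus), precursor_seq=fr.seq, fold=fr, mature_tag=tag,
        mature_offset=mature_offset, star_seq=fr.seq[star_lo:star_hi + 1],
        spacing=spacing, bulge_max=bulge_max, asymmetry=asym,
        copies_on_reference=n_copies, arm=arm, criteria=crit)


def dedupe_candidates(cands: list[HairpinCandidate]) -> list[MiRNARecord]:
    """Collapse candidates sharing a mature sequence into named novel records.

    Ordering (hence numbering) is by descending total tag count, then by
    mature sequence; counts merge, loci count as reference copies.
    """
    groups: dict[str, list[HairpinCandidate]] = {}
    for c in cands:
        groups.setdefault(c.mature_tag.seq, []).append(c)
    ordered = sorted(groups.items(),
                     key=lambda kv: (-kv[1][0].mature_tag.total, kv[0]))
    records = []
    for rank, (seq, group) in enumerate(ordered, start=1):
        rep = group[0]
        loci = {c.locus for c in group}
        records.append(MiRNARecord(
            name=f"novel-m{rank:04d}-{rep.arm}", status="novel",
            arm_label=rep.arm, mature_seq=transcribe(seq),
            precursor=rep.precursor_seq,
            counts=dict(rep.mature_tag.counts),
            copies_on_reference=max(len(loci), rep.copies_on_reference)))
    return records


def write_discovery_outputs(cands: list[HairpinCandidate],
                            records: list[MiRNARecord], outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "novel_hairpins.fa", "w") as fa, \
            open(out / "novel_structures.txt", "w") as st:
        for r in records:
            fa.write(f">{r.name}\n{r.precursor}\n")
        for c in cands:
            st.write(f">{c.locus[0]}:{c.locus[1]}-{c.locus[2]}({c.locus[3]})\n"
                     f"{c.fold.seq}\n{c.fold.structure} ({c.fold.mfe:.2f})\n")
    with open(out / "novel_mature.fa", "w") as fa:
        for r in records:
            fa.write(f">{r.name}\n{r.mature_seq}\n")
    import pandas as pd
    rows = []
    for c in cands:
        row = {"locus": f"{c.locus[0]}:{c.locus[1]}-{c.locus[2]}({c.locus[3]})",
               "mature": c.mature_tag.seq, "arm": c.arm, "passed": c.passed}
        for k, (v, ok) in c.criteria.items():
            row[k] = v
            row[f"{k}_pass"] = ok
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "hairpin_candidates.tsv", sep="\t", index=False)
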