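"""Synthetic stem small-RNA study generator with planted ground truth.

Emulates a three-stage (primary / transitional / secondary stem), three-
replicate small-RNA + mRNA experiment at toy scale: a random genome carrying
gene models, repeat copies and planted miRNA hairpin loci; per-class ncRNA
reference sets; a known-miRNA catalogue split into a focal-species and an
other-species tier; nine gzipped FASTQ libraries whose reads are category
mixtures (miRNA matures, ncRNA/repeat/degradation fragments, poly(A) and
too-short inserts, adapter artifacts, deliberately low-quality reads); and a
gene count matrix with negative-binomial noise.  Differential expression,
target sites and negatively correlated miRNA-target pairs are planted with
known effect sizes and recorded in a :class:`GroundTruth` object, so every
downstream stage can be scored against what was planted.

All randomness flows through one seeded generator; identical configurations
produce byte-identical output files (gzip members are written with a zeroed
timestamp).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._seq import back_transcribe, revcomp_dna, revcomp_rna, transcribe
from . import targets as _targets

BASES = np.array(list("ACGT"))
FLANK = 20
LOOP_LEN = 18
COMPARISONS = (("PS", "TS"), ("PS", "SS"), ("TS", "SS"))


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 500_000
    n_known_mirnas: int = 30
    n_novel_hairpins: int = 10
    n_genes: int = 300
    stages: tuple[str, ...] = ("PS", "TS", "SS")
    replicates_per_stage: int = 3
    library_depth: int = 200_000
    adapter_3p: str = "AGATCGGAAGAGCACACGTCT"
    adapter_5p: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    effect_log2fc: float = 3.0
    negcorr_fraction: float = 0.8
    nb_dispersion: float = 0.05
    mirna_proportion: float = 0.65
    contaminant_mix: dict = field(default_factory=lambda: {
        "rRNA": 0.05, "tRNA": 0.01, "snRNA": 0.002, "snoRNA": 0.003,
        "repeat": 0.005, "degradation": 0.25, "polyA": 0.02, "short": 0.01,
    })
    n_de_mirnas: int = 18
    n_targets_per_de: int = 2
    n_extra_degs: int = 30
    mrna_library_depth: int = 2_000_000
    n_artifact_reads: int = 120      # per artifact class per library
    n_lowquality_reads: int = 300    # reads given two Phred<=20 bases
    n_n_reads: int = 100             # reads given one N

    def validate(self) -> None:
        total = self.mirna_proportion + sum(self.contaminant_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"contaminant proportions plus miRNA proportion must sum to 1, got {total}")
        if not 0.0 <= self.negcorr_fraction <= 1.0:
            raise ValueError("negcorr_fraction must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if len(self.stages) != 3:
            raise ValueError("exactly three stage labels expected")

    @property
    def libraries(self) -> list[str]:
        return [f"{s}{r + 1}" for s in self.stages
                for r in range(self.replicates_per_stage)]


@dataclass
class GroundTruth:
    """What was planted: hairpins, DE effects, target sites, negative pairs.

    miRNAs are keyed by mature sequence (RNA), the one identifier that is
    stable across naming conventions.
    """

    planted_hairpins: list[dict] = field(default_factory=list)
    planted_de_mirnas: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_targets: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)
    planted_negative_pairs: list[tuple[str, str]] = field(default_factory=list)
    mirna_names: dict[str, str] = field(default_factory=dict)   # mature seq -> label

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["planted_negative_pairs"] = [list(p) for p in self.planted_negative_pairs]
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["planted_negative_pairs"] = [tuple(p) for p in d["planted_negative_pairs"]]
        d["planted_targets"] = {k: [tuple(v) for v in vs]
                                for k, vs in d["planted_targets"].items()}
        return cls(**d)


def _rand_seq(rng, n: int) -> str:
    return "".join(rng.choice(BASES, n))


def _rand_seq_clean(rng, n: int, forbidden: list[str]) -> str:
    for _ in range(50):
        s = _rand_seq(rng, n)
        if not any(f in s for f in forbidden):
            return s
    raise RuntimeError("could not draw a sequence avoiding adapter seeds")


def _build_hairpin(mature_rna: str, arm: str, rng, forbidden) -> tuple[str, str]:
    """Perfect-stem precursor around a mature; returns (precursor RNA, star RNA).

    The loop is drawn from {A, C} only so it cannot base-pair internally; the
    stem is fully complementary (flank + mature on one arm).  Star follows
    the 2-nt 3'-overhang convention.
    """
    loop = "".join(rng.choice(np.array(list("AC")), LOOP_LEN))
    flank = transcribe(_rand_seq_clean(rng, FLANK, forbidden))
    if arm == "5p":
        stem5 = flank + mature_rna
        pre = stem5 + loop + revcomp_rna(stem5)
        mstart = FLANK
    else:
        arm3 = mature_rna + flank
        pre = revcomp_rna(arm3) + loop + arm3
        mstart = len(arm3) + LOOP_LEN
    L = len(pre)
    mend = mstart + len(mature_rna) - 1
    partners = [L - 1 - p for p in range(mstart, mend + 1)]
    star_lo, star_hi = min(partners), min(max(partners) + 2, L - 1)
    return pre, pre[star_lo:star_hi + 1]


def plant_target_site(mirna: str, gene_seq: str, weighted_mismatches: float,
                      position: int, rules=None) -> str:
    """Insert a target site for ``mirna`` into ``gene_seq`` at ``position``.

    The site replaces len(miRNA) bases starting at ``position`` (0-based) and
    scores exactly ``weighted_mismatches`` under the duplex rules: G:U wobbles
    carry the half units, full mismatches the integer units, all placed at
    miRNA positions 13+ spaced two apart so rules 2-5 hold by construction.
    """
    rules = rules or _targets.DEFAULT_RULES
    w = float(weighted_mismatches)
    if not 0.0 <= w <= rules.max_total or (w * 2) != int(w * 2):
        raise ValueError("weighted_mismatches must be a half-integer in [0, 4]")
    mirna_rna = transcribe(mirna.upper())
    L = len(mirna_rna)
    if position < 0 or position + L > len(gene_seq):
        raise ValueError("site does not fit in gene sequence at this position")
    site = list(revcomp_dna(back_transcribe(mirna_rna)))
    n_full = int(w)
    n_half = int(round((w - n_full) * 2))
    slots = list(range(13, L + 1, 2))           # miRNA positions, 1-based
    gu_ok = [p for p in slots if mirna_rna[p - 1] in "GU"]
    if n_full + n_half > len(slots):
        raise ValueError("infeasible mismatch placement: not enough positions")
    if n_half and not gu_ok:
        raise ValueError("infeasible mismatch placement: no G/U position for a wobble")
    chosen_half = gu_ok[:n_half]
    remaining = [p for p in slots if p not in chosen_half]
    chosen_full = remaining[:n_full]
    full_base = {"A": "C", "C": "A", "G": "A", "U": "C"}
    for p in chosen_half:
        site[L - p] = "T" if mirna_rna[p - 1] == "G" else "G"
    for p in chosen_full:
        site[L - p] = full_base[mirna_rna[p - 1]]
    site_str = "".join(site)
    check = _targets.score_duplex(mirna_rna, site_str, rules)
    if abs(check.total_weighted - w) > 1e-9 or not check.passes_rules:
        raise ValueError("infeasible mismatch placement: constructed site fails rules")
    return gene_seq[:position] + site_str + gene_seq[position + L:]


def _choose_site_weight(mirna_rna: str, rng) -> float:
    """A planted-site weight that keeps the site discoverable: wobbles and at
    most one full mismatch keep the duplex MFE ratio comfortably above 74%."""
    options = [0.5, 1.0, 1.5]
    rng.shuffle(options)
    for w in options:
        n_half = int(round((w - int(w)) * 2))
        if n_half and not any(mirna_rna[p - 1] in "GU"
                              for p in range(13, len(mirna_rna) + 1, 2)):
            continue
        return w
    return 1.0


class _Pools:
    """Per-class pools of distinct read inserts with fixed relative weights."""

    def __init__(self, rng, cfg, refs, genes):
        self.inserts: dict[str, list[str]] = {}
        self.weights: dict[str, np.ndarray] = {}
        forbidden = [cfg.adapter_3p[:8], cfg.adapter_5p[:8]]

        def frag(src: str) -> str:
            n = int(rng.integers(18, 31)) if rng.random() < 0.6 else 24
            n = min(n, len(src))
            start = int(rng.integers(0, len(src) - n + 1))
            return src[start:start + n]

        def fill(cls, seqs, n):
            pool = []
            for _ in range(n):
                for _try in range(20):
                    s = frag(seqs[int(rng.integers(0, len(seqs)))])
                    if not any(f in s for f in forbidden):
                        break
                pool.append(s)
            self.inserts[cls] = pool
            self.weights[cls] = rng.exponential(1.0, size=len(pool))

        fill("rRNA", [s for _, s in refs["rRNA"]], 400)
        fill("tRNA", [s for _, s in refs["tRNA"]], 150)
        fill("snRNA", [s for _, s in refs["snRNA"]], 80)
        fill("snoRNA", [s for _, s in refs["snoRNA"]], 80)
        fill("repeat", refs["repeat_units"], 120)
        deg = []
        for _ in range(1500):
            g = genes[int(rng.integers(0, len(genes)))]
            r = rng.random()
            if r < 0.70:     # exon fragment (within one exon)
                exon = g["exons_seq"][int(rng.integers(0, len(g["exons_seq"])))]
                s = frag(exon)
                if r < 0.15:
                    s = revcomp_dna(s)
            else:            # intron fragment
                s = frag(g["intron_seq"])
                if r > 0.90:
                    s = revcomp_dna(s)
            deg.append(s)
        self.inserts["degradation"] = deg
        self.weights["degradation"] = rng.exponential(1.0, size=len(deg))
        self.inserts["polyA"] = ["A" * k for k in range(18, 26)]
        self.weights["polyA"] = np.ones(8)
        self.inserts["short"] = [_rand_seq_clean(rng, int(rng.integers(10, 18)), forbidden)
                                 for _ in range(100)]
        self.weights["short"] = np.ones(100)


def simulate_dataset(config: SimulationConfig, outdir: str | Path,
                     ) -> tuple[dict[str, Path], GroundTruth]:
    """Write the full input bundle and return (paths, ground truth)."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth()
    forbidden = [cfg.adapter_3p[:8], cfg.adapter_5p[:8]]

    # --- miRNA catalogue (known: focal 'ptc' tier + other-species tier) ---
    n_focal = int(round(cfg.n_known_mirnas * 0.6))
    catalogue = []   # dicts: name, mature (RNA), precursor (RNA), arm, tier
    seen = set()
    for i in range(cfg.n_known_mirnas):
        L = 24 if rng.random() < 0.2 else 21
        while True:
            mat = transcribe(_rand_seq_clean(rng, L, forbidden))
            if mat not in seen:
                seen.add(mat)
                break
        arm = "5p" if rng.random() < 0.5 else "3p"
        pre, star = _build_hairpin(mat, arm, rng, forbidden)
        if i < n_focal:
            name = f"ptc-miR{1001 + i}-{arm}"
            hp = f"ptc-MIR{1001 + i}"
            tier = "focal"
        else:
            name = f"ath-miR{2001 + i}"
            hp = f"ath-MIR{2001 + i}"
            tier = "other"
        catalogue.append(dict(name=name, hairpin_id=hp, mature=mat, precursor=pre,
                              arm=arm, tier=tier))
        truth.mirna_names[mat] = name

    # --- novel hairpins (to be planted in the genome) ---
    novel = []
    for i in range(cfg.n_novel_hairpins):
        while True:
            mat = transcribe(_rand_seq_clean(rng, 21, forbidden))
            if mat not in seen:
                seen.add(mat)
                break
        arm = "5p" if i % 2 == 0 else "3p"
        pre, star = _build_hairpin(mat, arm, rng, forbidden)
        novel.append(dict(mature=mat, precursor=pre, star=star, arm=arm))
        truth.mirna_names[mat] = f"planted-novel-{i + 1:04d}"

    # --- DE assignment over all matures -----------------------------------
    all_matures = [c["mature"] for c in catalogue] + [h["mature"] for h in novel]
    de_idx = rng.choice(len(all_matures), size=min(cfg.n_de_mirnas, len(all_matures)),
                        replace=False)
    stage_mult: dict[str, np.ndarray] = {m: np.ones(3) for m in all_matures}
    base_override: dict[str, float] = {}
    # Effects are planted in balanced up/down pairs whose base abundances are
    # chosen so the total miRNA mass is stage-invariant (an up 2^e paired with
    # a down 2^-e of base b*2^e cancels exactly); otherwise strong planted
    # effects would shift the relative abundance of every null miRNA and the
    # conditional test would rightly call them changed.
    per_comp: dict[tuple, int] = {}
    pending: dict[tuple, float] = {}
    f_abs = 2.0 ** cfg.effect_log2fc
    for k, idx in enumerate(sorted(de_idx)):
        mat = all_matures[idx]
        comp = COMPARISONS[k % 3]
        cnt = per_comp.get(comp, 0)
        per_comp[comp] = cnt + 1
        sign = 1.0 if cnt % 2 == 0 else -1.0
        if sign > 0:
            b = float(rng.lognormal(0.3, 0.6))
            pending[comp] = b
        else:
            b = pending.pop(comp, float(rng.lognormal(0.3, 0.6))) * f_abs
        base_override[mat] = b
        f = 2.0 ** (sign * cfg.effect_log2fc)
        mult = np.ones(3)
        yi = {"PS": 0, "TS": 1, "SS": 2}[comp[1]]
        mult[yi:] = f          # effect from the later stage onwards
        stage_mult[mat] = mult
        lfcs = {}
        for (x, y) in COMPARISONS:
            xi = {"PS": 0, "TS": 1, "SS": 2}[x]
            yi = {"PS": 0, "TS": 1, "SS": 2}[y]
            v = float(np.log2(mult[yi] / mult[xi]))
            if abs(v) > 1e-9:
                lfcs[f"{x}_vs_{y}"] = v
        truth.planted_de_mirnas[mat] = lfcs

    # --- gene structures ---------------------------------------------------
    genes = []
    for gi in range(cfg.n_genes):
        e1 = int(rng.integers(350, 501))
        il = int(rng.integers(120, 201))
        e2 = int(rng.integers(350, 501))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _rand_seq_clean(rng, e1 + il + e2, [])
        genes.append(dict(gene_id=f"Gene{gi + 1:04d}", e1=e1, il=il, e2=e2,
                          strand=strand, seq=seq))

    # --- plant target sites for DE miRNAs ---------------------------------
    de_matures = [all_matures[i] for i in sorted(de_idx)]
    target_gene_order = rng.permutation(cfg.n_genes)
    gene_cursor = 0
    all_pairs = []
    for mat in de_matures:
        mirna_rna = mat
        sites = []
        for _ in range(cfg.n_targets_per_de):
            if gene_cursor >= len(target_gene_order):
                break
            g = genes[int(target_gene_order[gene_cursor])]
            gene_cursor += 1
            L = len(mirna_rna)
            planted = False
            for _try in range(20):
                w = _choose_site_weight(mirna_rna, rng)
                pos = int(rng.integers(40, g["e1"] - L - 40))
                try:
                    new_seq = plant_target_site(mirna_rna, g["seq"], w, pos)
                except ValueError:
                    continue
                hit = _targets.score_duplex(mirna_rna, new_seq[pos:pos + L])
                hit = _targets.mfe_ratio_filter(hit, mirna_rna)
                if hit.passes:
                    g["seq"] = new_seq
                    sites.append((g["gene_id"], pos + L, w))
                    all_pairs.append((mat, g["gene_id"]))
                    planted = True
                    break
        if sites:
            truth.planted_targets[mat] = sites
    n_neg = int(round(cfg.negcorr_fraction * len(all_pairs)))
    neg_order = rng.permutation(len(all_pairs))
    negatives = [all_pairs[int(i)] for i in neg_order[:n_neg]]
    truth.planted_negative_pairs = sorted(negatives)

    # --- gene stage profiles ----------------------------------------------
    gene_mult = {g["gene_id"]: np.ones(3) for g in genes}
    neg_set = set(negatives)
    target_genes = set(g for _, g in all_pairs)
    for mat, gid in all_pairs:
        if (mat, gid) in neg_set:
            gene_mult[gid] = 1.0 / stage_mult[mat]
    spare = [g["gene_id"] for g in genes if g["gene_id"] not in target_genes]
    extra = rng.choice(len(spare), size=min(cfg.n_extra_degs, len(spare)), replace=False)
    for j in sorted(extra):
        gid = spare[int(j)]
        comp = COMPARISONS[int(rng.integers(0, 3))]
        f = 2.0 ** (float(rng.uniform(1.5, 3.0)) * (1 if rng.random() < 0.5 else -1))
        mult = np.ones(3)
        yi = {"PS": 0, "TS": 1, "SS": 2}[comp[1]]
        mult[yi:] = f
        gene_mult[gid] = mult

    # --- genome assembly ---------------------------------------------------
    parts: list[str] = []
    cursor = 0
    gff: list[str] = []
    repeats_bed: list[tuple[str, int, int]] = []
    chrom = "chr1"

    def gap():
        nonlocal cursor
        n = int(rng.integers(80, 201))
        parts.append(_rand_seq(rng, n))
        cursor += n

    repeat_unit = _rand_seq_clean(rng, 300, forbidden)
    hairpin_slots = set(np.linspace(0, cfg.n_genes - 1, cfg.n_novel_hairpins,
                                    dtype=int).tolist()) if cfg.n_novel_hairpins else set()
    repeat_slots = set(np.linspace(1, cfg.n_genes - 2, 4, dtype=int).tolist())
    for gi, g in enumerate(genes):
        gap()
        L = len(g["seq"])
        gseq = g["seq"] if g["strand"] == "+" else revcomp_dna(g["seq"])
        start1 = cursor + 1
        parts.append(gseq)
        # exon intervals in genome coordinates (1-based inclusive)
        e1, il, e2 = g["e1"], g["il"], g["e2"]
        local = [(0, e1), (e1 + il, L)]
        if g["strand"] == "-":
            local = [(L - b, L - a) for a, b in local][::-1]
        exons = [(cursor + a + 1, cursor + b) for a, b in local]
        gff.append(f"{chrom}\tmirwood_sim\tgene\t{start1}\t{cursor + L}\t.\t"
                   f"{g['strand']}\t.\tID={g['gene_id']}")
        for s, e in exons:
            gff.append(f"{chrom}\tmirwood_sim\texon\t{s}\t{e}\t.\t{g['strand']}\t.\t"
                       f"Parent={g['gene_id']}")
        g["exons_seq"] = [g["seq"][:e1], g["seq"][e1 + il:]]
        g["intron_seq"] = g["seq"][e1:e1 + il]
        cursor += L
        if gi in hairpin_slots:
            hp = novel[sorted(hairpin_slots).index(gi)]
            gap()
            pre_dna = back_transcribe(hp["precursor"])
            truth.planted_hairpins.append(dict(
                locus=[chrom, cursor + 1, cursor + len(pre_dna), "+"],
                precursor=hp["precursor"], mature=hp["mature"],
                star=hp["star"], arm=hp["arm"]))
            parts.append(pre_dna)
            cursor += len(pre_dna)
        if gi in repeat_slots:
            gap()
            repeats_bed.append((chrom, cursor, cursor + len(repeat_unit)))
            parts.append(repeat_unit)
            cursor += len(repeat_unit)
    gap()
    if cursor > cfg.genome_length:
        raise ValueError(f"genome_length {cfg.genome_length} too small; need >= {cursor}")
    parts.append(_rand_seq(rng, cfg.genome_length - cursor))
    genome = "".join(parts)

    # --- reference sets ----------------------------------------------------
    refs = {
        "rRNA": [(f"rRNA_{i + 1}", _rand_seq_clean(rng, 1200, forbidden)) for i in range(3)],
        "tRNA": [(f"tRNA_{i + 1}", _rand_seq_clean(rng, 75, forbidden)) for i in range(10)],
        "snRNA": [(f"snRNA_{i + 1}", _rand_seq_clean(rng, 150, forbidden)) for i in range(5)],
        "snoRNA": [(f"snoRNA_{i + 1}", _rand_seq_clean(rng, 120, forbidden)) for i in range(5)],
        "repeat_units": [repeat_unit],
    }

    # --- mRNA count matrix -------------------------------------------------
    import pandas as pd

    base_gene = rng.lognormal(0.0, 1.2, size=cfg.n_genes)
    gene_ids = [g["gene_id"] for g in genes]
    stage_of = {lib: lib[:-1] for lib in cfg.libraries}
    stage_idx = {s: i for i, s in enumerate(cfg.stages)}
    counts = {}
    phi = max(cfg.nb_dispersion, 1e-9)
    for lib in cfg.libraries:
        si = stage_idx[stage_of[lib]]
        w = base_gene * np.array([gene_mult[g][si] for g in gene_ids])
        mu = cfg.mrna_library_depth * w / w.sum()
        r = 1.0 / phi
        counts[lib] = rng.negative_binomial(r, r / (r + mu))
    mrna = pd.DataFrame(counts, index=gene_ids)

    # --- sRNA libraries ----------------------------------------------------
    pools = _Pools(rng, cfg, refs, genes)
    class_names = list(cfg.contaminant_mix) + ["miRNA"]
    class_probs = np.array([cfg.contaminant_mix[c] for c in cfg.contaminant_mix]
                           + [cfg.mirna_proportion])
    base_mirna = rng.lognormal(0.0, 1.0, size=len(all_matures))
    base_mirna = np.array([base_override.get(m, base_mirna[i])
                           for i, m in enumerate(all_matures)])
    fastq_paths = {}
    for lib in cfg.libraries:
        si = stage_idx[stage_of[lib]]
        class_counts = rng.multinomial(cfg.library_depth, class_probs)
        inserts: list[str] = []
        counts_per_insert: list[int] = []
        for cls, n_cls in zip(class_names, class_counts):
            if n_cls == 0:
                continue
            if cls == "miRNA":
                noise = rng.gamma(1.0 / phi, phi, size=len(all_matures))
                w = base_mirna * np.array([stage_mult[m][si] for m in all_matures]) * noise
                draw = rng.multinomial(n_cls, w / w.sum())
                for m, n in zip(all_matures, draw):
                    if n:
                        inserts.append(back_transcribe(m))
                        counts_per_insert.append(int(n))
            else:
                w = pools.weights[cls]
                draw = rng.multinomial(n_cls, w / w.sum())
                for s, n in zip(pools.inserts[cls], draw):
                    if n:
                        inserts.append(s)
                        counts_per_insert.append(int(n))
        # expand to per-read sequences with adapters
        rep = np.repeat(np.arange(len(inserts)), counts_per_insert)
        artifacts = []
        for _ in range(cfg.n_artifact_reads):
            artifacts.append(cfg.adapter_5p + cfg.adapter_3p)            # no insert
            artifacts.append(cfg.adapter_5p + _rand_seq(rng, 20))        # 5' only
            artifacts.append(_rand_seq_clean(rng, 25, forbidden))        # no adapter
            artifacts.append(cfg.adapter_3p)                             # 3' only
        n_reads = len(rep) + len(artifacts)
        order = rng.permutation(n_reads)
        n_lq = min(cfg.n_lowquality_reads, n_reads // 10)
        n_n = min(cfg.n_n_reads, n_reads // 10)
        lowq = set(int(x) for x in rng.choice(n_reads, n_lq, replace=False))
        nset_candidates = [i for i in range(n_reads) if i not in lowq]
        nsel = rng.choice(len(nset_candidates), n_n, replace=False)
        nset = set(nset_candidates[int(i)] for i in nsel)
        lines = []
        for serial, src in enumerate(order):
            src = int(src)
            if src < len(rep):
                seq = inserts[int(rep[src])] + cfg.adapter_3p
            else:
                seq = artifacts[src - len(rep)]
            qual = "I" * len(seq)
            if serial in lowq:
                p1, p2 = rng.choice(len(seq), 2, replace=False)
                q = list(qual)
                q[int(p1)] = q[int(p2)] = "#"
                qual = "".join(q)
            elif serial in nset:
                p = int(rng.integers(0, len(seq)))
                seq = seq[:p] + "N" + seq[p + 1:]
            lines.append(f"@{lib}_{serial + 1}\n{seq}\n+\n{qual}\n")
        path = out / f"srna_{lib}.fastq.gz"
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0, compresslevel=1) as gz:
                gz.write("".join(lines).encode())
        fastq_paths[lib] = path

    # --- write reference + expression files --------------------------------
    def write_fasta(path, records):
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")

    paths = dict(fastq_paths)
    paths["genome"] = out / "genome.fa"
    write_fasta(paths["genome"], [(chrom, genome)])
    for cls in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        paths[cls] = out / f"{cls}.fa"
        write_fasta(paths[cls], refs[cls])
    paths["repeats"] = out / "repeats.bed"
    paths["repeats"].write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in repeats_bed))
    paths["gff"] = out / "genes.gff3"
    (out / "genes.gff3").write_text("##gff-version 3\n" + "\n".join(gff) + "\n")
    paths["mature"] = out / "mature.fa"
    write_fasta(paths["mature"], [(c["name"], c["mature"]) for c in catalogue])
    paths["hairpin"] = out / "hairpin.fa"
    write_fasta(paths["hairpin"], [(c["hairpin_id"], c["precursor"]) for c in catalogue])
    paths["transcripts"] = out / "transcripts.fa"
    write_fasta(paths["transcripts"],
                [(g["gene_id"], g["exons_seq"][0] + g["exons_seq"][1]) for g in genes])
    paths["mrna_counts"] = out / "mrna_counts.tsv"
    mrna.to_csv(paths["mrna_counts"], sep="\t", index_label="gene_id")
    # annotation map: shared term for planted targets + random terms
    ann_lines = ["gene_id\tterm_id\tterm_name\tnamespace"]
    terms = [f"GO:{7000000 + t}" for t in range(40)]
    for g in genes:
        gid = g["gene_id"]
        if gid in target_genes:
            ann_lines.append(f"{gid}\tGO:0099000\twood formation\tBP")
        for t in rng.choice(40, int(rng.integers(1, 4)), replace=False):
            ann_lines.append(f"{gid}\t{terms[int(t)]}\tterm_{int(t)}\tBP")
    paths["annotation"] = out / "annotation.tsv"
    paths["annotation"].write_text("\n".join(ann_lines) + "\n")
    paths["truth"] = out / "truth.json"
    truth.to_json(paths["truth"])
    (out / "config.json").write_text(json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        indent=1, sort_keys=True))
    paths["config"] = out / "config.json"
    return paths, truth
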