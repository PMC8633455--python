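"""miRNA target-site prediction by weighted-mismatch duplex rules.

A candidate site is an ungapped antiparallel window of the transcript, equal
in length to the miRNA.  Each miRNA position is classified against the
opposite site base: Watson-Crick pair = 0, G:U wobble = 0.5, anything else a
full mismatch = 1.  Positions are numbered from the miRNA 5' end.  A site
passes when all of the following hold:

1. total weighted mismatches <= 4;
2. no run of more than two adjacent mismatch positions (a G:U counts as a
   mismatch event for adjacency even though it weighs 0.5);
3. no two adjacent full mismatches within positions 2-12;
4. no mismatch at positions 10-11 (strictly: G:U there also rejects;
   toggleable);
5. at most 2.5 weighted mismatches over positions 1-12;
6. duplex MFE at least 74% of the MFE of the miRNA bound to its perfect
   complement (the MFE-ratio criterion, applied on magnitudes).

Rules 1-5 are purely combinatorial; rule 6 uses the package energy model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import structure
from ._seq import encode, transcribe

# per-position weight lookup, indexed [mirna_base, site_base] (A,C,G,U)
_WEIGHT = np.ones((4, 4), dtype=np.float64)
_WEIGHT[0, 3] = 0.0  # A:U
_WEIGHT[3, 0] = 0.0  # U:A
_WEIGHT[2, 1] = 0.0  # G:C
_WEIGHT[1, 2] = 0.0  # C:G
_WEIGHT[2, 3] = 0.5  # G:U wobble
_WEIGHT[3, 2] = 0.5  # U:G wobble


@dataclass(frozen=True)
class RuleConfig:
    """Interpretation toggles for the positional rules."""

    max_total: float = 4.0
    max_adjacent_run: int = 2          # rule 2: longest allowed mismatch-event run
    adjacency_counts_gu: bool = True   # rule 2 counts G:U as a mismatch event
    rule3_full_only: bool = True       # rule 3 looks at adjacent *full* mismatches
    rule4_strict_gu: bool = True       # rule 4: G:U at positions 10-11 rejects
    max_seed_total: float = 2.5        # rule 5 cap over positions 1-12
    mfe_ratio_min: float = 0.74        # rule 6 threshold


DEFAULT_RULES = RuleConfig()


@dataclass
class DuplexHit:
    """One candidate miRNA/transcript site with its rule evaluation."""

    mirna: str
    transcript: str
    site_start: int            # 1-based transcript coordinate opposite miRNA position 1
    site_seq: str              # transcript window, 5'->3'
    mismatch_vector: tuple[float, ...]   # per miRNA position (5'->3')
    total_weighted: float
    rule_pass: dict[str, bool] = field(default_factory=dict)
    passes_rules: bool = False
    mfe_site: float = float("nan")
    mfe_perfect: float = float("nan")
    mfe_ratio: float = float("nan")
    passes_mfe: bool = False

    @property
    def passes(self) -> bool:
        return self.passes_rules and self.passes_mfe


def mismatch_vector(mirna: str, site: str) -> tuple[float, ...]:
    """Per-position weights for an ungapped antiparallel duplex.

    ``site`` is the transcript window 5'->3'; miRNA position k (1-based from
    its 5' end) faces site position ``len - k + 1``.
    """
    if len(mirna) != len(site):
        raise ValueError("miRNA and site must have equal length")
    m = encode(transcribe(mirna.upper()))
    s = encode(transcribe(site.upper()))[::-1]
    return tuple(float(x) for x in _WEIGHT[m, s])


def _evaluate_rules(vec: np.ndarray, rules: RuleConfig) -> dict[str, bool]:
    events = vec >= (0.5 if rules.adjacency_counts_gu else 1.0)
    full = vec >= 1.0
    run = longest = 0
    for e in events:
        run = run + 1 if e else 0
        longest = max(longest, run)
    seed = vec[:12]
    seed_full = full[1:12]  # positions 2..12 (0-based 1..11)
    rule3_events = seed_full if rules.rule3_full_only else events[1:12]
    rule4_bad = full[9:11] if not rules.rule4_strict_gu else (vec[9:11] > 0)
    return {
        "rule1_total": float(vec.sum()) <= rules.max_total + 1e-9,
        "rule2_adjacent": longest <= rules.max_adjacent_run,
        "rule3_seed_adjacent": not any(rule3_events[k] and rule3_events[k + 1]
                                       for k in range(len(rule3_events) - 1)),
        "rule4_cleavage": not rule4_bad.any(),
        "rule5_seed_total": float(seed.sum()) <= rules.max_seed_total + 1e-9,
    }


def score_duplex(mirna: str, site: str, rules: RuleConfig = DEFAULT_RULES,
                 mirna_id: str = "", transcript_id: str = "",
                 site_start: int = 0) -> DuplexHit:
    """Classify every position of an equal-length miRNA/site duplex and apply rules 1-5."""
    if not 18 <= len(mirna) <= 25:
        raise ValueError(f"miRNA length must be 18-25 nt, got {len(mirna)}")
    vec = np.array(mismatch_vector(mirna, site))
    rule_pass = _evaluate_rules(vec, rules)
    return DuplexHit(
        mirna=mirna_id, transcript=transcript_id, site_start=site_start,
        site_seq=transcribe(site.upper()),
        mismatch_vector=tuple(float(x) for x in vec),
        total_weighted=float(vec.sum()),
        rule_pass=rule_pass,
        passes_rules=all(rule_pass.values()),
    )


def mfe_ratio_filter(hit: DuplexHit, mirna_seq: str,
                     rules: RuleConfig = DEFAULT_RULES,
                     model: structure.EnergyModel = structure.DEFAULT_MODEL,
                     mfe_perfect: float | None = None) -> DuplexHit:
    """Attach duplex energies and decide the MFE-ratio criterion (rule 6).

    ratio = |MFE(miRNA, site)| / |MFE(miRNA, perfect complement)|; pass iff
    ratio >= threshold.  A miRNA whose perfect duplex has zero energy cannot
    be assessed and the site is rejected.
    """
    mirna_rna = transcribe(mirna_seq.upper())
    if mfe_perfect is None:
        mfe_perfect = structure.perfect_duplex_mfe(mirna_rna, model)
    if mfe_perfect >= 0.0:
        return replace(hit, mfe_perfect=mfe_perfect, passes_mfe=False)
    mfe_site = structure.duplex_mfe(mirna_rna, hit.site_seq, model).mfe
    ratio = abs(mfe_site) / abs(mfe_perfect)
    return replace(hit, mfe_site=mfe_site, mfe_perfect=mfe_perfect,
                   mfe_ratio=ratio, passes_mfe=ratio >= rules.mfe_ratio_min - 1e-12)


def _rules_mask(vals: np.ndarray, rules: RuleConfig) -> np.ndarray:
    """Boolean mask of rule-1-5-passing rows of a (n_windows, L) weight array."""
    L = vals.shape[1]
    events = vals >= (0.5 if rules.adjacency_counts_gu else 1.0)
    full = vals >= 1.0
    ok = vals.sum(axis=1) <= rules.max_total + 1e-9
    r = rules.max_adjacent_run
    for k in range(L - r):
        ok &= ~events[:, k:k + r + 1].all(axis=1)
    r3 = full if rules.rule3_full_only else events
    ok &= ~(r3[:, 1:11] & r3[:, 2:12]).any(axis=1)
    if rules.rule4_strict_gu:
        ok &= (vals[:, 9:11] == 0).all(axis=1)
    else:
        ok &= ~full[:, 9:11].any(axis=1)
    ok &= vals[:, :12].sum(axis=1) <= rules.max_seed_total + 1e-9
    return ok


_SENTINEL = 4
_WEIGHT5 = np.full((5, 5), 99.0)
_WEIGHT5[:4, :4] = _WEIGHT
_LUT5 = np.full(256, _SENTINEL, dtype=np.int8)
for _b, _v in (("A", 0), ("C", 1), ("G", 2), ("U", 3), ("T", 3)):
    _LUT5[ord(_b)] = _v


def _encode5(seq: str) -> np.ndarray:
    """Encode with a sentinel code for non-ACGU characters (separators)."""
    return _LUT5[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _scan_one(mirna_rna: str, tseq: str, rules: RuleConfig) -> np.ndarray:
    """Indices of rule-1-5-passing windows of ``tseq`` (vectorised)."""
    L = len(mirna_rna)
    t = _encode5(transcribe(tseq.upper()))
    if len(t) < L:
        return np.empty(0, dtype=np.int64)
    m = encode(mirna_rna)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
    vals = _WEIGHT5[m[None, :], windows]           # (n_windows, L)
    return np.nonzero(_rules_mask(vals, rules))[0]


def scan_transcriptome(mirnas, transcripts: dict[str, str],
                       rules: RuleConfig = DEFAULT_RULES,
                       model: structure.EnergyModel = structure.DEFAULT_MODEL,
                       ) -> list[DuplexHit]:
    """Score every sense-strand window of every transcript for every miRNA.

    ``mirnas`` maps miRNA id -> mature sequence (RNA or DNA).  Hits passing
    rules 1-6 are returned, deduplicated per (miRNA, transcript) keeping the
    best site (lowest weighted total, then highest MFE ratio, then smallest
    coordinate).
    """
    if isinstance(mirnas, dict):
        items = sorted(mirnas.items())
    else:
        items = sorted((rec.name, rec.mature_seq) for rec in mirnas)
    tids = sorted(transcripts)
    # concatenate all transcripts with sentinel separators: one vectorised
    # scan per miRNA instead of one per (miRNA, transcript)
    cat = _encode5("#".join(transcribe(transcripts[t].upper()) for t in tids))
    starts = np.cumsum([0] + [len(transcripts[t]) + 1 for t in tids[:-1]])
    hits: list[DuplexHit] = []
    for mid, mseq in items:
        mirna_rna = transcribe(mseq.upper())
        L = len(mirna_rna)
        if len(cat) < L:
            continue
        mfe_perfect = structure.perfect_duplex_mfe(mirna_rna, model)
        m = encode(mirna_rna)
        windows = np.lib.stride_tricks.sliding_window_view(cat, L)[:, ::-1]
        vals = _WEIGHT5[m[None, :], windows]
        best_per_t: dict[str, DuplexHit] = {}
        for gidx in np.nonzero(_rules_mask(vals, rules))[0]:
            ti = int(np.searchsorted(starts, gidx, side="right")) - 1
            tid = tids[ti]
            w0 = int(gidx - starts[ti])
            site = transcripts[tid][w0:w0 + L]
            hit = score_duplex(mirna_rna, site, rules, mirna_id=mid,
                               transcript_id=tid, site_start=w0 + L)
            hit = mfe_ratio_filter(hit, mirna_rna, rules, model, mfe_perfect)
            if not hit.passes_mfe:
                continue
            best = best_per_t.get(tid)
            if best is None or (hit.total_weighted, -hit.mfe_ratio, hit.site_start) < \
                    (best.total_weighted, -best.mfe_ratio, best.site_start):
                best_per_t[tid] = hit
        hits.extend(best_per_t[t] for t in sorted(best_per_t))
    return hits


def hits_table(hits: list[DuplexHit]):
    """Hits as a tidy DataFrame (one row per site)."""
    import pandas as pd

    rows = []
    for h in hits:
        row = {"mirna": h.mirna, "transcript": h.transcript,
               "site_start": h.site_start, "site_seq": h.site_seq,
               "total_weighted": h.total_weighted, "mfe_site": h.mfe_site,
               "mfe_perfect": h.mfe_perfect, "mfe_ratio": h.mfe_ratio}
        row.update(h.rule_pass)
        row["passes"] = h.passes
        rows.append(row)
    return pd.DataFrame(rows)
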