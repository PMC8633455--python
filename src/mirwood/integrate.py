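"""DE-miRNA / candidate-target-gene (CTG) correlation integration.

Pairs are formed per stage comparison: a miRNA called DE, a gene that carries
a rule-passing target site for it, and the gene itself called DE in the same
comparison.  Each pair's expression profiles (miRNA TPM, gene FPKM, both
log2(x+1)-transformed) are correlated across the six replicate libraries of
the two compared stages; a pair is *negative* when -1 < r < -0.8 with
p <= 0.05, *positive* (mirrored convention) when r > 0.8 with p <= 0.05, and
unclassified otherwise.  The negative class is the operational signature of
miRNA-mediated repression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationConfig:
    r_negative: float = -0.8      # strict: -1 < r < r_negative
    r_positive: float = 0.8       # strict: r > r_positive
    p_max: float = 0.05
    log_transform: bool = True


DEFAULT_CORRELATION = CorrelationConfig()


def build_pairs(de_mirnas: pd.DataFrame, hits, degs: pd.DataFrame,
                ) -> list[tuple[str, str]]:
    """Unique (miRNA, gene) pairs: DE miRNA, target hit, gene DE in same comparison."""
    comps = set(de_mirnas["comparison"]) | set(degs["comparison"])
    if len(comps) > 1:
        raise ValueError(f"inputs mix comparisons: {sorted(comps)}")
    de_m = set(de_mirnas.index[de_mirnas["called"]])
    de_g = set(degs.index[degs["called"]])
    pairs = set()
    for h in hits:
        mid = h.mirna if hasattr(h, "mirna") else h[0]
        gid = h.transcript if hasattr(h, "transcript") else h[1]
        if mid in de_m and gid in de_g:
            pairs.add((mid, gid))
    return sorted(pairs)


def correlate_pair(mirna_profile, ctg_profile) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t transform, n-2 df).

    Returns (nan, nan) when either profile has zero variance.
    """
    x = np.asarray(mirna_profile, dtype=float)
    y = np.asarray(ctg_profile, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("profiles must share >= 3 libraries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _classify(r: float, p: float, cfg: CorrelationConfig) -> str:
    if np.isnan(r) or p > cfg.p_max:
        return "none"
    if cfg.r_negative > r > -1.0:
        return "negative"
    if r > cfg.r_positive:
        return "positive"
    return "none"


def classify_pairs(pairs: list[tuple[str, str]], mirna_tpm: pd.DataFrame,
                   gene_fpkm: pd.DataFrame, libraries: list[str],
                   comparison: str = "",
                   cfg: CorrelationConfig = DEFAULT_CORRELATION,
                   ) -> tuple[pd.DataFrame, dict]:
    """Correlate and classify each pair; returns (records, summary).

    ``libraries`` are the replicate libraries of the two compared stages
    (normally six).  Profiles are log2(x+1)-transformed by default.
    """
    rows = []
    for mid, gid in sorted(set(pairs)):
        x = mirna_tpm.loc[mid, libraries].to_numpy(dtype=float)
        y = gene_fpkm.loc[gid, libraries].to_numpy(dtype=float)
        if cfg.log_transform:
            x = np.log2(x + 1.0)
            y = np.log2(y + 1.0)
        r, p = correlate_pair(x, y)
        rows.append({"mirna": mid, "ctg": gid, "comparison": comparison,
                     "r": r, "p": p, "cls": _classify(r, p, cfg)})
    records = pd.DataFrame(rows, columns=["mirna", "ctg", "comparison", "r", "p", "cls"])
    neg = records[records["cls"] == "negative"]
    summary = {
        "comparison": comparison,
        "n_pairs": len(records),
        "n_negative": int((records["cls"] == "negative").sum()),
        "n_positive": int((records["cls"] == "positive").sum()),
        "n_none": int((records["cls"] == "none").sum()),
        "n_unique_mirnas": records["mirna"].nunique(),
        "n_unique_ctgs": records["ctg"].nunique(),
        "negative_r_min": float(neg["r"].min()) if len(neg) else float("nan"),
        "negative_r_max": float(neg["r"].max()) if len(neg) else float("nan"),
    }
    return records, summary


def dedupe_network(records: pd.DataFrame) -> dict:
    """Unique DE-miRNAs and CTGs among negative pairs, plus the edge list."""
    neg = records[records["cls"] == "negative"]
    edges = neg[["mirna", "ctg"]].drop_duplicates().sort_values(["mirna", "ctg"])
    edges = edges.assign(sign="negative")
    return {
        "n_unique_mirnas": neg["mirna"].nunique(),
        "n_unique_ctgs": neg["ctg"].nunique(),
        "edges": edges.reset_index(drop=True),
    }
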