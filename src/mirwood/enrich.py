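"""Hypergeometric term enrichment with Benjamini-Hochberg control.

For a study gene set drawn from a population of N genes, a term annotating K
population genes and k study genes has upper-tail probability
P[X >= k] under Hypergeometric(N, K, n).  Terms with fewer than two
population genes are untestable and skipped; BH adjustment is applied within
each annotation namespace separately; significance is FDR <= 0.05.  The rich
factor k/K is reported for plotting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

log = logging.getLogger(__name__)

FDR_MAX = 0.05
MIN_TERM_SIZE = 2


def enrich(study: set[str], population: set[str], annotation: pd.DataFrame,
           fdr_max: float = FDR_MAX) -> pd.DataFrame:
    """Term enrichment of ``study`` against ``population``.

    ``annotation`` needs columns gene_id, term_id, term_name (namespace
    optional; defaults to a single namespace).
    """
    study = set(study)
    population = set(population)
    stray = study - population
    if stray:
        raise ValueError(f"study genes outside the population: {sorted(stray)[:10]}")
    ann = annotation[annotation["gene_id"].isin(population)].copy()
    if "namespace" not in ann.columns:
        ann["namespace"] = "default"
    if not (set(ann["gene_id"]) & study):
        raise ValueError("annotation covers no study gene")
    N, n = len(population), len(study)
    rows = []
    for (term, name, ns), sub in ann.groupby(["term_id", "term_name", "namespace"],
                                             sort=True):
        genes = set(sub["gene_id"])
        K = len(genes)
        if K < MIN_TERM_SIZE:
            log.debug("skipping untestable term %s (K=%d)", term, K)
            continue
        k = len(genes & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "term_name": name, "namespace": ns,
                     "k": k, "K": K, "n": n, "N": N, "p": p,
                     "rich_factor": k / K})
    res = pd.DataFrame(rows)
    if res.empty:
        res["fdr"] = res.get("p", pd.Series(dtype=float))
        res["significant"] = pd.Series(dtype=bool)
        return res
    res["fdr"] = np.nan
    for ns, idx in res.groupby("namespace").groups.items():
        res.loc[idx, "fdr"] = bh_adjust(res.loc[idx, "p"])
    res["significant"] = res["fdr"] <= fdr_max
    return res.sort_values(["fdr", "p", "term_id"]).reset_index(drop=True)


def rich_factor_plot_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table of significant terms: (term, rich_factor, k, fdr)."""
    if results.empty:
        return pd.DataFrame(columns=["term_id", "term_name", "rich_factor", "k", "fdr"])
    sig = results[results["significant"]]
    return (sig[["term_id", "term_name", "rich_factor", "k", "fdr"]]
            .sort_values("fdr").reset_index(drop=True))
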