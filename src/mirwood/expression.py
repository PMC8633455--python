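"""Expression normalisation, differential-expression calling and qPCR helpers.

miRNA abundances are normalised to transcripts-per-million of clean reads
(TPM = count / library clean-read total x 1e6); gene abundances to FPKM
(count / (length/1e3) / (mapped/1e6)).  Differential expression between two
developmental stages (three replicate libraries each) is decided by an exact
negative-binomial test conditioned on the two group sums, with fold changes
taken on mean normalised abundances with a pseudocount.  miRNAs are called at
|log2FC| >= 1 and raw p <= 0.05; genes at |log2FC| >= 1 and
Benjamini-Hochberg FDR <= 0.05 — the two feature classes deliberately use
different error controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Raw counts (features x libraries) plus the metadata normalisation needs."""

    counts: pd.DataFrame
    library_totals: pd.Series | None = None   # defaults to column sums
    feature_lengths: pd.Series | None = None  # nt; genes only

    def totals(self) -> pd.Series:
        if self.library_totals is not None:
            return self.library_totals.reindex(self.counts.columns)
        return self.counts.sum(axis=0)


def tpm_normalize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """count / library total x 1e6.  Totals default to column sums, in which
    case every normalised library sums to exactly 1e6; the pipeline passes
    per-library clean-read totals instead."""
    totals = matrix.totals().astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total libraries: {list(zero.index)}")
    return matrix.counts.div(totals, axis=1) * 1e6


def fpkm_normalize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """count / (length/1e3) / (mapped total/1e6)."""
    if matrix.feature_lengths is None:
        raise ValueError("feature lengths required for FPKM")
    lengths = matrix.feature_lengths.reindex(matrix.counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:5])
        raise ValueError(f"missing lengths for features: {missing}")
    totals = matrix.totals().astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total libraries: {list(zero.index)}")
    per_kb = matrix.counts.div(lengths / 1e3, axis=0)
    return per_kb.div(totals / 1e6, axis=1)


def nb_exact_test(counts_a, counts_b, dispersion: float,
                  lib_sizes_a=None, lib_sizes_b=None) -> float:
    """Two-sided exact test for a difference in mean count between two groups.

    Conditions on the total of the two group sums: under the null the group-A
    sum follows the conditional distribution of one negative-binomial sum
    given the total (binomial when dispersion is 0).  The two-sided p-value
    doubles the smaller tail, capped at 1.  Unequal library sizes are
    handled by scaling counts to the mean library size before summing.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one replicate")
    if lib_sizes_a is not None and lib_sizes_b is not None:
        libs = np.concatenate([np.asarray(lib_sizes_a, float),
                               np.asarray(lib_sizes_b, float)])
        ref = libs.mean()
        a = np.round(a * ref / np.asarray(lib_sizes_a, float))
        b = np.round(b * ref / np.asarray(lib_sizes_b, float))
    sa, sb = a.sum(), b.sum()
    total = int(round(sa + sb))
    if total == 0:
        return 1.0
    na, nb = a.size, b.size
    obs = int(round(sa))
    frac = na / (na + nb)
    if dispersion < 1e-12:
        # conditional law of the group-A sum is Binomial(total, na/(na+nb))
        sd = np.sqrt(max(total * frac * (1 - frac), 1.0))
        lo = max(0, min(obs, int(total * frac - 16 * sd)))
        hi = min(total, max(obs, int(total * frac + 16 * sd) + 1))
        s = np.arange(lo, hi + 1)
        logp = stats.binom.logpmf(s, total, frac)
    else:
        # two NB sums with a common success probability: the conditional law
        # given the total is exactly BetaBinomial(total, na/phi, nb/phi)
        alpha, beta = na / dispersion, nb / dispersion
        ab = alpha + beta
        var = total * alpha * beta * (ab + total) / (ab * ab * (ab + 1.0))
        sd = np.sqrt(max(var, 1.0))
        mean = total * frac
        lo = max(0, min(obs, int(mean - 16 * sd)))
        hi = min(total, max(obs, int(mean + 16 * sd) + 1))
        s = np.arange(lo, hi + 1)
        logp = (gammaln(s + alpha) - gammaln(s + 1.0)
                + gammaln(total - s + beta) - gammaln(total - s + 1.0))
        logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    lower = p[: obs - lo + 1].sum()
    upper = p[obs - lo:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def estimate_common_dispersion(counts: pd.DataFrame, groups: dict[str, str]) -> float:
    """Method-of-moments common dispersion across features.

    For each feature, pooled within-group variance v and mean m give
    phi = (v - m) / m^2; the common value is the median over features with
    positive mean, floored at 1e-6.
    """
    labels = pd.Series(groups).reindex(counts.columns)
    phis = []
    for _, sub in counts.T.groupby(labels):
        if len(sub) < 2:
            continue
        m = sub.mean(axis=0)
        v = sub.var(axis=0, ddof=1)
        ok = m > 0
        phis.append(((v[ok] - m[ok]) / m[ok] ** 2))
    if not phis:
        return 1e-6
    pooled = pd.concat(phis)
    if not len(pooled):
        return 1e-6
    return float(max(1e-6, np.median(pooled)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEOptions:
    lfc_min: float = 1.0
    p_max: float = 0.05
    fdr_max: float = 0.05
    pseudocount: float = 0.5


def _de_table(raw: pd.DataFrame, norm: pd.DataFrame, comparison: tuple[str, str],
              groups: dict[str, str], dispersion: float | None,
              lib_sizes: pd.Series | None, opts: DEOptions,
              use_fdr: bool) -> pd.DataFrame:
    earlier, later = comparison
    stages = set(groups.values())
    for st in comparison:
        if st not in stages:
            raise ValueError(f"unknown stage label {st!r}")
    libs_a = [l for l in raw.columns if groups[l] == earlier]
    libs_b = [l for l in raw.columns if groups[l] == later]
    if dispersion is None:
        dispersion = estimate_common_dispersion(raw[libs_a + libs_b],
                                                {l: groups[l] for l in libs_a + libs_b})
    mean_a = norm[libs_a].mean(axis=1)
    mean_b = norm[libs_b].mean(axis=1)
    c = opts.pseudocount
    lfc = np.log2((mean_b + c) / (mean_a + c))
    la = lib_sizes[libs_a].to_numpy() if lib_sizes is not None else None
    lb = lib_sizes[libs_b].to_numpy() if lib_sizes is not None else None
    pvals = np.array([
        nb_exact_test(raw.loc[f, libs_a].to_numpy(), raw.loc[f, libs_b].to_numpy(),
                      dispersion, la, lb)
        for f in raw.index
    ])
    fdr = bh_adjust(pvals)
    sig = fdr <= opts.fdr_max if use_fdr else pvals <= opts.p_max
    called = (np.abs(lfc) >= opts.lfc_min) & sig
    return pd.DataFrame({
        "feature": raw.index,
        "comparison": f"{earlier}_vs_{later}",
        "log2fc": lfc.to_numpy(),
        "p": pvals,
        "fdr": fdr,
        "called": called,
        "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
    }).set_index("feature")


def call_de_mirnas(matrix: ExpressionMatrix, comparison: tuple[str, str],
                   groups: dict[str, str], dispersion: float | None = None,
                   opts: DEOptions = DEOptions()) -> pd.DataFrame:
    """DE miRNAs: log2FC on mean TPM (pseudocount 0.5), raw p <= 0.05 and |log2FC| >= 1."""
    tpm = tpm_normalize(matrix)
    return _de_table(matrix.counts, tpm, comparison, groups, dispersion,
                     matrix.totals(), opts, use_fdr=False)


def call_degs(matrix: ExpressionMatrix, comparison: tuple[str, str],
              groups: dict[str, str], dispersion: float | None = None,
              opts: DEOptions = DEOptions()) -> pd.DataFrame:
    """DE genes: log2FC on mean FPKM (pseudocount 0.5), BH FDR <= 0.05 and |log2FC| >= 1."""
    fpkm = fpkm_normalize(matrix)
    return _de_table(matrix.counts, fpkm, comparison, groups, dispersion,
                     matrix.totals(), opts, use_fdr=True)


@dataclass
class CtTable:
    """Long-format qPCR Ct values: one row per (sample, assay, replicate)."""

    data: pd.DataFrame                 # columns: sample, assay, replicate, ct
    reference_assay: str               # e.g. 5.8S rRNA for miRNAs, beta-actin for genes
    calibrator_sample: str

    def __post_init__(self):
        need = {"sample", "assay", "replicate", "ct"}
        if not need <= set(self.data.columns):
            raise ValueError(f"CtTable needs columns {sorted(need)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")


def delta_delta_ct(ct: CtTable) -> pd.DataFrame:
    """Relative expression 2^-ddCt per (sample, assay), mean +/- SE over replicates.

    dCt = Ct_target - Ct_reference within each (sample, replicate); ddCt is
    taken against the calibrator sample's mean dCt, so the calibrator's point
    estimate is exactly 1.  SE comes from the per-replicate fold changes.
    """
    df = ct.data
    ref = df[df["assay"] == ct.reference_assay].set_index(["sample", "replicate"])["ct"]
    targets = df[df["assay"] != ct.reference_assay]
    rows = []
    for (sample, assay), sub in targets.groupby(["sample", "assay"], sort=True):
        idx = list(zip(sub["sample"], sub["replicate"]))
        missing = [i for i in idx if i not in ref.index]
        if missing:
            raise ValueError(f"missing reference Ct for {missing}")
        dct = sub["ct"].to_numpy() - ref.loc[idx].to_numpy()
        cal = targets[(targets["sample"] == ct.calibrator_sample)
                      & (targets["assay"] == assay)]
        if cal.empty:
            raise ValueError(f"calibrator sample has no Ct for assay {assay!r}")
        cal_idx = list(zip(cal["sample"], cal["replicate"]))
        cal_dct = cal["ct"].to_numpy() - ref.loc[cal_idx].to_numpy()
        ddct_point = dct.mean() - cal_dct.mean()
        fold_reps = 2.0 ** -(dct - cal_dct.mean())
        se = fold_reps.std(ddof=1) / np.sqrt(len(fold_reps)) if len(fold_reps) > 1 else 0.0
        rows.append({"sample": sample, "assay": assay,
                     "relative_expression": 2.0 ** -ddct_point,
                     "se": se, "n": len(fold_reps)})
    return pd.DataFrame(rows)
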