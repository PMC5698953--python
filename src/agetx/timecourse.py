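"""Normalization, expression filtering, and polynomial time-course DE.

Counts are normalized to CPM (and RPKM given gene lengths), genes are kept
when they exceed 1 CPM in at least three samples (strict inequality), and
age-regulated genes are called by ordinary least squares of log2(CPM + 1)
on a quadratic in age: an F-test of the full quadratic against the
intercept-only model, with Benjamini-Hochberg FDR control across genes.
A pooled Fisher's exact test provides pairwise differential expression for
low-count features such as circRNA junction counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountMatrix
from .motifs import bh_adjust


def cpm_normalize(counts: pd.DataFrame, lib_sizes=None) -> pd.DataFrame:
    """Counts per million. ``lib_sizes`` defaults to column sums."""
    if isinstance(counts, CountMatrix):
        lib_sizes = counts.lib_sizes if lib_sizes is None else lib_sizes
        counts = counts.counts
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * (1e6 / lib_sizes)


def filter_expressed(
    counts, lib_sizes=None, min_cpm: float = 1.0, min_samples: int = 3
) -> pd.Index:
    """Genes with CPM strictly above ``min_cpm`` in >= ``min_samples``
    samples."""
    cpm = cpm_normalize(counts, lib_sizes)
    if min_samples > cpm.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return cpm.index[keep]


def rpkm(counts, gene_lengths, lib_sizes=None) -> pd.DataFrame:
    """Reads per kilobase per million: CPM * 1e3 / length (nt)."""
    cpm = cpm_normalize(counts, lib_sizes)
    lengths = pd.Series(gene_lengths).reindex(cpm.index).astype(float)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("gene lengths must be positive and cover all genes")
    return cpm.mul(1e3 / lengths, axis=0)


def mean_rpkm(counts, gene_lengths, lib_sizes=None) -> pd.Series:
    """Mean RPKM across all samples, per gene."""
    return rpkm(counts, gene_lengths, lib_sizes).mean(axis=1)


def fit_timecourse(cm: CountMatrix, degree: int = 2) -> pd.DataFrame:
    """Quadratic (or chosen-degree) polynomial regression of expression on age.

    Fits log2(CPM + 1) ~ 1 + age + ... + age^degree per gene by OLS and
    tests the full model against the intercept-only model with an F-test on
    (degree, n - degree - 1) degrees of freedom. Returns coefficients
    a0..a_degree, F, p, and r2 per gene.
    """
    ages = cm.design["age"].to_numpy(dtype=float)
    if len(np.unique(ages)) < degree + 1:
        raise ValueError("need more distinct ages than the polynomial degree")
    n = len(ages)
    if n < degree + 2:
        raise ValueError("need at least degree + 2 observations")
    y = np.log2(cpm_normalize(cm).to_numpy() + 1.0)
    X = np.vander(ages, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = (X @ beta).T
    rss1 = ((y - fitted) ** 2).sum(axis=1)
    rss0 = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df1, df2 = degree, n - degree - 1
    tol = 1e-10 * np.maximum((y**2).sum(axis=1), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
        r2 = np.where(rss0 > tol, 1.0 - rss1 / rss0, 1.0)
    F = np.where(np.isfinite(F), F, np.where(rss0 > rss1, np.inf, 0.0))
    # a constant response carries no trend information
    F = np.where(rss0 <= tol, 0.0, np.maximum(F, 0.0))
    p = stats.f.sf(F, df1, df2)
    p = np.where(F == 0, 1.0, p)
    out = pd.DataFrame(
        beta.T,
        index=cm.counts.index,
        columns=[f"a{i}" for i in range(degree + 1)],
    )
    out["F"] = F
    out["p"] = p
    out["r2"] = np.clip(r2, 0.0, 1.0)
    return out


def call_age_regulated(
    results: pd.DataFrame, fdr: float = 0.05, age_lo: float = 10.0,
    age_hi: float = 40.0
) -> pd.DataFrame:
    """BH-adjust the per-gene p-values and call genes with q < fdr.

    Direction is the sign of the fitted change between the first and last
    age: up if f(age_hi) > f(age_lo).
    """
    if results.empty:
        raise ValueError("no fitted genes")
    out = results.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["called"] = out["q"] < fdr
    coef_cols = [c for c in out.columns if c.startswith("a") and c[1:].isdigit()]
    beta = out[coef_cols].to_numpy()
    powers = np.arange(beta.shape[1])
    delta = (beta * age_hi**powers).sum(axis=1) - (beta * age_lo**powers).sum(axis=1)
    out["direction"] = np.where(delta > 0, "up", "down")
    out.loc[delta == 0, "direction"] = "tie"
    return out


def pairwise_exact_de(
    counts: pd.DataFrame,
    lib_sizes: pd.Series,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    min_fc: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Pairwise DE by Fisher's exact test on pooled counts.

    For each gene, the 2x2 table is (gene counts, remaining counts) pooled
    within each group; fold change is the ratio of group mean CPM with a
    pseudocount. A gene is called when p <= alpha and the fold change is at
    least ``min_fc`` in either direction.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    lib_sizes = pd.Series(lib_sizes)
    tot_a = float(lib_sizes[group_a].sum())
    tot_b = float(lib_sizes[group_b].sum())
    ka = counts[group_a].sum(axis=1).to_numpy()
    kb = counts[group_b].sum(axis=1).to_numpy()
    pvals = np.array(
        [
            stats.fisher_exact(
                [[a, int(tot_a) - a], [b, int(tot_b) - b]]
            ).pvalue
            for a, b in zip(ka, kb)
        ]
    )
    cpm = cpm_normalize(counts, lib_sizes)
    mean_a = cpm[group_a].mean(axis=1).to_numpy()
    mean_b = cpm[group_b].mean(axis=1).to_numpy()
    fc = (mean_b + pseudocount) / (mean_a + pseudocount)
    log2fc = np.log2(fc)
    call = (pvals <= alpha) & (np.maximum(fc, 1 / fc) >= min_fc)
    return pd.DataFrame(
        {
            "p": pvals,
            "fold_change": fc,
            "log2_fc": log2fc,
            "call": call,
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=counts.index,
    )
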