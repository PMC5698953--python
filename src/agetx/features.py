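"""Gene-characteristic analysis: structural features versus regulation.

For each gene we compute the genomic length (introns included) of its most
abundant expressed isoform, the mean RPKM across all samples, and the
numbers of expressed exons (count > 1 in at least one sample) and expressed
isoforms (any assigned count). Feature distributions are compared across
expression clusters and the non-significant gene set with Kruskal-Wallis
and pairwise Wilcoxon rank-sum tests (BH-corrected), and each feature's
power to identify down- (or up-) regulated genes is summarized by ROC/AUC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountMatrix, GeneModelSet
from .motifs import RocCurve, bh_adjust, roc_auc

FEATURES = ["length_nt", "mean_rpkm", "n_expressed_exons", "n_expressed_isoforms"]


def feature_table(
    models: GeneModelSet,
    cm: CountMatrix,
    isoform_counts: pd.DataFrame,
    exon_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene feature table.

    Length is the genomic span (first exon start to last exon end, introns
    included) of the isoform with the highest total assigned count across
    all samples (ties broken by the longer isoform); an exon counts as
    expressed with count > 1 in at least one sample; an isoform with any
    assigned count. Genes with no expressed isoform are flagged missing.
    """
    rows = []
    for gene in models:
        gid = gene.gene_id
        if gid not in cm.counts.index:
            continue
        iso = isoform_counts.loc[gid]
        totals = iso.sum(axis=1)
        expressed_iso = int((totals > 0).sum())
        if expressed_iso == 0:
            rows.append(
                dict(gene_id=gid, length_nt=np.nan, mean_rpkm=np.nan,
                     n_expressed_exons=0, n_expressed_isoforms=0, missing=True)
            )
            continue
        spans = {i: gene.isoform_span_length(i) for i in iso.index}
        best = max(iso.index, key=lambda i: (totals[i], spans[i]))
        length = spans[best]
        ex = exon_counts.loc[gid]
        expressed_ex = int(((ex > 1).any(axis=1)).sum())
        rows.append(
            dict(gene_id=gid, length_nt=length, mean_rpkm=np.nan,
                 n_expressed_exons=expressed_ex,
                 n_expressed_isoforms=expressed_iso, missing=False)
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    lengths = table["length_nt"].fillna(1.0)
    cpm = cm.counts * (1e6 / cm.lib_sizes.to_numpy())
    table["mean_rpkm"] = (cpm.mul(1e3 / lengths, axis=0)).mean(axis=1)
    table.loc[table["missing"], "mean_rpkm"] = np.nan
    return table


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p: exact enumeration for small tie-free
    samples, normal approximation with continuity and tie correction
    otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = max(len(x), len(y)) <= 25
    ties = len(np.unique(np.r_[x, y])) < len(x) + len(y)
    method = "exact" if small and not ties else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def compare_feature_distributions(
    features: pd.DataFrame,
    clusters: pd.Series,
    nonsig_genes,
    min_group: int = 3,
) -> tuple[pd.Series, pd.DataFrame]:
    """Kruskal-Wallis across all groups plus pairwise cluster-vs-nonsig
    Wilcoxon tests per feature.

    Groups are the expression clusters plus the non-significant gene set.
    Pairwise p-values are BH-corrected within each feature; groups smaller
    than ``min_group`` are reported as missing rather than raising.
    """
    nonsig = [g for g in nonsig_genes if g in features.index]
    groups = {f"C{cid}": clusters.index[clusters == cid].tolist()
              for cid in sorted(clusters.unique())}
    groups["nonsig"] = nonsig
    kw = {}
    rows = []
    for feat in FEATURES:
        vals = {
            name: features.loc[[g for g in ids if g in features.index], feat]
            .dropna().to_numpy()
            for name, ids in groups.items()
        }
        usable = [v for v in vals.values() if len(v) >= min_group]
        if len(usable) < 2:
            kw[feat] = np.nan
        elif len(np.unique(np.concatenate(usable))) == 1:
            kw[feat] = 1.0  # zero statistic by convention
        else:
            kw[feat] = float(stats.kruskal(*usable).pvalue)
        for name, ids in groups.items():
            if name == "nonsig":
                continue
            x, y = vals[name], vals["nonsig"]
            if len(x) < min_group or len(y) < min_group:
                p = np.nan
            elif len(np.unique(np.r_[x, y])) == 1:
                p = 1.0
            else:
                p = wilcoxon_rank_sum(x, y)
            rows.append(
                dict(feature=feat, group=name, n=len(x),
                     median=float(np.median(x)) if len(x) else np.nan,
                     nonsig_median=float(np.median(y)) if len(y) else np.nan,
                     p=p)
            )
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = np.nan
    for feat in FEATURES:
        mask = (pairwise["feature"] == feat) & pairwise["p"].notna()
        if mask.any():
            pairwise.loc[mask, "q"] = bh_adjust(pairwise.loc[mask, "p"].to_numpy())
    return pd.Series(kw, name="kruskal_p"), pairwise


def feature_roc(feature_values: pd.Series, labels: pd.Series) -> RocCurve:
    """ROC of a raw gene feature against a binary regulation label
    (e.g. downregulated vs not)."""
    common = feature_values.dropna().index.intersection(labels.index)
    return roc_auc(feature_values[common].to_numpy(),
                   labels[common].to_numpy())
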