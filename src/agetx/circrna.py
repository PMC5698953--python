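"""circRNA quantification from back-splice junction scaffolds.

A circRNA is detectable only through reads spanning its back-splice
junction, so each candidate circle is turned into a linear alignment
target: the last <=85 exonic nt ending at the back-splice donor followed by
the first <=85 exonic nt starting at the acceptor (a 170-nt scaffold when
both flanks are full). Reads are aligned ungapped end-to-end to every
scaffold, kept when they best-match one scaffold with a small mismatch
budget and overlap the junction by at least 15 nt on each side, and PCR /
sequencing duplicates (identical scaffold, offset, sequence) are collapsed.
Counts are tier-flagged, CPM-normalized, tested for pairwise differential
abundance (pooled Fisher's exact), compared across ages (Wilcoxon,
Kruskal-Wallis with Nemenyi post-hoc), related to host-gene fold changes,
and regressed on age.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import CircRNARecord, GeneModel, GeneModelSet
from .synthetic import circle_sequence
from .timecourse import cpm_normalize, pairwise_exact_de

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def build_scaffold(
    circ_id: str,
    gene: GeneModel,
    genome: dict[str, str],
    start: int,
    end: int,
    take: int = 85,
) -> CircRNARecord:
    """Back-splice junction scaffold for a circle over [start, end).

    Both coordinates must lie on annotated exons of the host gene. The
    scaffold concatenates the donor-side flank (last min(take, available)
    exonic nt of the circular transcript) with the acceptor-side flank
    (first min(take, available) nt), walking the multi-exon structure and
    respecting strand; the junction index is the donor-flank length.
    """
    exons = gene.union_exons()
    if not any(s <= start < e for s, e in exons) or not any(
        s < end <= e for s, e in exons
    ):
        raise ValueError(f"{circ_id}: circle coordinates must lie on exons")
    circ = circle_sequence(gene, genome, start, end)
    up_take = min(take, len(circ))
    down_take = min(take, len(circ))
    scaffold = circ[-up_take:] + circ[:down_take]
    return CircRNARecord(
        circ_id=circ_id,
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        start=start,
        end=end,
        strand=gene.strand,
        scaffold=scaffold,
        junction_pos=up_take,
    )


def build_scaffolds(
    circs: list[tuple[str, str, int, int]],
    models: GeneModelSet,
    genome: dict[str, str],
    take: int = 85,
) -> list[CircRNARecord]:
    """Scaffolds for (circ_id, gene_id, start, end) candidate tuples."""
    return [
        build_scaffold(cid, models[gid], genome, s, e, take=take)
        for cid, gid, s, e in circs
    ]


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASES.get(b, 4) for b in seq.upper()], dtype=np.int8)


def align_junction_reads(
    reads: dict[str, list[tuple[str, str]]],
    scaffolds: list[CircRNARecord],
    max_mismatches: int = 2,
    min_overlap: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ungapped end-to-end alignment of reads to junction scaffolds.

    Each read is tried at every offset of every scaffold; the best offset
    per scaffold must have <= ``max_mismatches`` mismatches (N never
    matches) and leave >= ``min_overlap`` nt on each side of the junction.
    A read passing on several scaffolds is assigned to the strictly
    fewest-mismatch one; exact ties are dropped. Returns the alignment
    table and per-library accounting (accepted / overlap-rejected /
    unaligned / too-long), whose rows sum to the library read totals.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    enc = {r.circ_id: _encode(r.scaffold) for r in scaffolds}
    jpos = {r.circ_id: r.junction_pos for r in scaffolds}
    rows = []
    log_rows = []
    for sample_id, lib in reads.items():
        tally = {"accepted": 0, "overlap_rejected": 0, "unaligned": 0,
                 "too_long": 0, "ambiguous": 0}
        for read_id, seq in lib:
            q = _encode(seq)
            L = len(q)
            candidates = []  # (mismatches, circ_id, offset, ol, orr)
            fits_any = False
            for cid, s in enc.items():
                if L > len(s):
                    continue
                fits_any = True
                win = np.lib.stride_tricks.sliding_window_view(s, L)
                # N never matches, including N-vs-N
                mism = ((win != q) | ((q == 4)[None, :] & (win == 4))).sum(axis=1)
                best_off = int(mism.argmin())
                best_mm = int(mism[best_off])
                if best_mm <= max_mismatches:
                    j = jpos[cid]
                    ol = j - best_off
                    orr = best_off + L - j
                    candidates.append((best_mm, cid, best_off, ol, orr))
            if not fits_any:
                tally["too_long"] += 1
                continue
            if not candidates:
                tally["unaligned"] += 1
                continue
            candidates.sort(key=lambda c: c[0])
            if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
                tally["ambiguous"] += 1
                continue
            mm, cid, off, ol, orr = candidates[0]
            if ol < min_overlap or orr < min_overlap:
                tally["overlap_rejected"] += 1
                continue
            tally["accepted"] += 1
            rows.append(
                dict(read_id=read_id, sample=sample_id, circ_id=cid,
                     offset=off, mismatches=mm, overlap_left=ol,
                     overlap_right=orr, seq=seq.upper())
            )
        log_rows.append({"sample": sample_id, "total": len(lib), **tally})
    alignments = pd.DataFrame(
        rows, columns=["read_id", "sample", "circ_id", "offset", "mismatches",
                       "overlap_left", "overlap_right", "seq"]
    )
    return alignments, pd.DataFrame(log_rows).set_index("sample")


def dedupe(alignments: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR/sequencing duplicates: alignments identical in
    (circ_id, offset, read sequence) within a library keep one record."""
    if alignments.empty:
        return alignments
    return alignments.drop_duplicates(subset=["sample", "circ_id", "offset", "seq"])


def count_junction_reads(
    alignments: pd.DataFrame, libraries: list[str]
) -> pd.DataFrame:
    """circRNA x library table of unique junction-read counts."""
    if alignments.empty:
        return pd.DataFrame(columns=libraries, dtype=int)
    tab = (
        alignments.groupby(["circ_id", "sample"]).size().unstack(fill_value=0)
    )
    return tab.reindex(columns=libraries, fill_value=0)


def count_and_filter(
    counts: pd.DataFrame,
    report_min_total: int = 2,
    abundant_min_total: int = 7,
) -> pd.DataFrame:
    """Tier flags on total junction counts: reported (total >= 2) and
    abundant (total > 6)."""
    total = counts.sum(axis=1)
    return pd.DataFrame(
        {
            "total": total,
            "reported": total >= report_min_total,
            "abundant": total >= abundant_min_total,
        }
    )


def de_eligible(
    counts: pd.DataFrame, libraries: list[str], min_avg_per_library: float = 1.0
) -> pd.Series:
    """Eligibility for a pairwise comparison: at least ``min_avg_per_library``
    reads per involved library on average (e.g. 6 reads across 6
    libraries)."""
    need = min_avg_per_library * len(libraries)
    return counts[libraries].sum(axis=1) >= need


circ_cpm = cpm_normalize


def pairwise_circ_de(
    counts: pd.DataFrame,
    lib_sizes: pd.Series,
    libs_a: list[str],
    libs_b: list[str],
    alpha: float = 0.05,
    min_fc: float = 2.0,
) -> pd.DataFrame:
    """Pairwise circRNA differential abundance between two ages (pooled
    Fisher's exact test on junction counts; call at p <= alpha and
    CPM fold change >= min_fc)."""
    return pairwise_exact_de(counts, lib_sizes, libs_a, libs_b,
                             alpha=alpha, min_fc=min_fc)


def abundance_shift_tests(
    cpm: pd.DataFrame, design: pd.DataFrame, baseline_age: int | None = None
) -> dict:
    """Distribution shifts of per-circRNA CPM across ages.

    Per-circ CPM is averaged over each age's libraries; the baseline age is
    compared against each later age with a two-sided Wilcoxon rank-sum test
    (continuity-corrected normal approximation), all ages jointly with
    Kruskal-Wallis, and all age pairs with the Nemenyi post-hoc test.
    """
    if len(cpm) < 3:
        raise ValueError("need at least 3 circRNAs")
    ages = np.sort(design["age"].unique())
    if baseline_age is None:
        baseline_age = int(ages[0])
    per_age = {
        int(a): cpm[design.index[design["age"] == a]].mean(axis=1).to_numpy()
        for a in ages
    }
    wilcoxon = {}
    for a in ages:
        a = int(a)
        if a == baseline_age:
            continue
        res = stats.mannwhitneyu(
            per_age[baseline_age], per_age[a], alternative="two-sided",
            method="asymptotic", use_continuity=True,
        )
        wilcoxon[a] = float(res.pvalue)
    kw_p = float(stats.kruskal(*per_age.values()).pvalue)
    nemenyi = nemenyi_test(list(per_age.values()))
    labels = [int(a) for a in ages]
    nemenyi = pd.DataFrame(nemenyi, index=labels, columns=labels)
    return {"wilcoxon_p": wilcoxon, "kruskal_p": kw_p, "nemenyi_q": nemenyi}


def nemenyi_test(groups: list[np.ndarray]) -> np.ndarray:
    """Nemenyi all-pairs post-hoc test on pooled ranks.

    Mean-rank differences are referred to the studentized range
    distribution with k groups and infinite degrees of freedom.
    """
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    mean_ranks = np.asarray(mean_ranks)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(n * (n + 1) / 12.0 * (1 / sizes[i] + 1 / sizes[j]))
            q_stat = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
            p = stats.studentized_range.sf(q_stat, k, np.inf)
            out[i, j] = out[j, i] = p
    return out


def host_independence(
    circ_log2fc: pd.Series, host_log2fc: pd.Series
) -> tuple[pd.DataFrame, float, float]:
    """Pair each circRNA's fold change with its host gene's linear fold
    change and report the Spearman correlation.

    circRNAs without a matched host are flagged missing; with fewer than
    two pairs the correlation is undefined (NaN)."""
    table = pd.DataFrame({"circ_log2fc": circ_log2fc})
    table["host_log2fc"] = host_log2fc.reindex(circ_log2fc.index)
    table["missing_host"] = table["host_log2fc"].isna()
    paired = table.dropna()
    if len(paired) < 2:
        return table, float("nan"), float("nan")
    rho, p = stats.spearmanr(paired["circ_log2fc"], paired["host_log2fc"])
    return table, float(rho), float(p)


def age_trend(
    cpm: pd.DataFrame, design: pd.DataFrame, circ_subset=None
) -> tuple[float, float, float]:
    """OLS regression of per-library mean circRNA CPM on age.

    Returns (slope, intercept, r2); r2 is the squared Pearson correlation,
    defined 0 when the response has zero variance.
    """
    if circ_subset is not None:
        cpm = cpm.loc[list(circ_subset)]
    ages = design["age"].to_numpy(dtype=float)
    if len(np.unique(ages)) < 2:
        raise ValueError("need at least two distinct ages")
    y = cpm.mean(axis=0).to_numpy(dtype=float)
    res = stats.linregress(ages, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return float(res.slope), float(res.intercept), r2
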