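"""Promoter motif presence, enrichment, and ROC-based motif combination.

Given promoter windows around transcription start sites and a motif library
(IUPAC degenerate strings or position weight matrices), this module builds a
binary gene x motif presence matrix, tests per-motif enrichment in a target
gene set (upper-tail hypergeometric), and quantifies how well motifs —
singly and in greedy forward combination — identify a labelled gene class by
ROC/AUC. Paired AUC comparisons use DeLong's nonparametric test, which also
drives the "top motif" stopping rule. A random-matrix control calibrates
the AUC attainable by chance, and a co-occurrence network characterizes how
motifs cluster across promoters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Motif:
    """A sequence motif: either an IUPAC degenerate string or a 4 x w PWM
    (rows A, C, G, T; columns are probabilities)."""

    name: str
    iupac: str | None = None
    pwm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.iupac is None) == (self.pwm is None):
            raise ValueError("provide exactly one of iupac or pwm")
        if self.iupac is not None:
            if not self.iupac:
                raise ValueError("empty motif")
            bad = set(self.iupac.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC codes: {bad}")
            self.iupac = self.iupac.upper()
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[0] != 4 or self.pwm.shape[1] == 0:
                raise ValueError("PWM must be 4 x w with w >= 1")

    def __len__(self) -> int:
        return len(self.iupac) if self.iupac is not None else self.pwm.shape[1]

    def consensus(self, rng: np.random.Generator | None = None) -> str:
        """A concrete instance of the motif: PWM argmax letters, or a random
        (seeded) realization of each degenerate IUPAC position."""
        if self.pwm is not None:
            return "".join("ACGT"[i] for i in self.pwm.argmax(axis=0))
        if rng is None:
            return "".join(IUPAC[c][0] for c in self.iupac)
        return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in self.iupac)


def parse_motif_library(text: str) -> list[Motif]:
    """Parse a motif library from JASPAR-style PWM text (``>name`` header
    followed by four A/C/G/T rows) or one IUPAC string per line, optionally
    preceded by a name."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    motifs: list[Motif] = []
    if any(ln.startswith(">") for ln in lines):
        i = 0
        while i < len(lines):
            if not lines[i].startswith(">"):
                raise ValueError(f"expected '>' header, got {lines[i]!r}")
            name = lines[i][1:].split()[0]
            rows = []
            for j in range(1, 5):
                row = re.sub(r"^[ACGT]\s*[\[|]?", "", lines[i + j]).rstrip("]")
                rows.append([float(x) for x in row.split()])
            pwm = np.asarray(rows)
            pwm = pwm / pwm.sum(axis=0, keepdims=True)
            motifs.append(Motif(name=name, pwm=pwm))
            i += 5
    else:
        for i, ln in enumerate(lines):
            parts = ln.split()
            if len(parts) == 2:
                motifs.append(Motif(name=parts[0], iupac=parts[1]))
            else:
                motifs.append(Motif(name=f"motif_{i + 1}", iupac=parts[0]))
    return motifs


# ---------------------------------------------------------------------------
# Promoter scanning


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]"
                              for c in pattern))


def _pwm_hits(seq: str, logodds: np.ndarray, threshold: float) -> bool:
    w = logodds.shape[1]
    if len(seq) < w:
        return False
    idx = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    # N rows score -inf so windows containing N never reach the threshold
    lo = np.vstack([logodds, np.full(w, -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    scores = lo[windows, np.arange(w)].sum(axis=1)
    return bool((scores >= threshold).any())


def _motif_present(seq: str, motif: Motif, score_fraction: float) -> bool:
    seq = seq.upper()
    if motif.iupac is not None:
        rx = _iupac_regex(motif.iupac)
        return bool(rx.search(seq) or rx.search(revcomp(seq)))
    pwm = np.clip(motif.pwm, 1e-4, None)
    pwm = pwm / pwm.sum(axis=0, keepdims=True)
    logodds = np.log2(pwm / 0.25)
    threshold = score_fraction * logodds.max(axis=0).sum()
    return _pwm_hits(seq, logodds, threshold) or _pwm_hits(
        revcomp(seq), logodds, threshold
    )


def scan_promoters(
    promoters: dict[str, str],
    motifs: list[Motif],
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Binary presence matrix (genes x motifs) over promoter windows.

    A PWM hits where its log-odds score against a uniform background reaches
    ``score_fraction`` of the maximum attainable score on either strand; an
    IUPAC motif hits on exact degenerate match on either strand. ``N`` bases
    never match.
    """
    for m in motifs:
        for g, seq in promoters.items():
            if len(m) > len(seq):
                raise ValueError(f"motif {m.name} longer than promoter {g}")
            break
    data = {
        m.name: [int(_motif_present(promoters[g], m, score_fraction))
                 for g in promoters]
        for m in motifs
    }
    return pd.DataFrame(data, index=list(promoters), dtype=np.int8)


# ---------------------------------------------------------------------------
# Enrichment


def enrich_motifs(
    presence: pd.DataFrame, targets: list[str], alpha: float = 0.001
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each motif in ``targets``
    relative to the background (all rows of ``presence``)."""
    targets = list(targets)
    if not targets:
        raise ValueError("target gene set is empty")
    missing = set(targets) - set(presence.index)
    if missing:
        raise ValueError(f"targets not in background: {sorted(missing)[:5]}")
    n_bg = len(presence)
    n_t = len(targets)
    k_bg = presence.sum(axis=0)
    k_t = presence.loc[targets].sum(axis=0)
    p = stats.hypergeom.sf(k_t - 1, n_bg, k_bg, n_t)
    out = pd.DataFrame(
        {
            "n_background_hits": k_bg,
            "n_target_hits": k_t,
            "p": p,
            "significant": p < alpha,
        },
        index=presence.columns,
    )
    return out


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocCurve:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def _auc_rank(scores: np.ndarray, pos: np.ndarray) -> float:
    """Mann-Whitney AUC (ties count 0.5) via average ranks."""
    r = stats.rankdata(scores)
    m = int(pos.sum())
    n = len(scores) - m
    return (r[pos].sum() - m * (m + 1) / 2) / (m * n)


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC. The AUC equals the Mann-Whitney probability that a
    random positive outscores a random negative, with ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(np.asarray(labels))
    pos = labels == 1
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    tp = np.cumsum(labels[order])
    fp = np.cumsum(1 - labels[order])
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tp[distinct] / pos.sum()]
    fpr = np.r_[0.0, fp[distinct] / (~pos).sum()]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return RocCurve(float(_auc_rank(scores, pos)), fpr, tpr, thresholds)


def _batch_auc_int(scores: np.ndarray, pos: np.ndarray, n_levels: int) -> np.ndarray:
    """AUC for each column of an integer score matrix in [0, n_levels).

    Histogram formulation of the Mann-Whitney statistic: for each score
    level, positives at that level beat all negatives below it and tie
    (weight 0.5) with negatives at it.
    """
    n, c = scores.shape
    m = int(pos.sum())
    offsets = n_levels * np.arange(c)
    flat = scores + offsets
    hp = np.bincount(flat[pos].ravel(), minlength=n_levels * c).reshape(c, n_levels)
    hn = np.bincount(flat[~pos].ravel(), minlength=n_levels * c).reshape(c, n_levels)
    cum_below = np.concatenate(
        [np.zeros((c, 1)), np.cumsum(hn, axis=1)[:, :-1]], axis=1
    )
    wins = (hp * (cum_below + 0.5 * hn)).sum(axis=1)
    return wins / (m * (n - m))


@dataclass
class GreedyTrajectory:
    """Forward greedy motif-combination trajectory.

    At each step the motif maximizing the combined AUC is added; a gene's
    combination score is the number of selected motifs present in its
    promoter. ``aucs[i]`` is the AUC after adding ``motifs[i]``.
    """

    motifs: list[str]
    aucs: list[float]
    step_p: list[float] = field(default_factory=list)

    @property
    def max_auc(self) -> float:
        return max(self.aucs)


def _greedy_order(M: np.ndarray, pos: np.ndarray, names: list[str] | None = None):
    n, p = M.shape
    base = np.zeros(n, dtype=np.int32)
    remaining = list(range(p))
    order: list[int] = []
    aucs: list[float] = []
    for step in range(p):
        cand = base[:, None] + M[:, remaining]
        a = _batch_auc_int(cand, pos, step + 2)
        best_auc = a.max()
        tied = [remaining[j] for j in np.flatnonzero(np.isclose(a, best_auc, atol=0))]
        if names is not None and len(tied) > 1:
            best = min(tied, key=lambda j: names[j])
        else:
            best = tied[0]
        order.append(best)
        aucs.append(float(a[remaining.index(best)]))
        base += M[:, best]
        remaining.remove(best)
    return order, aucs


def greedy_combination(presence, labels) -> GreedyTrajectory:
    """Greedy forward selection of motif combinations by AUC.

    Step 1 picks the single motif with maximal AUC; each later step adds the
    motif maximizing the AUC of the count-of-present-motifs score. Ties are
    broken by lexicographic motif name.
    """
    if isinstance(presence, pd.DataFrame):
        names = [str(c) for c in presence.columns]
        M = presence.to_numpy()
    else:
        M = np.asarray(presence)
        names = [f"motif_{j}" for j in range(M.shape[1])]
    if M.shape[1] < 1:
        raise ValueError("need at least one motif")
    M = M.astype(np.int32)
    labels = _check_labels(np.asarray(labels))
    order, aucs = _greedy_order(M, labels == 1, names)
    return GreedyTrajectory(motifs=[names[j] for j in order], aucs=aucs)


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison


@dataclass
class DelongResult:
    p: float
    z: float
    auc_a: float
    auc_b: float
    degenerate: bool = False


def _delong_components(scores: np.ndarray, pos: np.ndarray):
    x, y = scores[pos], scores[~pos]
    m, n = len(x), len(y)
    r_all = stats.rankdata(np.r_[x, y])
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (r_all[:m] - rx) / n  # per-positive placement values
    v10 = 1.0 - (r_all[m:] - ry) / m  # per-negative placement values
    return auc, v01, v10


def delong_paired_test(scores_a, scores_b, labels) -> DelongResult:
    """DeLong's paired test for equality of two correlated AUCs.

    Both score vectors are evaluated on the same genes/labels; the variance
    of the AUC difference comes from the empirical covariance of the
    placement components. Identical score vectors give p = 1; a degenerate
    zero variance with unequal AUCs is reported as p = 0 with a flag.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    labels = _check_labels(np.asarray(labels))
    if sa.shape != sb.shape or sa.shape[0] != labels.shape[0]:
        raise ValueError("score vectors and labels must have equal length")
    pos = labels == 1
    if np.array_equal(sa, sb):
        auc = float(_auc_rank(sa, pos))
        return DelongResult(p=1.0, z=0.0, auc_a=auc, auc_b=auc)
    auc_a, v01a, v10a = _delong_components(sa, pos)
    auc_b, v01b, v10b = _delong_components(sb, pos)
    m, n = len(v01a), len(v10a)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    var = (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / m + (
        s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]
    ) / n
    if var <= 0:
        if np.isclose(auc_a, auc_b):
            return DelongResult(p=1.0, z=0.0, auc_a=auc_a, auc_b=auc_b)
        return DelongResult(p=0.0, z=np.inf, auc_a=auc_a, auc_b=auc_b,
                            degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return DelongResult(p=float(p), z=float(z), auc_a=float(auc_a),
                        auc_b=float(auc_b))


def top_motifs(
    trajectory: GreedyTrajectory, presence, labels, alpha: float = 0.05
) -> list[str]:
    """Longest trajectory prefix in which every single motif addition
    significantly improves the combined ROC (DeLong paired p < alpha).

    Step 1 is always included by convention (there is no previous curve to
    compare against); with an uninformative matrix the prefix is therefore
    length 1 and carries no signal.
    """
    if isinstance(presence, pd.DataFrame):
        cols = {str(c): presence[c].to_numpy() for c in presence.columns}
    else:
        M = np.asarray(presence)
        cols = {f"motif_{j}": M[:, j] for j in range(M.shape[1])}
    labels = _check_labels(np.asarray(labels))
    prev = np.zeros(len(labels))
    prefix: list[str] = []
    trajectory.step_p = []
    for i, name in enumerate(trajectory.motifs):
        cur = prev + cols[name]
        if i == 0:
            trajectory.step_p.append(np.nan)
            prefix.append(name)
        else:
            res = delong_paired_test(cur, prev, labels)
            trajectory.step_p.append(res.p)
            improved = res.auc_a > res.auc_b
            if len(prefix) == i and improved and res.p < alpha:
                prefix.append(name)
        prev = cur
    return prefix


# ---------------------------------------------------------------------------
# Random-matrix control


def random_control(
    n_genes: int = 7580,
    n_motifs: int = 40,
    p_max: float = 0.145,
    n_iter: int = 100,
    n_positive: int = 288,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Chance-level AUC of the greedy combination procedure.

    For each of ``n_iter`` random matrices, every motif gets a presence
    probability drawn uniformly from [0, p_max] and entries are Bernoulli;
    a fixed set of ``n_positive`` genes is labelled positive. The greedy
    combination is run and the maximum AUC along its trajectory recorded.
    Returns the maximum over iterations and the per-iteration maxima.
    """
    if not 0 < n_positive < n_genes:
        raise ValueError("need 0 < n_positive < n_genes")
    rng = np.random.default_rng(seed)
    pos = np.zeros(n_genes, dtype=bool)
    pos[:n_positive] = True
    per_iter = np.empty(n_iter)
    for it in range(n_iter):
        probs = rng.uniform(0.0, p_max, size=n_motifs)
        M = (rng.random((n_genes, n_motifs)) < probs).astype(np.int32)
        if p_max == 0:
            per_iter[it] = 0.5
            continue
        _, aucs = _greedy_order(M, pos)
        per_iter[it] = max(aucs)
    return float(per_iter.max()), per_iter


# ---------------------------------------------------------------------------
# Co-occurrence network


def cooccurrence_network(
    presence: pd.DataFrame,
    motif_subset: list[str] | None = None,
    alpha: float = 0.05,
) -> nx.Graph:
    """Motif co-occurrence graph over promoters.

    Two motifs are connected when their co-occurrence count exceeds the
    hypergeometric expectation (upper-tail test, BH-corrected q < alpha).
    Node attributes carry the degree and the local clustering coefficient
    (0 for degree < 2, the triangle-based definition otherwise).
    """
    cols = list(presence.columns if motif_subset is None else motif_subset)
    if len(cols) < 2:
        raise ValueError("need at least two motifs")
    M = presence[cols].to_numpy().astype(bool)
    n = M.shape[0]
    pairs = [(i, j) for i in range(len(cols)) for j in range(i + 1, len(cols))]
    pvals = []
    for i, j in pairs:
        k = int((M[:, i] & M[:, j]).sum())
        ki, kj = int(M[:, i].sum()), int(M[:, j].sum())
        pvals.append(stats.hypergeom.sf(k - 1, n, ki, kj))
    q = bh_adjust(np.asarray(pvals))
    g = nx.Graph()
    g.add_nodes_from(cols)
    for (i, j), qv in zip(pairs, q):
        if qv < alpha:
            g.add_edge(cols[i], cols[j], q=float(qv))
    cc = nx.clustering(g)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
        g.nodes[node]["clustering"] = cc[node]
    return g


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
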