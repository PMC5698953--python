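"""Temporal expression clustering and trajectory classification.

Age-regulated genes are represented by max-normalized per-age mean
expression profiles (maximum set to one), clustered by Euclidean k-means
(k = 11 by default, best of many seeded initializations), and each
cluster's median profile is fitted with a quadratic in age. The fitted
curve classifies the cluster: direction (up/down) from the sign of
f(last age) - f(first age), and timing from the relative magnitude of the
early (first interval) versus late (last interval) change — early if the
early change is at least twice the late one, late for the converse, middle
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .timecourse import cpm_normalize


def relative_profiles(
    cpm: pd.DataFrame, design: pd.DataFrame, genes=None
) -> pd.DataFrame:
    """Per-age replicate means divided by the per-gene maximum.

    Every profile has maximum exactly 1; an all-zero gene cannot be
    normalized and raises.
    """
    if genes is not None:
        cpm = cpm.loc[list(genes)]
    ages = np.sort(design["age"].unique())
    means = pd.DataFrame(
        {age: cpm[design.index[design["age"] == age]].mean(axis=1) for age in ages}
    )
    mx = means.max(axis=1)
    if (mx <= 0).any():
        bad = means.index[mx <= 0][:5].tolist()
        raise ValueError(f"cannot normalize all-zero genes: {bad}")
    return means.div(mx, axis=0)


def cluster_profiles(
    profiles: pd.DataFrame, k: int = 11, seed: int | None = None, n_init: int = 50
) -> pd.Series:
    """Euclidean k-means over profiles; best of ``n_init`` seeded
    k-means++ initializations by within-cluster sum of squares. Cluster ids
    are 1..k."""
    if k > len(profiles):
        raise ValueError("k exceeds the number of profiles")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy())
    return pd.Series(labels + 1, index=profiles.index, name="cluster")


@dataclass
class ClusterFit:
    cluster_id: int
    gene_ids: list[str]
    ages: np.ndarray
    median_profile: np.ndarray
    coef: tuple[float, float, float]  # a0 + a1*age + a2*age^2
    r2: float
    direction: str
    timing: str
    degenerate: bool = False

    def predict(self, age) -> np.ndarray:
        a0, a1, a2 = self.coef
        age = np.asarray(age, dtype=float)
        return a0 + a1 * age + a2 * age**2


def fit_cluster_quadratic(
    profiles: pd.DataFrame, assignments: pd.Series, ages=None
) -> list[ClusterFit]:
    """Quadratic least-squares fit to each cluster's per-age median profile.

    r2 = 1 - RSS/TSS, with the zero-variance target (constant medians)
    reported as a perfect fit (r2 = 1) and flagged degenerate.
    """
    if ages is None:
        ages = np.asarray(profiles.columns, dtype=float)
    else:
        ages = np.asarray(ages, dtype=float)
    fits = []
    for cid in sorted(assignments.unique()):
        members = assignments.index[assignments == cid]
        if len(members) == 0:
            raise ValueError(f"cluster {cid} is empty")
        med = profiles.loc[members].median(axis=0).to_numpy()
        X = np.vander(ages, 3, increasing=True)
        beta, *_ = np.linalg.lstsq(X, med, rcond=None)
        fitted = X @ beta
        rss = float(((med - fitted) ** 2).sum())
        tss = float(((med - med.mean()) ** 2).sum())
        degenerate = tss == 0
        r2 = 1.0 if degenerate else 1.0 - rss / tss
        direction, timing, dir_degen = classify_curve(tuple(beta), ages)
        fits.append(
            ClusterFit(
                cluster_id=int(cid),
                gene_ids=list(members),
                ages=ages,
                median_profile=med,
                coef=(float(beta[0]), float(beta[1]), float(beta[2])),
                r2=float(np.clip(r2, 0.0, 1.0)),
                direction=direction,
                timing=timing,
                degenerate=degenerate or dir_degen,
            )
        )
    return fits


def classify_curve(
    coef: tuple[float, float, float], ages=(10, 20, 25, 30, 40)
) -> tuple[str, str, bool]:
    """Direction and timing of a fitted quadratic.

    Direction is the sign of f(last) - f(first); an exact tie falls back to
    the sign of the total variation over the sampled ages and is flagged
    degenerate (a fully constant curve reports middle). Timing compares the
    early change De = |f(ages[1]) - f(ages[0])| with the late change
    Dl = |f(last) - f(second-last)|: early if De >= 2*Dl, late if
    Dl >= 2*De, middle otherwise.
    """
    a0, a1, a2 = coef
    ages = np.asarray(ages, dtype=float)
    f = a0 + a1 * ages + a2 * ages**2
    delta = f[-1] - f[0]
    degenerate = False
    if delta == 0:
        diffs = np.diff(f)
        tv = diffs.sum()  # signed net change along the sampled curve
        degenerate = True
        if np.all(diffs == 0):
            return "tie", "middle", True
        delta = tv if tv != 0 else diffs[np.nonzero(diffs)[0][0]]
    direction = "up" if delta > 0 else "down"
    d_early = abs(f[1] - f[0])
    d_late = abs(f[-1] - f[-2])
    if d_early >= 2 * d_late:
        timing = "early"
    elif d_late >= 2 * d_early:
        timing = "late"
    else:
        timing = "middle"
    return direction, timing, degenerate


def cluster_and_classify(
    counts_or_cpm,
    design: pd.DataFrame,
    genes,
    k: int = 11,
    seed: int | None = None,
    n_init: int = 50,
) -> tuple[pd.DataFrame, list[ClusterFit]]:
    """Full clustering stage: profiles -> k-means -> per-cluster quadratic
    fit and classification. Returns the per-gene table (cluster, direction,
    timing) and the list of cluster fits."""
    cpm = counts_or_cpm
    if hasattr(cpm, "counts"):
        cpm = cpm_normalize(cpm)
    profiles = relative_profiles(cpm, design, genes)
    assignments = cluster_profiles(profiles, k=k, seed=seed, n_init=n_init)
    fits = fit_cluster_quadratic(profiles, assignments)
    by_cluster = {f.cluster_id: f for f in fits}
    table = pd.DataFrame(
        {
            "cluster": assignments,
            "direction": [by_cluster[c].direction for c in assignments],
            "timing": [by_cluster[c].timing for c in assignments],
        },
        index=assignments.index,
    )
    return table, fits
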