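"""Cluster age-regulated genes on relative temporal profiles.

Max-normalized per-age mean CPM profiles of the called genes are grouped
by k-means (k = 11); each cluster's median profile is fitted with a
quadratic in age and classified as up/down and early/middle/late. Writes
the per-cluster summary and per-gene assignments.
"""

import importlib.util
from pathlib import Path

import pandas as pd

from agetx import clustering as cl, io, timecourse as tc

HERE = Path(__file__).resolve().parent
spec = importlib.util.spec_from_file_location("de02", HERE / "02_timecourse_de.py")
de02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(de02)

OUT = HERE.parent / "results"
SEED_KMEANS = 5


def main():
    cm, truth, results = de02.run_de()
    genes = results.index[results.called]
    table, fits = cl.cluster_and_classify(
        tc.cpm_normalize(cm), cm.design, genes, k=11, seed=SEED_KMEANS
    )
    summary = pd.DataFrame(
        [
            {
                "cluster": f.cluster_id, "n_genes": len(f.gene_ids),
                "a0": f.coef[0], "a1": f.coef[1], "a2": f.coef[2],
                "r2": f.r2, "direction": f.direction, "timing": f.timing,
            }
            for f in fits
        ]
    ).set_index("cluster")
    io.write_tsv(summary, OUT / "03_cluster_fits.tsv")
    io.write_tsv(table, OUT / "03_gene_clusters.tsv")
    reg = [g for g in table.index if truth.loc[g, "regulated"]]
    agree = (table.loc[reg, "direction"] == truth.loc[reg, "direction"]).mean()
    n_up = (table.direction == "up").sum()
    n_down = (table.direction == "down").sum()
    print(f"clustered {len(table)} genes into {len(fits)} clusters "
          f"(k-means seed {SEED_KMEANS})")
    print(f"direction partition: {n_up} up + {n_down} down = {n_up + n_down}")
    print(f"direction agreement with planted truth: {agree:.3f}")
    print(summary.round(4).to_string())


if __name__ == "__main__":
    main()
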