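"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates a five-age (days 10, 20, 25, 30, 40), three-replicate
negative-binomial RNA-seq time course in an aging neuronal tissue: gene
models with exon/isoform structure on a synthetic chromosome, promoter
windows with motifs planted at class-specific rates, counts in which a
configurable subset of genes follows quadratic temporal trajectories, and
back-splice junction reads whose circRNA abundance rises with age
independently of the host gene. Every generator returns a truth table
enumerating exactly the planted signal, and is byte-identical across runs
for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import CircPlan, CountMatrix, GeneModel, GeneModelSet, TrajectoryPlan
from .motifs import Motif, revcomp

DEFAULT_AGES = (10, 20, 25, 30, 40)

# Quadratic trajectory templates q(u) over u = (age - 10) / 30, later
# min-max normalized over the sampled ages. Shapes chosen so that the
# direction/timing classifier recovers the stated labels and the
# max-normalized linear profiles of distinct templates are separable.
TRAJECTORY_TEMPLATES: dict[str, dict] = {
    "up_early_1": {"direction": "up", "timing": "early", "coef": (0.0, 2.0, -1.0)},
    "up_early_2": {"direction": "up", "timing": "early", "coef": (0.0, 2.4, -1.4)},
    "up_middle_1": {"direction": "up", "timing": "middle", "coef": (0.0, 1.0, 0.0)},
    "up_middle_2": {"direction": "up", "timing": "middle", "coef": (0.0, 0.65, 0.35)},
    "up_late_1": {"direction": "up", "timing": "late", "coef": (0.0, 0.0, 1.0)},
    "up_late_2": {"direction": "up", "timing": "late", "coef": (0.04, -0.4, 1.0)},
    "up_late_3": {"direction": "up", "timing": "late", "coef": (0.0, 0.15, 0.85)},
    "down_early_1": {"direction": "down", "timing": "early", "coef": (0.0, 2.0, -1.0)},
    "down_early_2": {"direction": "down", "timing": "early", "coef": (0.0, 2.4, -1.4)},
    "down_middle_1": {"direction": "down", "timing": "middle", "coef": (0.0, 1.0, 0.0)},
    "down_late_1": {"direction": "down", "timing": "late", "coef": (0.0, 0.0, 1.0)},
}


def template_shape(template_id: str, ages) -> np.ndarray:
    """Normalized shape v(age) in [0, 1] of a trajectory template, evaluated
    at the sampled ages (min-max normalized over those ages)."""
    info = TRAJECTORY_TEMPLATES[template_id]
    b0, b1, b2 = info["coef"]
    u = (np.asarray(ages, dtype=float) - 10.0) / 30.0
    q = b0 + b1 * u + b2 * u**2
    return (q - q.min()) / (q.max() - q.min())


def template_log2_profile(plan: TrajectoryPlan, ages) -> np.ndarray:
    """Expected log2 CPM at each age for a planned gene (day-10 anchored)."""
    base = np.log2(plan.baseline_mean)
    if plan.template_id is None or plan.log2_amplitude == 0:
        return np.full(len(ages), base)
    v = template_shape(plan.template_id, ages)
    sign = 1.0 if TRAJECTORY_TEMPLATES[plan.template_id]["direction"] == "up" else -1.0
    return base + sign * plan.log2_amplitude * (v - v[0])


# ---------------------------------------------------------------------------
# Gene models and genome


def make_gene_models(
    n_genes: int,
    seed: int | None = None,
    length_params: dict | None = None,
    exon_params: dict | None = None,
    isoform_params: dict | None = None,
    bias_gene_indices: set[int] | None = None,
    bias_length_factor: float = 2.5,
    bias_exon_factor: float = 2.0,
    chrom: str = "chr_sim",
    gap: int = 2000,
) -> GeneModelSet:
    """Random gene models laid head-to-tail on a synthetic chromosome.

    Genomic spans are log-normal, exon counts shifted Poisson (1 + Poisson),
    isoform counts likewise; extra isoforms are contiguous exon runs with
    Dirichlet relative abundances. With ``bias_gene_indices`` set, those
    genes get longer spans and more exons (the down-regulation bias mode
    used to plant gene-characteristic signal).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lp = {"meanlog": np.log(5000.0), "sdlog": 0.8}
    lp.update(length_params or {})
    ep = {"extra_exon_mean": 3.0, "min_exon": 30, "exonic_fraction": 0.4}
    ep.update(exon_params or {})
    ip = {"extra_isoform_mean": 0.8}
    ip.update(isoform_params or {})
    if lp["meanlog"] <= 0 or lp["sdlog"] <= 0 or ep["extra_exon_mean"] < 0:
        raise ValueError("distribution parameters must be positive")
    bias = bias_gene_indices or set()

    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    cursor = 1000
    for i in range(n_genes):
        biased = i in bias
        span = int(rng.lognormal(lp["meanlog"], lp["sdlog"]))
        if biased:
            span = int(span * bias_length_factor)
        lam = ep["extra_exon_mean"] * (bias_exon_factor if biased else 1.0)
        n_exons = 1 + int(rng.poisson(lam))
        min_exon = ep["min_exon"]
        exonic = max(n_exons * min_exon, int(ep["exonic_fraction"] * span))
        span = max(span, exonic + (n_exons - 1) * min_exon)
        # partition exonic/intronic totals with a floor per piece
        exon_lens = _partition(rng, exonic, n_exons, min_exon)
        if n_exons > 1:
            intron_lens = _partition(rng, span - exonic, n_exons - 1, min_exon)
        else:
            intron_lens = []
        exons: list[tuple[int, int]] = []
        pos = cursor
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if k < len(intron_lens):
                pos += intron_lens[k]
        n_iso = 1 + int(rng.poisson(ip["extra_isoform_mean"]))
        isoforms = [exons]
        for _ in range(n_iso - 1):
            if len(exons) == 1:
                isoforms.append(exons)
            else:
                a = int(rng.integers(0, len(exons)))
                b = int(rng.integers(a, len(exons)))
                isoforms.append(exons[a : b + 1])
        weights = rng.dirichlet(np.ones(n_iso)).tolist()
        strand = "+" if rng.random() < 0.5 else "-"
        tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:05d}",
                chrom=chrom,
                strand=strand,
                tss=tss,
                isoforms=isoforms,
                isoform_weights=weights,
            )
        )
        cursor = pos + gap
    return GeneModelSet(genes)


def _partition(rng: np.random.Generator, total: int, k: int, floor: int) -> list[int]:
    """Split ``total`` into k integer parts each >= floor."""
    if k == 1:
        return [total]
    free = total - k * floor
    w = rng.dirichlet(np.ones(k))
    parts = np.floor(w * free).astype(int)
    parts[0] += free - parts.sum()
    return (parts + floor).tolist()


def make_genome(
    models: GeneModelSet, seed: int | None = None, pad: int = 1000
) -> dict[str, str]:
    """Uniform-random genome sequence covering all gene models (per chrom)."""
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    for chrom in sorted({g.chrom for g in models}):
        end = max(g.span[1] for g in models if g.chrom == chrom) + pad
        genome[chrom] = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=end)]
        )
    return genome


# ---------------------------------------------------------------------------
# Promoters with planted motifs


def make_promoters(
    models: GeneModelSet | list[str],
    motif_library: list[Motif],
    enrichment_plan: dict[str, dict[str, float] | float],
    gene_classes: dict[str, str] | None = None,
    seed: int | None = None,
    window: int = 500,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Promoter windows (2*window + 1 nt, TSS-centered) with planted motifs.

    ``enrichment_plan`` maps motif name to either a single presence
    probability or per-class probabilities for ``up`` / ``down`` /
    ``background`` genes (classes from ``gene_classes``, default all
    background). Background sequence is i.i.d. uniform A/C/G/T; each planted
    instance is a concrete realization of the motif placed wholly inside the
    window on a random strand. The truth matrix records exactly the planted
    instances.
    """
    gene_ids = models.gene_ids if isinstance(models, GeneModelSet) else list(models)
    gene_classes = gene_classes or {}
    wlen = 2 * window + 1
    by_name = {m.name: m for m in motif_library}
    for name, plan in enrichment_plan.items():
        probs = [plan] if isinstance(plan, (int, float)) else list(plan.values())
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError(f"{name}: probabilities must be in [0, 1]")
        if len(by_name[name]) > wlen:
            raise ValueError(f"{name}: motif longer than promoter window")
    rng = np.random.default_rng(seed)
    letters = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    truth = pd.DataFrame(
        0, index=gene_ids, columns=[m.name for m in motif_library], dtype=np.int8
    )
    for gid in gene_ids:
        seq = rng.integers(0, 4, size=wlen)
        chars = letters[seq].tolist()
        cls = gene_classes.get(gid, "background")
        for name, plan in enrichment_plan.items():
            p = plan if isinstance(plan, (int, float)) else plan.get(cls, 0.0)
            if rng.random() < p:
                inst = by_name[name].consensus(rng)
                if rng.random() < 0.5:
                    inst = revcomp(inst)
                start = int(rng.integers(0, wlen - len(inst) + 1))
                chars[start : start + len(inst)] = list(inst)
                truth.loc[gid, name] = 1
        promoters[gid] = "".join(chars)
    return promoters, truth


# ---------------------------------------------------------------------------
# Time-course counts


def make_design(
    ages=DEFAULT_AGES, n_replicates: int = 3, lib_sizes=None
) -> pd.DataFrame:
    """Design table for an ages x replicates layout."""
    rows = []
    for age in ages:
        for rep in range(1, n_replicates + 1):
            rows.append({"sample_id": f"d{age}_r{rep}", "age": age, "replicate": rep})
    design = pd.DataFrame(rows).set_index("sample_id")
    if lib_sizes is not None:
        design["library_size"] = np.asarray(lib_sizes, dtype=float)
    return design


def make_trajectory_plans(
    gene_ids: list[str],
    frac_regulated: float = 0.1,
    seed: int | None = None,
    baseline_meanlog: float = np.log(50.0),
    baseline_sdlog: float = 1.2,
    amplitude_range: tuple[float, float] = (1.5, 3.0),
    dispersion: float = 0.1,
    templates: list[str] | None = None,
) -> list[TrajectoryPlan]:
    """Assign quadratic templates to a random subset of genes.

    Regulated genes cycle round-robin through the trajectory templates with
    amplitudes drawn uniformly from ``amplitude_range``; all other genes are
    flat. Baseline day-10 CPM is log-normal.
    """
    rng = np.random.default_rng(seed)
    templates = templates or list(TRAJECTORY_TEMPLATES)
    n = len(gene_ids)
    n_reg = int(round(frac_regulated * n))
    reg_idx = set(rng.choice(n, size=n_reg, replace=False).tolist())
    plans = []
    j = 0
    for i, gid in enumerate(gene_ids):
        baseline = float(rng.lognormal(baseline_meanlog, baseline_sdlog))
        if i in reg_idx:
            tid = templates[j % len(templates)]
            j += 1
            amp = float(rng.uniform(*amplitude_range))
        else:
            tid, amp = None, 0.0
        plans.append(
            TrajectoryPlan(
                gene_id=gid,
                template_id=tid,
                baseline_mean=baseline,
                log2_amplitude=amp,
                dispersion=dispersion,
            )
        )
    return plans


def simulate_timecourse_counts(
    plans: list[TrajectoryPlan],
    design: pd.DataFrame,
    lib_sizes=None,
    seed: int | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts following the planned trajectories.

    The expected CPM of a gene at age t is its day-10 baseline scaled by
    2^(sign * amplitude * shape(t)); the expected count scales with library
    size. Counts are gamma-Poisson (NB) draws with the planned dispersion.
    Returns the count matrix and the truth table of planted labels.
    """
    rng = np.random.default_rng(seed)
    ages = design["age"].to_numpy()
    n_s = len(design)
    if lib_sizes is None:
        lib_sizes = design.get("library_size")
        if lib_sizes is None:
            # ~32M reads per library, the depth of the emulated experiment
            lib_sizes = 32e6 * rng.uniform(0.8, 1.2, size=n_s)
        else:
            lib_sizes = lib_sizes.to_numpy()
    else:
        lib_sizes = np.asarray(lib_sizes, dtype=float)
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    counts = np.empty((len(plans), n_s), dtype=np.int64)
    truth_rows = []
    for i, plan in enumerate(plans):
        log2cpm = template_log2_profile(plan, ages)
        mu = 2.0**log2cpm * lib_sizes / 1e6
        shape = 1.0 / plan.dispersion
        lam = rng.gamma(shape, mu / shape)
        counts[i] = rng.poisson(lam)
        info = TRAJECTORY_TEMPLATES.get(plan.template_id, {})
        truth_rows.append(
            {
                "gene_id": plan.gene_id,
                "regulated": plan.template_id is not None,
                "template_id": plan.template_id,
                "direction": info.get("direction"),
                "timing": info.get("timing"),
                "baseline_mean": plan.baseline_mean,
                "log2_amplitude": plan.log2_amplitude,
            }
        )
    counts_df = pd.DataFrame(
        counts, index=[p.gene_id for p in plans], columns=design.index
    )
    dsn = design.copy()
    dsn["library_size"] = lib_sizes
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return CountMatrix(counts_df, dsn), truth


def assign_isoform_exon_counts(
    models: GeneModelSet, cm: CountMatrix, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split gene counts into isoform and union-exon counts.

    Each sample's gene count is split multinomially across isoforms by the
    model's isoform weights; a union exon's count is the sum over isoforms
    whose structure includes it. Indexes are (gene_id, isoform) and
    (gene_id, exon).
    """
    rng = np.random.default_rng(seed)
    iso_rows, iso_idx = [], []
    exon_rows, exon_idx = [], []
    for gene in models:
        if gene.gene_id not in cm.counts.index:
            continue
        gc = cm.counts.loc[gene.gene_id].to_numpy()
        w = np.asarray(gene.isoform_weights)
        iso_counts = np.vstack([rng.multinomial(int(c), w) for c in gc]).T
        for k in range(len(gene.isoforms)):
            iso_rows.append(iso_counts[k])
            iso_idx.append((gene.gene_id, k))
        for e, iv in enumerate(gene.union_exons()):
            member = np.array(
                [any(s < iv[1] and iv[0] < t for s, t in iso)
                 for iso in gene.isoforms]
            )
            exon_rows.append(iso_counts[member].sum(axis=0))
            exon_idx.append((gene.gene_id, e))
    iso_df = pd.DataFrame(
        iso_rows,
        index=pd.MultiIndex.from_tuples(iso_idx, names=["gene_id", "isoform"]),
        columns=cm.counts.columns,
    )
    exon_df = pd.DataFrame(
        exon_rows,
        index=pd.MultiIndex.from_tuples(exon_idx, names=["gene_id", "exon"]),
        columns=cm.counts.columns,
    )
    return iso_df, exon_df


# ---------------------------------------------------------------------------
# circRNA junction reads


def spliced_sequence(
    genome: dict[str, str], chrom: str, exons: list[tuple[int, int]], strand: str
) -> str:
    """Exonic sequence of sorted genomic intervals, in transcript
    orientation (reverse-complemented for minus strand)."""
    seq = "".join(genome[chrom][s:e] for s, e in exons)
    return revcomp(seq) if strand == "-" else seq


def circle_sequence(
    gene: GeneModel, genome: dict[str, str], start: int, end: int
) -> str:
    """Spliced sequence of the circularized interval [start, end) of a gene,
    in transcript orientation."""
    parts = []
    for s, e in gene.union_exons():
        s2, e2 = max(s, start), min(e, end)
        if s2 < e2:
            parts.append((s2, e2))
    if not parts:
        raise ValueError("circle interval covers no exonic sequence")
    return spliced_sequence(genome, gene.chrom, parts, gene.strand)


def make_circ_plans(
    models: GeneModelSet,
    n_circs: int,
    seed: int | None = None,
    ages=DEFAULT_AGES,
    base_reads: int | tuple[int, int] = (3, 6),
    fold_by_last_age: float = 3.0,
) -> list[CircPlan]:
    """Plant circRNAs on multi-exon hosts with read counts rising with age.

    Expected junction reads per library grow linearly from a per-circ base
    (drawn uniformly from the ``base_reads`` range) at the first age to
    ``fold_by_last_age``-fold at the last, independent of the host's linear
    expression.
    """
    rng = np.random.default_rng(seed)
    hosts = [g for g in models if len(g.isoforms[0]) >= 2]
    if len(hosts) < n_circs:
        raise ValueError("not enough multi-exon host genes")
    chosen = rng.choice(len(hosts), size=n_circs, replace=False)
    ages = list(ages)
    plans = []
    for c, hi in enumerate(sorted(chosen.tolist())):
        g = hosts[hi]
        exons = g.isoforms[0]
        i = int(rng.integers(0, len(exons) - 1))
        j = int(rng.integers(i + 1, len(exons)))
        if isinstance(base_reads, tuple):
            base = int(rng.integers(base_reads[0], base_reads[1] + 1))
        else:
            base = int(base_reads)
        reads = {
            age: int(round(base * (1 + (fold_by_last_age - 1)
                                   * (age - ages[0]) / (ages[-1] - ages[0]))))
            for age in ages
        }
        plans.append(
            CircPlan(
                circ_id=f"circ{c + 1:04d}",
                gene_id=g.gene_id,
                start=exons[i][0],
                end=exons[j][1],
                reads_per_age=reads,
            )
        )
    return plans


def simulate_circ_reads(
    models: GeneModelSet,
    genome: dict[str, str],
    plans: list[CircPlan],
    design: pd.DataFrame,
    read_length: int = 50,
    seed: int | None = None,
    min_overlap: int = 15,
    scaffold_take: int = 85,
    boundary_reads: int = 0,
    duplicate_fraction: float = 0.0,
    n_decoys: int = 0,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame, pd.DataFrame]:
    """Junction-spanning reads per library, with a read-level truth table.

    Each junction read is a substring of the circular transcript crossing
    the back-splice point, with at least ``min_overlap`` nt on each side and
    within the +/- ``scaffold_take`` nt scaffold flanks; offsets within a
    (circRNA, library) pair are drawn without replacement so noise-free
    reads are pairwise distinct. ``boundary_reads`` adds must-reject reads
    with exactly ``min_overlap - 1`` nt on one side; ``n_decoys`` adds
    random-sequence reads per library; ``duplicate_fraction`` appends
    literal PCR-style copies of existing reads. Returns per-library reads,
    the read truth table, and the expected unique accepted count table
    (circ x library).
    """
    if read_length < 2 * min_overlap:
        raise ValueError("read_length too short to satisfy the overlap rule")
    if boundary_reads and read_length < 2 * min_overlap + 1:
        raise ValueError("boundary reads need read_length >= 2*min_overlap + 1")
    rng = np.random.default_rng(seed)
    reads: dict[str, list[tuple[str, str]]] = {s: [] for s in design.index}
    rows = []
    counts = pd.DataFrame(
        0, index=[p.circ_id for p in plans], columns=design.index, dtype=int
    )
    for plan in plans:
        gene = models[plan.gene_id]
        circ = circle_sequence(gene, genome, plan.start, plan.end)
        up_take = min(scaffold_take, len(circ))
        down_take = min(scaffold_take, len(circ))
        lo = max(min_overlap, read_length - down_take)
        hi = min(read_length - min_overlap, up_take)
        if hi < lo:
            raise ValueError(f"{plan.circ_id}: circle too short for junction reads")
        capacity = hi - lo + 1
        for sample_id, srow in design.iterrows():
            n = int(plan.reads_per_age.get(int(srow["age"]), 0))
            if n > capacity:
                raise ValueError(
                    f"{plan.circ_id}: {n} reads exceed {capacity} distinct offsets"
                )
            offs = rng.choice(np.arange(lo, hi + 1), size=n, replace=False)
            for o_l in sorted(int(o) for o in offs):
                o_r = read_length - o_l
                seq = circ[-o_l:] + circ[:o_r]
                rid = f"{plan.circ_id}_{sample_id}_j{o_l}"
                reads[sample_id].append((rid, seq))
                rows.append(
                    dict(read_id=rid, sample=sample_id, circ_id=plan.circ_id,
                         overlap_left=o_l, overlap_right=o_r, accept=True,
                         is_duplicate=False, is_decoy=False)
                )
                counts.loc[plan.circ_id, sample_id] += 1
            for b in range(boundary_reads):
                o_l = min_overlap - 1 if b % 2 == 0 else read_length - min_overlap + 1
                o_r = read_length - o_l
                seq = circ[-o_l:] + circ[:o_r]
                rid = f"{plan.circ_id}_{sample_id}_b{b}"
                reads[sample_id].append((rid, seq))
                rows.append(
                    dict(read_id=rid, sample=sample_id, circ_id=plan.circ_id,
                         overlap_left=o_l, overlap_right=o_r, accept=False,
                         is_duplicate=False, is_decoy=False)
                )
    letters = np.array(list("ACGT"))
    for sample_id in design.index:
        for d in range(n_decoys):
            seq = "".join(letters[rng.integers(0, 4, size=read_length)])
            rid = f"decoy_{sample_id}_{d}"
            reads[sample_id].append((rid, seq))
            rows.append(
                dict(read_id=rid, sample=sample_id, circ_id=None,
                     overlap_left=0, overlap_right=0, accept=False,
                     is_duplicate=False, is_decoy=True)
            )
        lib = reads[sample_id]
        n_dup = int(np.floor(duplicate_fraction * len(lib)))
        if n_dup:
            picks = rng.integers(0, len(lib), size=n_dup)
            for k, pk in enumerate(picks):
                rid0, seq = lib[pk]
                rid = f"{rid0}_dup{k}"
                lib.append((rid, seq))
                src = next(r for r in rows if r["read_id"] == rid0)
                rows.append({**src, "read_id": rid, "is_duplicate": True})
    truth = pd.DataFrame(rows)
    return reads, truth, counts
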