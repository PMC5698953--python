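"""Core domain containers shared across the pipeline stages.

The pipeline revolves around a small set of objects: annotated gene models
(exon/isoform structure on a genome), a count matrix with its experimental
design (age time course with replicates), simulation plans describing the
signal planted by the synthetic-data generator, and circRNA records built
around back-splice junction scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """A gene with one or more transcript isoforms.

    Coordinates are 0-based half-open genomic positions. Exons within an
    isoform are sorted and non-overlapping; ``isoform_weights`` are relative
    abundances summing to one.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    isoforms: list[list[Interval]]
    isoform_weights: list[float]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.isoforms:
            raise ValueError(f"{self.gene_id}: gene needs at least one isoform")
        if len(self.isoform_weights) != len(self.isoforms):
            raise ValueError(f"{self.gene_id}: one weight per isoform required")
        w = np.asarray(self.isoform_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.gene_id}: weights must be >=0 and sum to 1")
        for exons in self.isoforms:
            if not exons:
                raise ValueError(f"{self.gene_id}: empty isoform")
            for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
                if not (s0 < e0 <= s1 < e1):
                    raise ValueError(
                        f"{self.gene_id}: exons must be sorted, non-overlapping"
                    )
            if exons[0][0] >= exons[0][1]:
                raise ValueError(f"{self.gene_id}: empty exon")

    @property
    def span(self) -> Interval:
        """Genomic span (first exon start, last exon end) over all isoforms."""
        starts = [iso[0][0] for iso in self.isoforms]
        ends = [iso[-1][1] for iso in self.isoforms]
        return min(starts), max(ends)

    def isoform_span_length(self, i: int) -> int:
        """Genomic span (introns included) of isoform ``i`` in nt."""
        exons = self.isoforms[i]
        return exons[-1][1] - exons[0][0]

    def union_exons(self) -> list[Interval]:
        """Merged exon intervals across all isoforms."""
        ivs = sorted(iv for iso in self.isoforms for iv in iso)
        merged: list[Interval] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged


@dataclass
class GeneModelSet:
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus the per-sample design table.

    ``design`` is indexed by sample id with columns ``age`` (days),
    ``replicate`` and ``library_size``. Library size defaults to the column
    sum of the counts.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("count columns must match design rows, in order")
        if self.counts.isna().any().any():
            raise ValueError("counts must not contain missing values")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if "library_size" not in self.design.columns:
            self.design = self.design.assign(
                library_size=self.counts.sum(axis=0).to_numpy()
            )
        if (self.design["library_size"] <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.design["library_size"]

    @property
    def ages(self) -> np.ndarray:
        return np.sort(self.design["age"].unique())


@dataclass
class TrajectoryPlan:
    """Planted temporal trajectory for one gene.

    ``template_id`` selects one of the quadratic cluster templates (``None``
    for a flat, non-regulated gene); ``baseline_mean`` is the expected count
    at day 10 in a million-read library; ``log2_amplitude`` is the maximum
    absolute log2 fold change over the time course.
    """

    gene_id: str
    template_id: str | None
    baseline_mean: float
    log2_amplitude: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.template_id is None and self.log2_amplitude != 0:
            raise ValueError("non-regulated genes must have log2_amplitude = 0")


@dataclass
class CircPlan:
    """Planted circRNA: which exons circularize and how many junction reads
    to emit per age."""

    circ_id: str
    gene_id: str
    start: int  # genomic, 0-based half-open: acceptor side
    end: int  # genomic: donor side
    reads_per_age: dict[int, int]
    host_baseline: float = 100.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("circle end must exceed start")
        if any(v < 0 for v in self.reads_per_age.values()):
            raise ValueError("expected read counts must be >= 0")


@dataclass
class CircRNARecord:
    """A circRNA with its back-splice junction scaffold.

    The scaffold is the donor-side exonic flank (last ``up_take`` nt of the
    circular transcript) followed by the acceptor-side flank (first
    ``down_take`` nt); ``junction_pos`` is the index of the first base past
    the junction, i.e. ``up_take``.
    """

    circ_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    scaffold: str
    junction_pos: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.junction_pos < len(self.scaffold)):
            raise ValueError("junction must fall strictly inside the scaffold")
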