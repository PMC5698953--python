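"""Readers and writers for the pipeline's on-disk formats.

Gene models go to GTF, genomes/promoters/scaffolds to FASTA, reads to
FASTQ (Biopython), circRNA candidates to BED6 (0-based half-open), and
tabular data (counts, design, truth, results) to TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, GeneModelSet


def write_gtf(models: GeneModelSet, path) -> None:
    with open(path, "w") as fh:
        for g in models:
            s0, e1 = g.span
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tagetx\tgene\t{s0 + 1}\t{e1}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ti, exons in enumerate(g.isoforms):
                tid = f"{g.gene_id}.t{ti + 1}"
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                fh.write(
                    f"{g.chrom}\tagetx\ttranscript\t{exons[0][0] + 1}\t"
                    f"{exons[-1][1]}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in exons:
                    fh.write(
                        f"{g.chrom}\tagetx\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"{tattrs}\n"
                    )


def read_gtf(path) -> GeneModelSet:
    """Rebuild gene models from a GTF written by :func:`write_gtf`.

    Isoform weights are not stored in GTF and come back uniform.
    """
    tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, _, feat, start, end, _, strand, _, attrs = line.rstrip(
                "\n"
            ).split("\t")
            if feat != "exon":
                continue
            fields = dict(
                kv.strip().split(" ", 1)
                for kv in attrs.strip().strip(";").split(";")
            )
            gid = fields["gene_id"].strip('"')
            tid = fields["transcript_id"].strip('"')
            if gid not in tx:
                tx[gid] = {"chrom": chrom, "strand": strand, "isoforms": {}}
                order.append(gid)
            tx[gid]["isoforms"].setdefault(tid, []).append(
                (int(start) - 1, int(end))
            )
    genes = []
    for gid in order:
        info = tx[gid]
        isoforms = [sorted(v) for _, v in sorted(info["isoforms"].items())]
        n = len(isoforms)
        span_lo = min(iso[0][0] for iso in isoforms)
        span_hi = max(iso[-1][1] for iso in isoforms)
        tss = span_lo if info["strand"] == "+" else span_hi - 1
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=info["chrom"],
                strand=info["strand"],
                tss=tss,
                isoforms=isoforms,
                isoform_weights=[1.0 / n] * n,
            )
        )
    return GeneModelSet(genes)


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_circ_bed(circs, path) -> None:
    """BED6 of circRNA candidates: (circ_id, chrom, start, end, strand)."""
    with open(path, "w") as fh:
        for c in circs:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.circ_id}\t0\t{c.strand}\n")


def read_circ_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "circ_id", "score", "strand"],
    )


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
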