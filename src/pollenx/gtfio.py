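"""Readers/writers for the file formats the pipeline consumes and emits.

GTF/GFF3/BED parsing is delegated to :mod:`pyranges`; this module only
converts between its 0-based frames and the package's domain types, and
formats output lines (re-emitting 1-based inclusive coordinates).
"""

from __future__ import annotations

from pathlib import Path

import pyranges as pr
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import AnnotationSet, GenomicInterval, TranscriptModel


# ---------------------------------------------------------------- GTF

def read_transcript_gtf(path: str | Path) -> list[TranscriptModel]:
    """Load cuffmerge-style transcript models (exon rows, XLOC/TCONS tags)."""
    df = pr.read_gtf(str(path)).df
    df = df[df.Feature == "exon"]
    if df.empty:
        return []
    models: list[TranscriptModel] = []
    for (tcons, xloc), grp in sorted(
        df.groupby(["transcript_id", "gene_id"], observed=True), key=lambda kv: kv[0]
    ):
        strands = set(grp.Strand.astype(str))
        strand = strands.pop() if len(strands) == 1 else "."
        exons = [
            GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End), strand)
            for r in grp.itertuples()
        ]
        models.append(
            TranscriptModel(tcons_id=tcons, exons=exons, strand=strand, xloc_id=xloc)
        )
    return models


def write_transcript_gtf(
    transcripts: list[TranscriptModel], path: str | Path, source: str = "pollenx"
) -> None:
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.tcons_id)):
            xloc = t.xloc_id or t.tcons_id
            attrs = f'gene_id "{xloc}"; transcript_id "{t.tcons_id}";'
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------- GFF3 / BED

def read_annotation(path: str | Path, default_biotype: str = "protein_coding") -> AnnotationSet:
    """Load a reference annotation (GFF3 with a ``biotype`` attribute, or BED).

    Features lacking a biotype attribute get ``default_biotype`` (for TE
    files pass ``default_biotype='TE'``).
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pr.read_bed(str(path)).df
        biotypes = [default_biotype] * len(df)
    else:
        df = pr.read_gff3(str(path)).df
        df = df[df.Feature.isin(["gene", "transposable_element"])]
        if "biotype" in df.columns:
            biotypes = [
                b if isinstance(b, str) and b else default_biotype for b in df.biotype
            ]
        else:
            biotypes = [default_biotype] * len(df)
    feats = []
    for (_, r), biotype in zip(df.iterrows(), biotypes):
        strand = str(r.Strand) if "Strand" in df.columns and str(r.Strand) in "+-" else "."
        feats.append(
            (GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End), strand), biotype)
        )
    return AnnotationSet(feats)


def write_annotation_gff3(
    annset: AnnotationSet, path: str | Path, source: str = "pollenx"
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, (iv, biotype) in enumerate(
            sorted(annset.features, key=lambda f: (f[0].chrom, f[0].start)), start=1
        ):
            ftype = "transposable_element" if biotype == "TE" else "gene"
            fh.write(
                f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={ftype}{k:05d};biotype={biotype}\n"
            )


# ---------------------------------------------------------------- FASTA

def read_genome(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def spliced_sequence(t: TranscriptModel, genome: dict[str, str]) -> str:
    """Exon-concatenated sequence, reverse-complemented on the minus strand.

    Unknown-strand transcripts are returned in genome (plus) orientation;
    downstream ORF scans handle both strands in that case.
    """
    chrom_seq = genome[t.chrom]
    seq = "".join(chrom_seq[e.start:e.end] for e in t.exons)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
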