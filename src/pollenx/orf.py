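"""ORF detection, transcript biotype classification and homology binning.

The biotype rules follow the common operational definition of plant long
noncoding RNAs: a transcript is *short* below 200 nt; with an ORF of at
least 100 codons it is treated as potentially protein coding; otherwise it
is a lncRNA, and a lncRNA at least 500 bp from any annotated
protein-coding gene that does not overlap a transposable element is the
intergenic subclass (lincRNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

START = "ATG"
STOPS = {"TAA", "TAG", "TGA"}

BIOTYPE_CLASSES = ("short", "lncRNA", "lincRNA", "orf_coding")


@dataclass(frozen=True)
class OrfHit:
    """One ATG..stop open reading frame on the scanned strand.

    ``start``/``end`` are 0-based half-open positions on the scanned
    sequence (i.e., on the reverse complement for ``strand == '-'``);
    ``end`` includes the stop codon and ``peptide_length`` excludes it.
    """

    frame: int
    strand: str
    start: int
    end: int
    peptide_length: int

    def __post_init__(self) -> None:
        if self.end - self.start != 3 * (self.peptide_length + 1):
            raise ValueError("ORF span inconsistent with peptide length")


def _scan_forward(seq: str, strand: str) -> list[OrfHit]:
    hits: list[OrfHit] = []
    n = len(seq)
    for frame in range(3):
        orf_start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if orf_start is None:
                if codon == START:
                    orf_start = pos
            elif codon in STOPS:
                hits.append(
                    OrfHit(
                        frame=frame,
                        strand=strand,
                        start=orf_start,
                        end=pos + 3,
                        peptide_length=(pos - orf_start) // 3,
                    )
                )
                orf_start = None
        # open-ended ORFs (no in-frame stop) are not reported
    return hits


def find_orfs(sequence: str, strand_mode: str = "both") -> list[OrfHit]:
    """All bounded ATG..stop ORFs, longest per stop within each frame.

    Codons containing N never match the start or a stop, so they extend
    the current ORF scan without terminating it.  ``strand_mode='both'``
    (the default, appropriate for non-strand-specific libraries) also
    scans the reverse complement.
    """
    if strand_mode not in ("both", "forward"):
        raise ValueError("strand_mode must be 'both' or 'forward'")
    seq = sequence.upper().replace("U", "T")
    if not seq:
        return []
    hits = _scan_forward(seq, "+")
    if strand_mode == "both":
        hits += _scan_forward(str(Seq(seq).reverse_complement()), "-")
    return hits


def longest_orf_aa(orfs: list[OrfHit]) -> int:
    return max((o.peptide_length for o in orfs), default=0)


@dataclass(frozen=True)
class BiotypeCall:
    biotype: str
    longest_orf_aa: int
    spliced_length: int
    distance_to_gene: int | None
    te_overlap: bool

    @property
    def is_lncrna(self) -> bool:
        """lincRNA is a subclass of lncRNA."""
        return self.biotype in ("lncRNA", "lincRNA")


def classify_biotype(
    spliced_length: int,
    orfs: list[OrfHit],
    distance_to_gene: int | None,
    te_flag: bool,
    short_max_nt: int = 200,
    orf_min_aa: int = 100,
    linc_min_distance: int = 500,
) -> BiotypeCall:
    """Assign one of short / orf_coding / lncRNA / lincRNA.

    A transcript shorter than ``short_max_nt`` is 'short' (exactly 200 nt
    ties are resolved toward lncRNA); otherwise an ORF of >= ``orf_min_aa``
    codons makes it 'orf_coding'; remaining transcripts are lncRNAs, with
    the lincRNA subclass requiring distance >= ``linc_min_distance`` from
    protein-coding genes and no exonic TE overlap.
    """
    longest = longest_orf_aa(orfs)
    if spliced_length < short_max_nt:
        biotype = "short"
    elif longest >= orf_min_aa:
        biotype = "orf_coding"
    else:
        if distance_to_gene is None:
            raise ValueError(
                "distance_to_gene required to resolve the lincRNA subclass"
            )
        if distance_to_gene >= linc_min_distance and not te_flag:
            biotype = "lincRNA"
        else:
            biotype = "lncRNA"
    return BiotypeCall(
        biotype=biotype,
        longest_orf_aa=longest,
        spliced_length=spliced_length,
        distance_to_gene=distance_to_gene,
        te_overlap=te_flag,
    )


@dataclass(frozen=True)
class HomologyCall:
    """Best protein-homology evidence for a locus, binned by identity."""

    bin: str  # none | partial | full
    best_identity: float | None = None
    best_evalue: float | None = None


NO_HOMOLOGY = HomologyCall(bin="none")


def parse_homology_table(
    path_or_df: str | Path | pd.DataFrame,
    evalue_max: float = 1e-7,
    partial_min_identity: float = 50.0,
    full_min_identity: float = 97.0,
) -> dict[str, HomologyCall]:
    """Bin tabular (blastx-style) hits per query into none/partial/full.

    Expected columns: qseqid, sseqid, pident, evalue (extra columns are
    ignored).  Rows failing ``evalue_max`` are dropped before binning; the
    best remaining hit per query is chosen by lowest E-value, then highest
    identity.  Identity bins: < 50 none, [50, 97) partial, >= 97 full.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(
            path_or_df,
            sep="\t",
            comment="#",
            header=None,
            names=["qseqid", "sseqid", "pident", "evalue"],
            usecols=[0, 1, 2, 3],
            dtype={"qseqid": str, "sseqid": str},
        )
    for col in ("pident", "evalue"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"malformed {col} value in hit table at data line {line}")
        df[col] = coerced
    df = df.dropna(subset=["pident", "evalue"])

    calls: dict[str, HomologyCall] = {}
    kept = df[df.evalue <= evalue_max]
    for qseqid, grp in kept.groupby("qseqid", sort=False):
        best = grp.sort_values(["evalue", "pident"], ascending=[True, False]).iloc[0]
        identity = float(best.pident)
        if identity >= full_min_identity:
            b = "full"
        elif identity >= partial_min_identity:
            b = "partial"
        else:
            b = "none"
        calls[str(qseqid)] = HomologyCall(
            bin=b, best_identity=identity, best_evalue=float(best.evalue)
        )
    return calls
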