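"""Ribosome P-site tracks, frame periodicity and translation-likelihood calls.

Elongating ribosomes advance in steps of three nucleotides, so the P-sites
inferred from ribosome-protected fragments (RPFs) of a translated ORF
pile up in one reading frame.  A transcript position with P-site signal
(count >= ``pf_min_count``) is a periodic-footprint (PF) P-site; PF
P-sites are tallied per frame relative to an anchor position, and a
transcript with at least five PF P-sites in one frame — among those with
RPF coverage of at least 1 RPM — is called likely translated.  Raw-count
thresholding stands in for wavelet denoising of the P-site signal; the
decision rule itself consumes only per-frame PF counts, and the threshold
is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest


@dataclass
class PsiteTrack:
    """Per-nucleotide P-site counts on one transcript."""

    transcript_id: str
    counts: np.ndarray  # length = transcript length, non-negative integers
    library_total: int  # total reads of the RPF library (RPM denominator)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("P-site counts must be non-negative")
        if self.library_total <= 0:
            raise ValueError("library_total must be positive")

    @property
    def total_rpf_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def rpm(self) -> float:
        return self.total_rpf_reads / self.library_total * 1e6


def assign_psites(
    read_positions: pd.DataFrame,
    offset_table: dict[int, int],
    transcript_id: str,
    transcript_length: int,
    library_total: int,
) -> tuple[PsiteTrack, int]:
    """P-site track from RPF 5'-end positions and a length->offset table.

    ``read_positions`` needs columns ``position`` (0-based 5' end on the
    transcript) and ``length``.  The P-site of a read is its 5' end plus
    the offset for its length; reads with lengths absent from the table,
    or whose P-site falls off the transcript, are dropped and counted in
    the second return value.
    """
    counts = np.zeros(transcript_length, dtype=np.int64)
    dropped = 0
    for row in read_positions.itertuples():
        offset = offset_table.get(int(row.length))
        if offset is None:
            dropped += 1
            continue
        p = int(row.position) + offset
        if 0 <= p < transcript_length:
            counts[p] += 1
        else:
            dropped += 1
    return PsiteTrack(transcript_id, counts, library_total), dropped


def pf_frame_counts(
    track: PsiteTrack, frame_anchor: int = 0, pf_min_count: int = 1
) -> tuple[int, int, int]:
    """Number of PF P-site *positions* (not reads) in each frame.

    Frame of a position is ``(position - frame_anchor) mod 3``; a PF
    P-site is a position with count >= ``pf_min_count``.
    """
    positions = np.flatnonzero(track.counts >= pf_min_count)
    frames = (positions - frame_anchor) % 3
    return tuple(int((frames == f).sum()) for f in range(3))


@dataclass
class TranslationCall:
    transcript_id: str
    rpf_rpm: dict[str, float]  # per condition
    pf_counts: tuple[int, int, int]
    dominant_frame: int | None
    considered: bool
    translated: bool
    multi_frame: bool
    periodicity_p: float | None = field(default=None)


def call_translation(
    tracks: dict[str, PsiteTrack],
    frame_anchor: int = 0,
    min_pf: int = 5,
    rpf_rpm_min: float = 1.0,
    pf_min_count: int = 1,
) -> TranslationCall:
    """Translation-likelihood call for one transcript.

    ``tracks`` maps condition name to that condition's P-site track.  The
    transcript is considered when its RPF coverage reaches ``rpf_rpm_min``
    RPM in at least one condition; frame tallies are taken on the
    condition-summed track.  Translated: considered and the best frame has
    >= ``min_pf`` PF P-sites; multi-frame: at least two frames each reach
    ``min_pf`` (the signature of retained introns / frameshifted ORFs).
    """
    if not tracks:
        raise ValueError("need at least one condition track")
    ids = {t.transcript_id for t in tracks.values()}
    if len(ids) != 1:
        raise ValueError(f"tracks from different transcripts: {sorted(ids)}")
    rpms = {cond: t.rpm for cond, t in tracks.items()}
    considered = any(r >= rpf_rpm_min for r in rpms.values())

    lengths = {len(t.counts) for t in tracks.values()}
    if len(lengths) != 1:
        raise ValueError("condition tracks have different lengths")
    summed = PsiteTrack(
        next(iter(ids)),
        sum(t.counts for t in tracks.values()),
        max(t.library_total for t in tracks.values()),
    )
    pf = pf_frame_counts(summed, frame_anchor=frame_anchor, pf_min_count=pf_min_count)
    dominant = int(np.argmax(pf)) if any(pf) else None
    translated = considered and max(pf) >= min_pf
    multi_frame = translated and sum(c >= min_pf for c in pf) >= 2
    return TranslationCall(
        transcript_id=summed.transcript_id,
        rpf_rpm=rpms,
        pf_counts=pf,
        dominant_frame=dominant,
        considered=considered,
        translated=translated,
        multi_frame=multi_frame,
        periodicity_p=periodicity_test(*pf),
    )


def periodicity_test(f0: int, f1: int, f2: int) -> float | None:
    """Exact binomial test of max-frame PF enrichment against p = 1/3.

    Returns None (no signal) when all frames are empty.
    """
    total = f0 + f1 + f2
    if total == 0:
        return None
    return float(binomtest(max(f0, f1, f2), total, 1 / 3, alternative="two-sided").pvalue)


# ---------------------------------------------------------------- track I/O

def write_tracks(
    tracks: dict[str, dict[str, PsiteTrack]],
    lengths: dict[str, int],
    path: str | Path,
) -> None:
    """TSV with columns condition, transcript, position, count (sparse) plus
    a header line recording per-condition library totals and lengths."""
    conds = sorted(tracks)
    with open(path, "w") as fh:
        totals = {
            c: max((t.library_total for t in tracks[c].values()), default=1)
            for c in conds
        }
        fh.write("#library_totals\t" + ";".join(f"{c}={totals[c]}" for c in conds) + "\n")
        fh.write("#lengths\t" + ";".join(f"{t}={n}" for t, n in sorted(lengths.items())) + "\n")
        fh.write("condition\ttranscript\tposition\tcount\n")
        for cond in conds:
            for tid in sorted(tracks[cond]):
                tr = tracks[cond][tid]
                for pos in np.flatnonzero(tr.counts):
                    fh.write(f"{cond}\t{tid}\t{pos}\t{tr.counts[pos]}\n")


def read_tracks(path: str | Path) -> dict[str, dict[str, PsiteTrack]]:
    """Inverse of :func:`write_tracks`: condition -> transcript -> track."""
    with open(path) as fh:
        header1 = fh.readline().rstrip("\n").split("\t")
        header2 = fh.readline().rstrip("\n").split("\t")
    if header1[0] != "#library_totals" or header2[0] != "#lengths":
        raise ValueError(f"{path}: not a P-site track file")
    totals = dict(kv.split("=") for kv in header1[1].split(";")) if header1[1] else {}
    lengths = dict(kv.split("=") for kv in header2[1].split(";")) if header2[1] else {}
    df = pd.read_csv(path, sep="\t", skiprows=2)
    out: dict[str, dict[str, PsiteTrack]] = {}
    for cond, total in totals.items():
        out[cond] = {}
        block = df[df.condition == cond]
        per_tid = dict(tuple(block.groupby("transcript")))
        for tid, n in lengths.items():
            counts = np.zeros(int(n), dtype=np.int64)
            if tid in per_tid:
                rows = per_tid[tid]
                counts[rows.position.to_numpy()] = rows["count"].to_numpy()
            out[cond][tid] = PsiteTrack(tid, counts, int(total))
    return out
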