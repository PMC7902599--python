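import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenx.intervals import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    classify_novelty,
    distance_to_nearest_gene,
    group_into_loci,
    te_overlap,
)


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


class TestGenomicInterval:
    def test_rejects_bad_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, strand="x")

    def test_overlap_is_half_open(self):
        assert not iv(0, 10).overlaps(iv(10, 20))  # touching is not overlap
        assert iv(0, 11).overlaps(iv(10, 20))
        assert not iv(0, 10).overlaps(iv(0, 10, chrom="chr2"))

    def test_distance(self):
        assert iv(0, 10).distance(iv(10, 20)) == 0 + 0  # adjacent: zero gap
        assert iv(0, 10).distance(iv(15, 20)) == 5
        assert iv(15, 20).distance(iv(0, 10)) == 5
        assert iv(0, 10).distance(iv(5, 20)) == 0
        assert iv(0, 10).distance(iv(0, 10, chrom="chr2")) is None


class TestTranscriptModel:
    def test_sorts_exons_and_validates(self):
        t = TranscriptModel("T1", [iv(100, 200), iv(0, 50)])
        assert [e.start for e in t.exons] == [0, 100]
        assert t.spliced_length == 150
        assert t.span.start == 0 and t.span.end == 200

    def test_rejects_overlapping_exons(self):
        with pytest.raises(ValueError):
            TranscriptModel("T1", [iv(0, 50), iv(40, 80)])

    def test_exonic_overlap_intron_gap(self):
        # second transcript sits entirely inside the first's intron
        a = TranscriptModel("A", [iv(0, 100), iv(500, 600)])
        b = TranscriptModel("B", [iv(200, 300)])
        assert not a.exonic_overlap(b)
        c = TranscriptModel("C", [iv(250, 550)])
        assert a.exonic_overlap(c)

    def test_strand_restriction_needs_both_known(self):
        plus = TranscriptModel("P", [iv(0, 100, strand="+")], strand="+")
        minus = TranscriptModel("M", [iv(50, 150, strand="-")], strand="-")
        unk = TranscriptModel("U", [iv(50, 150)], strand=".")
        assert not plus.exonic_overlap(minus, stranded=True)
        assert plus.exonic_overlap(minus, stranded=False)
        assert plus.exonic_overlap(unk, stranded=True)
        assert minus.exonic_overlap(unk, stranded=True)


# ---------------------------------------------------------------- annotation set

@st.composite
def interval_sets(draw):
    n = draw(st.integers(1, 25))
    feats = []
    for _ in range(n):
        s = draw(st.integers(0, 5000))
        ln = draw(st.integers(1, 400))
        feats.append((GenomicInterval("chr1", s, s + ln), "protein_coding"))
    qs = draw(st.integers(0, 5400))
    ql = draw(st.integers(1, 300))
    return feats, GenomicInterval("chr1", qs, qs + ql)


@settings(max_examples=200, deadline=None)
@given(interval_sets())
def test_annotation_index_matches_linear_scan(case):
    feats, query = case
    annset = AnnotationSet(feats)
    # identical duplicate features collapse in the index, so compare sets
    linear = {(f.start, f.end) for f, _ in feats if f.overlaps(query)}
    indexed = {(f.start, f.end) for f, _ in annset.overlapping(query)}
    assert indexed == linear

    gaps = [d for d in (query.distance(f) for f, _ in feats) if d is not None]
    assert annset.nearest_distance(query) == min(gaps)


def test_nearest_distance_no_feature_on_chrom():
    annset = AnnotationSet([(iv(0, 10, chrom="chr2"), "protein_coding")])
    assert annset.nearest_distance(iv(0, 10)) is None
    with pytest.raises(ValueError):
        distance_to_nearest_gene([iv(0, 10)], annset)


# ---------------------------------------------------------------- locus grouping

def _brute_force_components(transcripts, stranded):
    """Oracle: connected components by repeated expansion."""
    n = len(transcripts)
    adj = [
        {j for j in range(n) if j != i
         and transcripts[i].exonic_overlap(transcripts[j], stranded=stranded)}
        for i in range(n)
    ]
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


@st.composite
def transcript_sets(draw):
    n = draw(st.integers(1, 20))
    ts = []
    for i in range(n):
        chrom = draw(st.sampled_from(["chr1", "chr2"]))
        strand = draw(st.sampled_from(["+", "-", "."]))
        n_ex = draw(st.integers(1, 3))
        pos = draw(st.integers(0, 3000))
        exons = []
        for _ in range(n_ex):
            ln = draw(st.integers(50, 300))
            exons.append(GenomicInterval(chrom, pos, pos + ln, strand))
            pos += ln + draw(st.integers(1, 200))
        ts.append(TranscriptModel(f"TCONS_{i:04d}", exons, strand=strand))
    return ts


@settings(max_examples=150, deadline=None)
@given(transcript_sets(), st.booleans())
def test_grouping_matches_connected_components(transcripts, stranded):
    assignment = group_into_loci(transcripts, stranded=stranded)
    got = {}
    for i, t in enumerate(transcripts):
        got.setdefault(assignment[t.tcons_id], set()).add(i)
    assert {frozenset(v) for v in got.values()} == _brute_force_components(
        transcripts, stranded
    )


def test_grouping_ids_ordered_by_leftmost():
    ts = [
        TranscriptModel("Tb", [iv(1000, 1200)]),
        TranscriptModel("Ta", [iv(0, 100)]),
        TranscriptModel("Tc", [iv(50, 150)]),
    ]
    assignment = group_into_loci(ts)
    assert assignment["Ta"] == assignment["Tc"] == "XLOC_000001"
    assert assignment["Tb"] == "XLOC_000002"


def test_grouping_is_deterministic_under_input_order():
    rng = np.random.default_rng(0)
    base = []
    for i in range(30):
        s = int(rng.integers(0, 5000))
        base.append(TranscriptModel(f"T{i}", [iv(s, s + int(rng.integers(50, 400)))]))
    a1 = group_into_loci(list(base))
    a2 = group_into_loci(list(reversed(base)))
    assert a1 == a2


# ---------------------------------------------------------------- novelty

def _annset(*spans, biotype="protein_coding"):
    return AnnotationSet([(iv(s, e), biotype) for s, e in spans])


def test_novelty_tiers():
    tair = _annset((0, 100))
    araport = _annset((0, 100), (500, 600))
    exons_known = [iv(50, 150)]
    exons_recent = [iv(550, 650)]
    exons_novel = [iv(2000, 2100)]
    assert classify_novelty(exons_known, tair, araport) == "known"
    assert classify_novelty(exons_recent, tair, araport) == "recent"
    assert classify_novelty(exons_novel, tair, araport) == "novel"


def test_novelty_te_overlap_does_not_make_known():
    tair = AnnotationSet([(iv(0, 100), "TE")])
    assert classify_novelty([iv(50, 150)], tair, tair) == "novel"


def test_te_overlap_is_exon_level():
    te = _annset((200, 300), biotype="TE")
    # TE inside the intron only
    assert not te_overlap([iv(0, 100), iv(400, 500)], te)
    assert te_overlap([iv(0, 250)], te)


def test_distance_uses_locus_span():
    genes = _annset((1000, 1100))
    assert distance_to_nearest_gene([iv(0, 100), iv(300, 400)], genes) == 600
    assert distance_to_nearest_gene([iv(950, 1050)], genes) == 0
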