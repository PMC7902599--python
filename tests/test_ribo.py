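import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from pollenx.ribo import (
    PsiteTrack,
    assign_psites,
    call_translation,
    periodicity_test,
    pf_frame_counts,
    read_tracks,
    write_tracks,
)


def _track(counts, tid="T1", lib=1_000_000):
    return PsiteTrack(tid, np.asarray(counts), lib)


def test_track_validation():
    with pytest.raises(ValueError):
        _track([-1, 0])
    with pytest.raises(ValueError):
        PsiteTrack("T", np.array([1]), 0)


def test_rpm():
    t = _track([2, 0, 3], lib=1_000_000)
    assert t.total_rpf_reads == 5
    assert t.rpm == 5.0


def test_assign_psites_offsets_and_drops():
    reads = pd.DataFrame({"position": [0, 5, 90, 3], "length": [28, 30, 28, 31]})
    offsets = {28: 12, 30: 13}
    track, dropped = assign_psites(reads, offsets, "T1", 100, 1_000_000)
    assert track.counts[12] == 1  # 0 + 12
    assert track.counts[18] == 1  # 5 + 13
    # 90 + 12 = 102 off the end -> dropped; length 31 not in table -> dropped
    assert dropped == 2
    assert track.total_rpf_reads == 2


def test_pf_frame_counts_positions_not_reads():
    counts = np.zeros(12, dtype=int)
    counts[0] = 10  # frame 0, one PF position despite 10 reads
    counts[3] = 1
    counts[4] = 2  # frame 1
    assert pf_frame_counts(_track(counts)) == (2, 1, 0)


def test_pf_frame_counts_anchor_rotation():
    counts = np.zeros(9, dtype=int)
    counts[[0, 3, 6]] = 1
    assert pf_frame_counts(_track(counts), frame_anchor=0) == (3, 0, 0)
    assert pf_frame_counts(_track(counts), frame_anchor=1) == (0, 0, 3)
    assert pf_frame_counts(_track(counts), frame_anchor=2) == (0, 3, 0)


def test_pf_min_count_threshold():
    counts = np.array([1, 0, 0, 2, 0, 0])
    assert pf_frame_counts(_track(counts), pf_min_count=2) == (1, 0, 0)


def _frame_tally_oracle(counts, anchor, min_count):
    out = [0, 0, 0]
    for pos, c in enumerate(counts):
        if c >= min_count:
            out[(pos - anchor) % 3] += 1
    return tuple(out)


def test_frame_tally_oracle_random():
    rng = np.random.default_rng(4)
    for _ in range(300):
        n = int(rng.integers(3, 200))
        counts = rng.poisson(0.3, size=n)
        anchor = int(rng.integers(0, 3))
        mc = int(rng.integers(1, 3))
        got = pf_frame_counts(_track(counts), frame_anchor=anchor, pf_min_count=mc)
        assert got == _frame_tally_oracle(counts, anchor, mc)


# ---------------------------------------------------------------- calls

def _signal_track(n_codons=30, lib=1_000_000):
    counts = np.zeros(n_codons * 3, dtype=int)
    counts[::3] = 2  # clean frame-0 signal, n_codons PF positions
    return _track(counts, lib=lib)


def test_translated_call():
    c = call_translation({"control": _signal_track()})
    assert c.considered and c.translated and not c.multi_frame
    assert c.dominant_frame == 0
    assert c.periodicity_p < 1e-6


def test_not_considered_below_rpm():
    # 60 reads in a 1e9 library -> 0.06 RPM < 1
    c = call_translation({"control": _signal_track(lib=1_000_000_000)})
    assert not c.considered and not c.translated


def test_translated_needs_min_pf():
    counts = np.zeros(12, dtype=int)
    counts[[0, 3, 6, 9]] = 5  # only 4 PF positions in frame 0
    c = call_translation({"control": _track(counts)})
    assert c.considered and not c.translated
    counts2 = np.zeros(15, dtype=int)
    counts2[[0, 3, 6, 9, 12]] = 5
    assert call_translation({"control": _track(counts2)}).translated


def test_multi_frame_detection():
    counts = np.zeros(30, dtype=int)
    counts[0::3] = 3
    counts[1::3] = 3
    c = call_translation({"control": _track(counts)})
    assert c.translated and c.multi_frame


def test_frames_tallied_on_condition_sum():
    # each condition alone has 3 PF positions (< 5); the union has 6
    a = np.zeros(18, dtype=int)
    b = np.zeros(18, dtype=int)
    a[[0, 3, 6]] = 2
    b[[9, 12, 15]] = 2
    c = call_translation({"control": _track(a), "HS": _track(b)})
    assert c.pf_counts == (6, 0, 0)
    assert c.translated


def test_call_requires_matching_transcripts():
    with pytest.raises(ValueError):
        call_translation({"a": _track([1] * 9, tid="T1"), "b": _track([1] * 9, tid="T2")})


def test_periodicity_test():
    assert periodicity_test(0, 0, 0) is None
    p = periodicity_test(10, 0, 0)
    assert p == pytest.approx(
        binomtest(10, 10, 1 / 3, alternative="two-sided").pvalue
    )
    assert periodicity_test(4, 3, 3) > 0.5


# ---------------------------------------------------------------- I/O

def test_track_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    lengths = {"T1": 40, "T2": 25}
    tracks = {
        cond: {
            tid: PsiteTrack(tid, rng.poisson(0.4, size=n), lib)
            for tid, n in lengths.items()
        }
        for cond, lib in (("control", 1_000_000), ("HS", 1_500_000))
    }
    path = tmp_path / "tracks.tsv"
    write_tracks(tracks, lengths, path)
    back = read_tracks(path)
    for cond in tracks:
        for tid in lengths:
            assert np.array_equal(back[cond][tid].counts, tracks[cond][tid].counts)
            assert back[cond][tid].library_total == tracks[cond][tid].library_total


def test_read_tracks_rejects_other_files(tmp_path):
    p = tmp_path / "x.tsv"
    p.write_text("a\tb\n1\t2\n")
    with pytest.raises(ValueError):
        read_tracks(p)
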