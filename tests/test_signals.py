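"""NLS pattern scanners, NES scoring and the signal classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from nucloc.records import LocClass
from nucloc.signals import (
    basic_fraction,
    classify_localization,
    nes_call,
    nls_score,
    profile_sequence,
    scan_bipartite,
    scan_pat4,
    scan_pat7,
    surrogate_nes_track,
)

seq_strategy = st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=0, max_size=50)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("PKKKRKV", [1, 2, 3]),  # SV40 NLS: PKKK, KKKR, KKRK qualify; KRKV does not
        ("AAAA", []),
        ("KRK", []),  # shorter than the window
        ("KKKK", [1]),
        ("KKKX", []),  # X is neither basic nor a tolerated fourth residue
    ],
)
def test_pat4_examples(seq, expected):
    assert [m.start for m in scan_pat4(seq)] == expected


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("PKKKRKV", [1]),
        ("PAAKKKK", [1]),  # the qualifying 4-mer sits at offset 2
        ("PAAAKKK", [1]),  # the offset-3 4-mer AKKK carries 3 basic residues
        ("AAAAAAA", []),  # no proline anchor
        ("PAAAAKK", []),  # no internal 4-mer reaches 3 basic residues
    ],
)
def test_pat7_examples(seq, expected):
    assert [m.start for m in scan_pat7(seq)] == expected


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("KRPAATKKAGQAKKKKK", [1]),  # nucleoplasmin-style bipartite
        ("KAPAATAAAGQAKKKKK", []),  # second basic position broken
        ("KRPAATKKAGQAKKKK", []),  # length 16, below the 17-residue window
    ],
)
def test_bipartite_examples(seq, expected):
    assert [m.start for m in scan_bipartite(seq)] == expected


def test_match_slices_equal_sequence():
    seq = "PKKKRKVAAKRPAATKKAGQAKKKKK"
    for scan in (scan_pat4, scan_pat7, scan_bipartite):
        for m in scan(seq):
            assert m.matched_subsequence == seq[m.start - 1 : m.start - 1 + m.length]


@given(seq_strategy)
def test_scanners_match_exhaustive_enumeration(seq):
    """Each scanner equals brute-force window enumeration of its predicate."""
    assert [m.start for m in scan_pat4(seq)] == oracles.pat4_starts(seq)
    assert [m.start for m in scan_pat7(seq)] == oracles.pat7_starts(seq)
    assert [m.start for m in scan_bipartite(seq)] == oracles.bipartite_starts(seq)


def test_planted_motif_recall(rng):
    """Motifs spliced into a basic-free background are always recovered."""
    background = "ACDEGNQSTWY"
    plants = {
        "pat4": ("KKKR", scan_pat4),
        "pat7": ("PKKKRKV", scan_pat7),
        "bipartite": ("KR" + "A" * 10 + "KKKKK", scan_bipartite),
    }
    for _, (motif, scan) in plants.items():
        for _ in range(50):
            n = int(rng.integers(40, 80))
            seq = "".join(rng.choice(list(background), size=n))
            pos = int(rng.integers(0, n - len(motif) + 1))
            planted = seq[:pos] + motif + seq[pos + len(motif):]
            assert any(m.start == pos + 1 for m in scan(planted))


@pytest.mark.parametrize(
    "seq,expected",
    [("KRKR", 100.0), ("ACDE", 0.0), ("PKKKRKV", 500 / 7), ("HHHH", 0.0)],
)
def test_basic_fraction(seq, expected):
    assert basic_fraction(seq) == pytest.approx(expected)
    # the printed form of the SV40 case rounds to 71.43
    assert round(basic_fraction("PKKKRKV"), 2) == 71.43


def test_basic_fraction_empty_sequence_errors():
    with pytest.raises(ValueError):
        basic_fraction("")


@pytest.mark.parametrize(
    "counts,score,positive",
    [((0, 0, 0), -1, False), ((0, 0, 1), 1, True), ((3, 1, 0), 3, True),
     ((1, 0, 0), 0, False)],  # a single PAT4 alone does not clear the base offset
)
def test_nls_score_defaults(counts, score, positive):
    s = nls_score(*counts)
    assert s == score and (s > 0) is positive


def test_nls_score_matches_scan_counts():
    """The SV40-style NLS yields counts (3,1,0) and a positive score."""
    seq = "PKKKRKV"
    s = nls_score(len(scan_pat4(seq)), len(scan_pat7(seq)), len(scan_bipartite(seq)))
    assert s == 3 and s > 0


def test_surrogate_nes_track_anchor_positions():
    track = surrogate_nes_track("LAALAALAL")
    assert list(np.flatnonzero(track) + 1) == [1, 4, 7, 9]
    assert not surrogate_nes_track("AAAAAAAA").any()
    assert not surrogate_nes_track("LL").any()


@given(st.text(alphabet="ALIVFMG", min_size=0, max_size=40))
def test_surrogate_track_matches_consensus_enumeration(seq):
    track = surrogate_nes_track(seq)
    assert set(np.flatnonzero(track)) == oracles.nes_anchor_positions(seq)


@pytest.mark.parametrize(
    "positions,n,positive",
    [
        ([1, 5, 9], 10, True),  # span 9 fits a 15-window
        ([1, 20, 40], 45, False),
        ([1, 15, 16], 20, False),  # windows 1-15 and 2-16 each hold only two
        ([2, 15, 16], 20, True),  # span 15 exactly
    ],
)
def test_nes_call_windowed_rule(positions, n, positive):
    track = np.zeros(n)
    track[np.array(positions) - 1] = 1.0
    score, call = nes_call(track, residue_threshold=0.5)
    assert score == len(positions)
    assert call is positive


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=0, max_size=60))
def test_nes_call_matches_bruteforce_oracle(track):
    _, call = nes_call(track, residue_threshold=0.5)
    assert call == oracles.nes_positive_bruteforce(track)


@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
    st.data(),
)
def test_nes_call_monotone_under_score_increase(track, data):
    """Raising one residue's score can never turn a positive call negative."""
    _, before = nes_call(track, residue_threshold=0.5)
    i = data.draw(st.integers(0, len(track) - 1))
    bumped = list(track)
    bumped[i] = 1.0
    _, after = nes_call(bumped, residue_threshold=0.5)
    assert after or not before


def test_nes_score_additive_over_concatenation(rng):
    a, b = rng.uniform(size=20), rng.uniform(size=33)
    assert nes_call(np.concatenate([a, b]))[0] == pytest.approx(
        nes_call(a)[0] + nes_call(b)[0]
    )


@pytest.mark.parametrize(
    "nls,nes,expected",
    [
        (True, False, LocClass.NUCLEAR_RESIDENT),
        (True, True, LocClass.SHUTTLING),
        (False, True, LocClass.EXPORT_SIGNAL_ONLY),
        (False, False, LocClass.NO_SIGNAL),
    ],
)
def test_classify_localization(nls, nes, expected):
    assert classify_localization(nls, nes) is expected


def test_profile_sequence_is_internally_consistent():
    seq = "PKKKRKV" + "A" * 10 + "LAALAALAL" + "A" * 10
    prof = profile_sequence("p1", seq)
    assert prof.nls_positive and prof.nes_positive
    assert prof.loc_class is LocClass.SHUTTLING
    assert prof.nes_score == pytest.approx(prof.nes_track.sum())
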