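"""polyX / CAST / IDR detectors against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lcrevol.detectors import (
    _BLOSUM62,
    DetectorConfig,
    DisorderProfile,
    detect_all,
    disorder_adapter,
    fallback_disorder_scores,
    max_homopolymer_segment,
    predict_idr,
    scan_cbr_cast,
    scan_polyx,
    write_disorder_scores,
)
from lcrevol.seqio import AA20, Interval, Sequence, SequenceFeature

from conftest import SP, make_group, random_protein

CFG = DetectorConfig(disorder_source="adapter")


def seq(residues, sid="s"):
    return Sequence(sid, "Homo sapiens", residues)


# ---------------------------------------------------------------------------
# polyX


def polyx_oracle(residues, min_count=8, window=10):
    """Brute-force window enumeration, merge and trim."""
    n = len(residues)
    out = []
    for x in sorted(set(residues)):
        if x not in AA20:
            continue
        wins = []
        if n < window:
            if n >= min_count and residues.count(x) >= min_count:
                wins.append((0, n - 1))
        else:
            for i in range(n - window + 1):
                if residues[i : i + window].count(x) >= min_count:
                    wins.append((i, i + window - 1))
        merged = []
        for s, e in wins:
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            span = residues[s : e + 1]
            first = s + span.index(x)
            last = s + len(span) - 1 - span[::-1].index(x)
            out.append((x, first + 1, last + 1))
    return sorted(out, key=lambda t: (t[1], t[0]))


@pytest.mark.parametrize(
    "residues,expected",
    [
        # the printed HAP40 decamer: 8 prolines in a window of 10
        ("PPPPPPAPQP", [("P", 1, 10)]),
        # exact-threshold pure run in a sequence shorter than the window
        ("QQQQQQQQ", [("Q", 1, 8)]),
        # all twenty residues once: nothing
        ("ACDEFGHIKLMNPQRSTVWY", []),
        # seven of eight is below threshold
        ("QQQQQQQA", []),
        # trimming clips the leading/trailing non-repeat residues
        ("GAAAAAAAAG", [("A", 2, 9)]),
        # two disjoint repeats of different residues may both fire
        ("A" * 10 + "WCDEWCDEWCDE" + "S" * 10, [("A", 1, 10), ("S", 23, 32)]),
    ],
)
def test_scan_polyx_examples(residues, expected):
    got = [
        (f.residue, f.interval.start, f.interval.end)
        for f in scan_polyx(seq(residues), CFG)
    ]
    assert got == expected


def test_scan_polyx_short_sequences():
    assert scan_polyx(seq("QQQQQQQ"), CFG) == []  # length 7 < min_count
    assert scan_polyx(seq("QQQQQQQQQ"), CFG) != []  # 9 pure


def test_polyx_emitted_regions_satisfy_window_rule(rng):
    """Every emitted interval ends on its residue and some window inside it
    reaches the count threshold."""
    for _ in range(50):
        s = random_protein(rng, int(rng.integers(1, 120)), alphabet="AQPS")
        for f in scan_polyx(seq(s), CFG):
            x = f.residue
            sub = s[f.interval.start - 1 : f.interval.end]
            assert sub[0] == x and sub[-1] == x
            w = min(10, len(s))
            counts = [
                s[i : i + w].count(x) for i in range(0, len(s) - w + 1)
            ]
            assert max(counts) >= min(8, len(s))


def test_scan_polyx_equals_oracle_exhaustive_lengths(rng):
    """Scanner == brute-force oracle on random biased sequences covering
    every length up to 50 (plus longer samples)."""
    for n in list(range(1, 51)) + [77, 133, 400]:
        for _ in range(4):
            s = random_protein(rng, n, alphabet="AAPQS")  # A-heavy: many hits
            got = [
                (f.residue, f.interval.start, f.interval.end)
                for f in scan_polyx(seq(s), CFG)
            ]
            assert got == polyx_oracle(s), s


# ---------------------------------------------------------------------------
# CAST maximal segment


def max_segment_oracle(residues, target):
    best = None
    for i in range(len(residues)):
        total = 0.0
        for j in range(i, len(residues)):
            c = residues[j]
            total += float(_BLOSUM62[c if c in _BLOSUM62.alphabet else "X", target])
            if total > 0 and (best is None or total > best[0]):
                best = (total, i + 1, j + 1)
    return best


@pytest.mark.parametrize(
    "residues,target,expected",
    [
        ("AAAA", "A", (16.0, 1, 4)),  # 4 x BLOSUM62(A,A)=4
        ("AAAAAAAAAA", "A", (40.0, 1, 10)),  # exactly the default threshold
        ("DDDD", "A", None),  # all scores negative
        ("DDAAAADD", "A", (16.0, 3, 6)),
    ],
)
def test_max_homopolymer_segment_examples(residues, target, expected):
    got = max_homopolymer_segment(residues, target)
    if expected is None:
        assert got is None
    else:
        score, iv = got
        assert (score, iv.start, iv.end) == expected


def test_max_homopolymer_segment_rejects_nonstandard_residue():
    with pytest.raises(ValueError, match="standard amino acid"):
        max_homopolymer_segment("AAAA", "X")


def test_max_segment_equals_quadratic_oracle(rng):
    for _ in range(60):
        s = random_protein(rng, int(rng.integers(1, 40)))
        target = AA20[int(rng.integers(0, 20))]
        got = max_homopolymer_segment(s, target)
        want = max_segment_oracle(s, target)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert got[0] == want[0]  # same maximal score
            # emitted segment must itself attain that score
            sub = s[got[1].start - 1 : got[1].end]
            assert sum(float(_BLOSUM62[c, target]) for c in sub) == got[0]


# ---------------------------------------------------------------------------
# CAST iteration


def test_cast_pure_run_emits_once_and_terminates():
    feats = scan_cbr_cast(seq("A" * 10), CFG)
    assert [(f.kind, f.interval.start, f.interval.end, f.score) for f in feats] == [
        ("CBR:A", 1, 10, 40.0)
    ]


def test_cast_glutamate_run_reaches_threshold():
    # 9 x BLOSUM62(E,E)=5 -> 45 >= 40, so a 9-mer E run is emitted
    feats = scan_cbr_cast(seq("E" * 9), CFG)
    assert [(f.kind, f.score) for f in feats] == [("CBR:E", 45.0)]
    # while an 8-mer A run (8 x 4 = 32) is not
    assert scan_cbr_cast(seq("A" * 8), CFG) == []


def test_cast_no_run_no_features():
    assert scan_cbr_cast(seq("ACDEFGHIKLMNPQRSTVWY"), CFG) == []


def test_cast_masking_finds_second_region():
    """Two well-separated A-rich stretches are both emitted; masking the
    first does not erase the second."""
    spacer = "NDKTRGHM" * 6
    s = "A" * 12 + spacer + "A" * 11
    feats = scan_cbr_cast(seq(s), CFG)
    a_feats = [f for f in feats if f.kind == "CBR:A"]
    assert len(a_feats) == 2
    starts = sorted(f.interval.start for f in a_feats)
    assert starts == [1, 13 + len(spacer)]


def test_cast_terminates_and_masks_disjoint_residues(rng):
    """CAST terminates on composition-heavy sequences, every emitted segment
    holds at least one copy of its residue, and the residue occurrences
    claimed by successive emissions of the same type are disjoint."""
    for _ in range(20):
        s = random_protein(rng, 200, alphabet="AAEEPQS")
        feats = scan_cbr_cast(seq(s), CFG)
        by_res = {}
        for f in feats:
            by_res.setdefault(f.residue, []).append(f.interval)
        for x, ivs in by_res.items():
            for iv in ivs:
                assert x in s[iv.start - 1 : iv.end], (
                    "emitted segment without its residue"
                )
            assert len(ivs) <= s.count(x)


# ---------------------------------------------------------------------------
# Disorder


def test_predict_idr_threshold_and_minimum_length():
    forty = DisorderProfile("s", np.full(40, 0.9))
    (f,) = predict_idr(forty, CFG)
    assert (f.kind, f.interval.start, f.interval.end) == ("IDR", 1, 40)
    twentynine = DisorderProfile("s", np.concatenate([np.full(29, 0.9), [0.1]]))
    assert predict_idr(twentynine, CFG) == []


def test_predict_idr_equals_run_oracle(rng):
    for _ in range(40):
        scores = rng.random(int(rng.integers(1, 200)))
        prof = DisorderProfile("s", scores)
        got = [(f.interval.start, f.interval.end) for f in predict_idr(prof, CFG)]
        # brute-force run enumeration
        runs, start = [], None
        for i, v in enumerate(scores >= 0.5):
            if v and start is None:
                start = i
            if not v and start is not None:
                runs.append((start + 1, i))
                start = None
        if start is not None:
            runs.append((start + 1, len(scores)))
        assert got == [(s, e) for s, e in runs if e - s + 1 >= 30]


def test_fallback_scores_track_propensity():
    high = fallback_disorder_scores(seq("P" * 40), CFG)
    low = fallback_disorder_scores(seq("W" * 40), CFG)
    assert np.all(high.scores > 0.9)
    assert np.all(low.scores < 0.1)


def test_fallback_moving_average_hand_computed():
    """Alternating E/I 30-mer: interior scores equal the mean of the two
    scaled propensities; ends are truncated means."""
    s = "EI" * 15
    prof = fallback_disorder_scores(seq(s), CFG)
    e = (0.736 + 0.884) / (0.987 + 0.884)
    i = (-0.486 + 0.884) / (0.987 + 0.884)
    # position 11 (0-based 10): full 21-wide window, 11 E's and 10 I's
    assert prof.scores[10] == pytest.approx((11 * e + 10 * i) / 21)
    # first position: truncated window over positions 1..11 (6 E, 5 I)
    assert prof.scores[0] == pytest.approx((6 * e + 5 * i) / 11)


def test_fallback_rejects_residue_without_scale_entry():
    with pytest.raises(ValueError, match="propensity-scale"):
        fallback_disorder_scores(seq("MKVX"), CFG)


def test_disorder_adapter_round_trip(tmp_path):
    s = seq("MKVLAEPQRS", sid="P1")
    prof = DisorderProfile("P1", np.linspace(0, 1, 10))
    path = tmp_path / "P1.scores"
    write_disorder_scores(prof, s, path)
    back = disorder_adapter(path, s)
    np.testing.assert_allclose(back.scores, prof.scores, atol=1e-4)


def test_disorder_adapter_rejects_mismatched_residue(tmp_path):
    s = seq("MKV", sid="P1")
    path = tmp_path / "P1.scores"
    path.write_text("1 M 0.5\n2 Q 0.5\n3 V 0.5\n")
    with pytest.raises(ValueError, match="does not match"):
        disorder_adapter(path, s)


def test_disorder_adapter_rejects_missing_positions(tmp_path):
    s = seq("MKV", sid="P1")
    path = tmp_path / "P1.scores"
    path.write_text("1 M 0.5\n3 V 0.5\n")
    with pytest.raises(ValueError, match="missing"):
        disorder_adapter(path, s)


# ---------------------------------------------------------------------------
# detect_all


def test_detect_all_combines_sources(caplog):
    # A-run, neutral spacer, then a 35-Q run; the Q run is both a polyQ and
    # a Q-rich CBR (overlapping definitions), but no E-rich call: a segment
    # holding no glutamate at all is never emitted as E-rich even though
    # glutamines score +2 against E under BLOSUM62
    human = "A" * 12 + "NDTGWFILVYMP" * 2 + "Q" * 35
    mouse = human
    g = make_group("g", {"Homo sapiens": human, "Mus musculus": mouse})
    hid = g.members["Homo sapiens"].identifier
    mid = g.members["Mus musculus"].identifier
    cc = {hid: [SequenceFeature(hid, "CC", Interval(5, 20))],
          "NOT_IN_GROUP": [SequenceFeature("NOT_IN_GROUP", "CC", Interval(1, 4))]}
    n = len(human)
    disorder = {
        hid: DisorderProfile(hid, np.concatenate([np.full(n - 35, 0.1), np.full(35, 0.9)])),
        mid: DisorderProfile(mid, np.full(n, 0.1)),
    }
    with caplog.at_level("WARNING", logger="lcrevol"):
        feats = detect_all(g, CFG, annotations=cc, disorder=disorder)
    assert any("NOT_IN_GROUP" in r.message for r in caplog.records)
    kinds_h = sorted({f.kind for f in feats[hid]})
    assert kinds_h == ["CBR:A", "CBR:Q", "CC", "IDR", "polyX:A", "polyX:Q"]
    kinds_m = sorted({f.kind for f in feats[mid]})
    assert kinds_m == ["CBR:A", "CBR:Q", "polyX:A", "polyX:Q"]


def test_detect_all_empty_group():
    g = make_group("g", {})
    assert detect_all(g, CFG) == {}


def test_detect_all_cc_only():
    g = make_group("g", {"Homo sapiens": "ACDEFGHIKLMNPQRSTVWY"})
    hid = g.members["Homo sapiens"].identifier
    cc = {hid: [SequenceFeature(hid, "CC", Interval(1, 10))]}
    feats = detect_all(g, CFG, annotations=cc)
    assert [f.kind for f in feats[hid]] == ["CC"]
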