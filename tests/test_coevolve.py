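"""IDR column profiles, species-pair Jaccard scores and profile clustering."""

import numpy as np
import pytest

from lcrevol.coevolve import (
    FragmentSpec,
    PairScoreProfile,
    cluster_profiles,
    default_htt_fragments,
    fragment_pair_profiles,
    idr_column_profile,
    pair_jaccard_profile,
    profile_distance,
    split_fragments,
)
from lcrevol.seqio import Interval, SequenceFeature
from lcrevol.synth import gen_profile_archetypes, rand_index

from conftest import SP, make_group

N_PAIRS = 45


def idr(sid, s, e):
    return SequenceFeature(sid, "IDR", Interval(s, e))


# ---------------------------------------------------------------------------
# Column profiles


def test_idr_column_profile_full_and_empty():
    full = idr_column_profile("ACDEF", [idr("s", 1, 5)])
    assert full.tolist() == [1, 1, 1, 1, 1]
    assert idr_column_profile("ACDEF", []).tolist() == [0] * 5


def test_idr_column_profile_gap_aware_hand_case():
    # sequence positions: A=1 C=2 G=3 T=4; IDR at 2-3 -> columns 2 and 5
    prof = idr_column_profile("AC--GT", [idr("s", 2, 3)])
    assert prof.tolist() == [0, 1, 0, 0, 1, 0]


def test_pair_profile_informative_rules():
    g = make_group(
        "g",
        {
            "Homo sapiens": "AAAACCCC",
            "Pan troglodytes": "AAAACCCC",
            "Mus musculus": "AAAACCCC",
        },
    )
    hid = g.members["Homo sapiens"].identifier
    pid = g.members["Pan troglodytes"].identifier
    feats = {hid: [idr(hid, 1, 4)], pid: [idr(pid, 1, 4)]}  # mouse: no IDRs
    prof = pair_jaccard_profile(g, feats)
    pairs = g.panel.pairs()
    scores = dict(zip(pairs, prof.scores))
    assert scores[("Homo sapiens", "Pan troglodytes")] == 1.0
    # one side empty, other not: informative zero
    assert scores[("Homo sapiens", "Mus musculus")] == 0.0
    # absent species: non-informative
    assert np.isnan(scores[("Homo sapiens", "Danio rerio")])
    n_present_pairs = 3
    assert int(prof.informative.sum()) == n_present_pairs


def test_pair_profile_both_empty_is_non_informative():
    g = make_group(
        "g", {"Homo sapiens": "AAAA", "Mus musculus": "AAAA"}
    )
    prof = pair_jaccard_profile(g, {})
    assert np.isnan(prof.scores).all()


def test_pair_profile_partial_overlap_hand_computed():
    g = make_group(
        "g",
        {"Homo sapiens": "AAAAAAAA", "Mus musculus": "AAAAAAAA"},
    )
    hid = g.members["Homo sapiens"].identifier
    mid = g.members["Mus musculus"].identifier
    feats = {hid: [idr(hid, 1, 6)], mid: [idr(mid, 4, 8)]}
    prof = pair_jaccard_profile(g, feats)
    scores = dict(zip(g.panel.pairs(), prof.scores))
    # intersection 4-6 (3 columns), union 1-8 (8 columns)
    assert scores[("Homo sapiens", "Mus musculus")] == pytest.approx(3 / 8)


# ---------------------------------------------------------------------------
# Fragments


def test_default_htt_fragments_tile_the_sequence():
    frags = default_htt_fragments()
    assert frags[0].interval.start == 1
    assert frags[-1].interval.end == 3142
    for a, b in zip(frags, frags[1:]):
        assert b.interval.start == a.interval.end + 1


def test_split_fragments_hand_case():
    g = make_group(
        "g",
        {
            "Homo sapiens": "AC--GTAC",
            "Mus musculus": "ACGGGTAC",
        },
    )
    frags = [
        FragmentSpec("n", Interval(1, 2)),  # human 1-2 -> columns 1-2
        FragmentSpec("c", Interval(3, 6)),  # human 3-6 -> columns 5-8
    ]
    out = split_fragments(g, frags)
    assert [fg.alignment_length for _, fg in out] == [2, 4]
    assert out[0][1].members["Mus musculus"].aligned == "AC"
    assert out[1][1].members["Homo sapiens"].aligned == "GTAC"
    # slices keep every species, even if fully gapped in the slice
    g2 = make_group(
        "g2", {"Homo sapiens": "ACGT", "Mus musculus": "AC--"}
    )
    out2 = split_fragments(g2, [FragmentSpec("c", Interval(3, 4))])
    assert out2[0][1].members["Mus musculus"].aligned == "--"


def test_split_fragments_exceeding_human_length_errors():
    g = make_group("g", {"Homo sapiens": "ACGT"})
    with pytest.raises(ValueError, match="exceeds"):
        split_fragments(g, [FragmentSpec("x", Interval(1, 10))])


def test_fragment_profiles_slice_full_length_idrs():
    g = make_group(
        "g",
        {"Homo sapiens": "A" * 40, "Mus musculus": "A" * 40},
    )
    hid = g.members["Homo sapiens"].identifier
    mid = g.members["Mus musculus"].identifier
    feats = {hid: [idr(hid, 1, 40)], mid: [idr(mid, 21, 40)]}
    frags = [FragmentSpec("f1", Interval(1, 20)), FragmentSpec("f2", Interval(21, 40))]
    p1, p2 = fragment_pair_profiles(g, feats, frags)
    s1 = dict(zip(g.panel.pairs(), p1.scores))
    s2 = dict(zip(g.panel.pairs(), p2.scores))
    assert s1[("Homo sapiens", "Mus musculus")] == 0.0  # mouse IDR-free here
    assert s2[("Homo sapiens", "Mus musculus")] == 1.0


# ---------------------------------------------------------------------------
# Distances and clustering


def test_profile_distance_identical_and_rescaled():
    a = PairScoreProfile("a", np.full(N_PAIRS, 0.4))
    b = PairScoreProfile("b", np.full(N_PAIRS, 0.4))
    assert profile_distance(a, b) == 0.0
    # fully informative pairs: plain Euclidean
    c = PairScoreProfile("c", np.full(N_PAIRS, 0.6))
    assert profile_distance(a, c) == pytest.approx(np.sqrt(N_PAIRS * 0.2**2))
    # pairwise deletion: masking half the coordinates leaves the rescaled
    # distance unchanged when the signal is uniform
    half = np.full(N_PAIRS, 0.6)
    half[: N_PAIRS // 2] = np.nan
    d = PairScoreProfile("d", half)
    assert profile_distance(a, d) == pytest.approx(np.sqrt(N_PAIRS * 0.2**2))


def test_profile_distance_no_shared_coordinates_max(caplog):
    left = np.full(N_PAIRS, np.nan)
    left[:10] = 0.5
    right = np.full(N_PAIRS, np.nan)
    right[10:20] = 0.5
    a, b = PairScoreProfile("a", left), PairScoreProfile("b", right)
    with caplog.at_level("WARNING", logger="lcrevol"):
        d = profile_distance(a, b)
    assert d == pytest.approx(np.sqrt(N_PAIRS))
    assert any("no informative" in r.message for r in caplog.records)


def test_identical_profiles_merge_first():
    rng = np.random.default_rng(3)
    base = rng.random(N_PAIRS)
    profiles = [
        PairScoreProfile("twin1", base.copy()),
        PairScoreProfile("twin2", base.copy()),
        PairScoreProfile("far", np.clip(base + 0.5, 0, 1)),
    ]
    res = cluster_profiles(profiles, n_clusters=2)
    assert res.labels["twin1"] == res.labels["twin2"] != res.labels["far"]
    # first linkage merge is the zero-distance twin pair
    assert res.linkage[0, 2] == 0.0


def test_cluster_input_order_invariance():
    rng = np.random.default_rng(4)
    profiles = [PairScoreProfile(f"p{i}", rng.random(N_PAIRS)) for i in range(6)]
    a = cluster_profiles(profiles, n_clusters=3)
    b = cluster_profiles(list(reversed(profiles)), n_clusters=3)
    assert a.labels == b.labels
    assert a.newick() == b.newick()


def test_two_planted_archetypes_recovered():
    rng = np.random.default_rng(5)
    arch1 = np.clip(rng.random(N_PAIRS) * 0.3, 0, 1)
    arch2 = np.clip(arch1 + 0.6, 0, 1)
    profiles, truth = gen_profile_archetypes([arch1, arch2], n_per=8, noise=0.05, seed=6)
    res = cluster_profiles(profiles, n_clusters=2)
    assert rand_index(truth, res.labels) == 1.0


def test_all_non_informative_profile_is_isolated():
    rng = np.random.default_rng(8)
    base = rng.random(N_PAIRS) * 0.2
    profiles = [
        PairScoreProfile("a", base),
        PairScoreProfile("b", np.clip(base + 0.05, 0, 1)),
        PairScoreProfile("grey", np.full(N_PAIRS, np.nan)),
    ]
    res = cluster_profiles(profiles, n_clusters=2)
    assert res.labels["a"] == res.labels["b"] != res.labels["grey"]
    # the grey profile sits at maximal distance from everything
    i = res.identifiers.index("grey")
    others = [j for j in range(3) if j != i]
    assert all(res.distances[i, j] == pytest.approx(np.sqrt(N_PAIRS)) for j in others)


def test_cluster_needs_two_profiles():
    with pytest.raises(ValueError, match="at least two"):
        cluster_profiles([PairScoreProfile("a", np.zeros(N_PAIRS))])


def test_newick_is_well_formed():
    from io import StringIO

    from Bio import Phylo

    rng = np.random.default_rng(9)
    profiles = [PairScoreProfile(f"p{i}", rng.random(N_PAIRS)) for i in range(5)]
    res = cluster_profiles(profiles)
    tree = Phylo.read(StringIO(res.newick()), "newick")
    leaves = sorted(t.name for t in tree.get_terminals())
    assert leaves == [f"p{i}" for i in range(5)]
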