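"""IDR co-evolution: per-species disorder column profiles, species-pair
Jaccard scores, fragment slicing of large proteins, and hierarchical
clustering of the resulting pair-score profiles.

For each protein (or protein fragment) every aligned sequence is reduced to
a binary vector over alignment columns — 1 where the column holds a residue
predicted to lie in an IDR, 0 at ordered residues and at gaps. Every
unordered species pair is then scored by the Jaccard similarity of the two
vectors. A pair is non-informative (serialized ``NA``) when one species is
absent from the group or when both members have empty IDR profiles; such
cells do not contribute to clustering: distances are Euclidean over the
coordinates informative in both profiles, rescaled by
``sqrt(n_pairs / n_shared)`` (the standard pairwise-deletion convention),
and agglomerated with complete linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .seqio import Interval, OrthologGroup, SequenceFeature, SpeciesPanel

log = logging.getLogger("lcrevol")

#: Default fragmentation of human Huntingtin: five regions bounded by the
#: large intrinsically disordered insertions between its helical domains.
DEFAULT_HTT_FRAGMENTS = (
    ("fragm1", Interval(1, 402)),
    ("fragm2", Interval(403, 970)),
    ("fragm3", Interval(971, 1330)),
    ("fragm4", Interval(1331, 2080)),
    ("fragm5", Interval(2081, 3142)),
)


@dataclass(frozen=True)
class FragmentSpec:
    label: str
    interval: Interval


def default_htt_fragments() -> list[FragmentSpec]:
    return [FragmentSpec(lbl, iv) for lbl, iv in DEFAULT_HTT_FRAGMENTS]


@dataclass(frozen=True)
class PairScoreProfile:
    """Per protein/fragment: one score per unordered species pair.

    ``scores`` has one entry per pair in fixed panel order; NaN marks a
    non-informative comparison.
    """

    identifier: str
    scores: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))

    @property
    def informative(self) -> np.ndarray:
        return ~np.isnan(self.scores)


def idr_column_profile(
    aligned: str, idr_features: Iterable[SequenceFeature]
) -> np.ndarray:
    """Binary vector over alignment columns: 1 at IDR residues, 0 elsewhere.

    ``idr_features`` are IDR intervals in (ungapped) sequence coordinates of
    the aligned sequence; gap columns are always 0.
    """
    from .seqio import CoordinateMap

    out = np.zeros(len(aligned), dtype=np.int8)
    feats = [f for f in idr_features if f.kind == "IDR"]
    if not feats:
        return out
    cmap = CoordinateMap(aligned)
    for f in feats:
        out[cmap.columns_of(f.interval) - 1] = 1
    return out


def pair_jaccard_profile(
    group: OrthologGroup,
    idr_features: Mapping[str, Iterable[SequenceFeature]],
    identifier: str | None = None,
    column_profiles: Mapping[str, np.ndarray] | None = None,
) -> PairScoreProfile:
    """Jaccard of IDR column vectors for every species pair of a group.

    A pair is NaN (non-informative) when either species is absent or when
    both members' IDR vectors are all-zero. ``column_profiles`` (keyed by
    species) overrides profile computation, e.g. for fragment slices.
    """
    profiles: dict[str, np.ndarray] = {}
    if column_profiles is not None:
        profiles = {s: np.asarray(v) for s, v in column_profiles.items()}
    else:
        for species in group.present_species:
            member = group.members[species]
            profiles[species] = idr_column_profile(
                member.aligned, idr_features.get(member.identifier, [])
            )
    scores = []
    for a, b in group.panel.pairs():
        if a not in profiles or b not in profiles:
            scores.append(np.nan)
            continue
        u, v = profiles[a].astype(bool), profiles[b].astype(bool)
        union = int((u | v).sum())
        if union == 0:
            scores.append(np.nan)  # both without IDRs: not informative
        else:
            scores.append(float((u & v).sum() / union))
    return PairScoreProfile(identifier or group.group_id, np.array(scores))


def split_fragments(
    group: OrthologGroup, fragments: TypingSequence[FragmentSpec]
) -> list[tuple[FragmentSpec, OrthologGroup]]:
    """Column-slice one group into per-fragment groups.

    Fragment intervals are given in the leading (human) sequence's
    coordinates and mapped to column ranges via the human coordinate map;
    every species is retained in each slice, including species fully gapped
    there (they then yield non-informative pairs downstream).
    """
    from .seqio import AlignedMember

    human = group.human()
    cmap = group.coordinate_map(group.leading_species)
    out = []
    for frag in fragments:
        if frag.interval.end > cmap.sequence_length:
            raise ValueError(
                f"fragment {frag.label} {frag.interval} exceeds the "
                f"{group.leading_species} sequence ({cmap.sequence_length} aa)"
            )
        cols = cmap.map_interval(frag.interval)
        members = [
            AlignedMember(
                f"{m.identifier}_{frag.label}",
                m.species,
                m.aligned[cols.start - 1 : cols.end],
            )
            for m in (group.members[s] for s in group.present_species)
        ]
        sliced = OrthologGroup(
            f"{group.group_id}_{frag.label}",
            members,
            panel=group.panel,
            leading_species=group.leading_species,
        )
        out.append((frag, sliced))
    return out


def fragment_pair_profiles(
    group: OrthologGroup,
    idr_features: Mapping[str, Iterable[SequenceFeature]],
    fragments: TypingSequence[FragmentSpec],
) -> list[PairScoreProfile]:
    """Pair-score profiles of each fragment of one group.

    IDRs are predicted on the full-length sequences; their column profiles
    are computed once and sliced per fragment, so a disordered run crossing
    a fragment boundary contributes to both sides.
    """
    cmap = group.coordinate_map(group.leading_species)
    full = {
        s: idr_column_profile(
            group.members[s].aligned, idr_features.get(group.members[s].identifier, [])
        )
        for s in group.present_species
    }
    out = []
    for frag in fragments:
        if frag.interval.end > cmap.sequence_length:
            raise ValueError(f"fragment {frag.label} exceeds the leading sequence")
        cols = cmap.map_interval(frag.interval)
        sliced = {s: v[cols.start - 1 : cols.end] for s, v in full.items()}
        out.append(
            pair_jaccard_profile(
                group,
                idr_features,
                identifier=f"{group.group_id}_{frag.label}",
                column_profiles=sliced,
            )
        )
    return out


def profile_distance(p: PairScoreProfile, q: PairScoreProfile) -> float:
    """Pairwise-deletion Euclidean distance between two score profiles.

    Computed over the coordinates informative in both, rescaled by
    ``sqrt(n_total / n_shared)``; fully informative pairs are plain
    Euclidean. With zero shared coordinates the maximal attainable distance
    ``sqrt(n_total)`` is assigned (scores live in [0, 1]).
    """
    n_total = p.scores.size
    if q.scores.size != n_total:
        raise ValueError("profiles of unequal length")
    shared = p.informative & q.informative
    n_shared = int(shared.sum())
    if n_shared == 0:
        log.warning(
            "profiles %s and %s share no informative coordinates; "
            "assigning maximal distance",
            p.identifier,
            q.identifier,
        )
        return float(np.sqrt(n_total))
    d = p.scores[shared] - q.scores[shared]
    return float(np.sqrt(float(d @ d) * n_total / n_shared))


def cluster_profiles(
    profiles: TypingSequence[PairScoreProfile], n_clusters: int | None = None
) -> "ClusterResult":
    """Complete-linkage agglomeration of pair-score profiles.

    Profiles are ordered lexicographically by identifier before clustering so
    the result is invariant to input order. ``n_clusters`` requests a flat
    cut (maxclust); when omitted, only the dendrogram is produced.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    profs = sorted(profiles, key=lambda p: p.identifier)
    ids = [p.identifier for p in profs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate profile identifiers")
    m = len(profs)
    dmat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dmat[i, j] = dmat[j, i] = profile_distance(profs[i], profs[j])
    linkage = hierarchy.linkage(squareform(dmat, checks=False), method="complete")
    labels = None
    if n_clusters is not None:
        flat = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
        labels = dict(zip(ids, (int(c) for c in flat)))
    return ClusterResult(ids, dmat, linkage, labels)


@dataclass
class ClusterResult:
    identifiers: list[str]
    distances: np.ndarray
    linkage: np.ndarray
    labels: dict[str, int] | None = None

    def newick(self) -> str:
        """Dendrogram in Newick format (branch lengths from merge heights)."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            blen = parent_height - node.dist
            if node.is_leaf():
                return f"{self.identifiers[node.id]}:{blen:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{blen:.6g}"

        return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def write_profile_matrix(
    profiles: Iterable[PairScoreProfile], path: str | Path, panel: SpeciesPanel | None = None
) -> None:
    """Rows = proteins/fragments, columns = species pairs, NaN as ``NA``."""
    panel = panel or SpeciesPanel()
    cols = [f"{a.split()[0][0]}{a.split()[1][:3]}-{b.split()[0][0]}{b.split()[1][:3]}"
            for a, b in panel.pairs()]
    df = pd.DataFrame(
        {p.identifier: p.scores for p in profiles}, index=cols
    ).T
    df.to_csv(path, sep="\t", index_label="id", na_rep="NA")


def read_profile_matrix(path: str | Path) -> list[PairScoreProfile]:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values=["NA"])
    return [PairScoreProfile(str(i), row.to_numpy(dtype=float)) for i, row in df.iterrows()]
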