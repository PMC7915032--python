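"""Consolidation of per-sequence features onto alignment coordinates.

For one ortholog group and one feature kind, each sequence's features are
translated to alignment columns (gap-aware) and the union of covered columns
is taken; every maximal contiguous run of covered columns becomes one
consolidated feature carrying a per-species conservation profile over
``{1, 0, -}``: 1 where the species has a feature of the kind overlapping the
run by at least one column, 0 where the species is present without overlap,
``-`` where the species is absent from the group. Kinds are consolidated
independently, so overlapping features of different kinds are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqio import Interval, OrthologGroup, SequenceFeature, SpeciesPanel

_CONSOLIDATED_COLUMNS = ["group", "kind", "aln_start", "aln_end", "profile"]


@dataclass(frozen=True)
class ConsolidatedFeature:
    """A union interval in alignment columns plus its conservation profile."""

    group_id: str
    kind: str
    interval: Interval
    profile: str

    def __post_init__(self):
        if set(self.profile) - set("10-"):
            raise ValueError(f"invalid profile {self.profile!r}")
        if "1" not in self.profile:
            raise ValueError("a consolidated feature must be present somewhere")

    @property
    def n_conserved(self) -> int:
        """Number of species in which the interval contains the feature."""
        return self.profile.count("1")


def consolidate_group(
    group: OrthologGroup,
    features: Mapping[str, Iterable[SequenceFeature]],
    kind: str,
) -> list[ConsolidatedFeature]:
    """Union the given kind's features over one group's alignment columns.

    ``features`` maps sequence id -> features in sequence coordinates; ids
    not in the group raise. Returns consolidated features sorted by start.
    """
    known = set(group.sequence_ids())
    for sid in features:
        if sid not in known:
            raise KeyError(
                f"{group.group_id}: features given for unknown sequence {sid!r}"
            )
    ncol = group.alignment_length
    covered = np.zeros(ncol, dtype=bool)
    # per species: boolean column coverage of this kind
    species_cov: dict[str, np.ndarray] = {}
    for species in group.present_species:
        member = group.members[species]
        feats = [f for f in features.get(member.identifier, []) if f.kind == kind]
        if not feats:
            continue
        cmap = group.coordinate_map(species)
        cov = np.zeros(ncol, dtype=bool)
        for f in feats:
            cols = cmap.columns_of(f.interval)
            cov[cols - 1] = True
        species_cov[species] = cov
        covered |= cov
    out: list[ConsolidatedFeature] = []
    boundaries = np.flatnonzero(
        np.diff(np.concatenate([[0], covered.view(np.int8), [0]]))
    )
    for s, e in zip(boundaries[::2], boundaries[1::2]):
        run = slice(int(s), int(e))  # 0-based half-open columns
        profile = []
        for species in group.panel:
            if species not in group.members:
                profile.append("-")
            elif species in species_cov and species_cov[species][run].any():
                profile.append("1")
            else:
                profile.append("0")
        out.append(
            ConsolidatedFeature(
                group.group_id,
                kind,
                Interval(int(s) + 1, int(e)),
                "".join(profile),
            )
        )
    return out


def consolidate_all(
    group: OrthologGroup,
    features: Mapping[str, Iterable[SequenceFeature]],
    kinds: Iterable[str] | None = None,
) -> list[ConsolidatedFeature]:
    """Consolidate every kind occurring in ``features`` (or the given kinds)."""
    if kinds is None:
        kinds = sorted({f.kind for feats in features.values() for f in feats})
    out: list[ConsolidatedFeature] = []
    for kind in kinds:
        out.extend(consolidate_group(group, features, kind))
    out.sort(key=lambda c: (c.kind, c.interval.start))
    return out


def conservation_pattern(cf: ConsolidatedFeature) -> str:
    """The profile string in fixed panel order (e.g. ``1111--1000``)."""
    return cf.profile


def count_consolidated(
    features: Iterable[ConsolidatedFeature],
) -> tuple[pd.Series, pd.DataFrame]:
    """Counts of consolidated features per kind.

    Returns ``(totals, per_group)``: totals indexed by kind, and a tidy
    frame with one row per (group, kind) pair.
    """
    rows = [{"group": c.group_id, "kind": c.kind} for c in features]
    if not rows:
        empty = pd.DataFrame(columns=["group", "kind", "count"])
        return pd.Series(dtype=int, name="total"), empty
    df = pd.DataFrame(rows)
    per_group = (
        df.groupby(["group", "kind"]).size().reset_index(name="count")
    )
    totals = df.groupby("kind").size().sort_index()
    totals.name = "total"
    return totals, per_group


def pattern_census(
    features: Iterable[ConsolidatedFeature],
) -> pd.DataFrame:
    """Frequency of each distinct conservation profile, per kind and overall.

    Returns a tidy frame (kind, profile, count) where kind ``"*"`` carries
    the overall census across kinds.
    """
    feats = list(features)
    if not feats:
        return pd.DataFrame(columns=["kind", "profile", "count"])
    df = pd.DataFrame({"kind": [c.kind for c in feats], "profile": [c.profile for c in feats]})
    per_kind = df.groupby(["kind", "profile"]).size().reset_index(name="count")
    overall = df.groupby("profile").size().reset_index(name="count")
    overall.insert(0, "kind", "*")
    out = pd.concat([overall, per_kind], ignore_index=True)
    return out.sort_values(["kind", "count", "profile"], ascending=[True, False, True]).reset_index(
        drop=True
    )


def write_consolidated_table(
    features: Iterable[ConsolidatedFeature], path: str | Path
) -> None:
    """Write the consolidated-feature TSV consumed by downstream stages."""
    rows = [
        {
            "group": c.group_id,
            "kind": c.kind,
            "aln_start": c.interval.start,
            "aln_end": c.interval.end,
            "profile": c.profile,
        }
        for c in features
    ]
    df = pd.DataFrame(rows, columns=_CONSOLIDATED_COLUMNS)
    df = df.sort_values(["group", "kind", "aln_start"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_consolidated_table(path: str | Path) -> list[ConsolidatedFeature]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"profile": str})
    except pd.errors.EmptyDataError:
        return []
    return [
        ConsolidatedFeature(
            str(r.group), str(r.kind), Interval(int(r.aln_start), int(r.aln_end)), str(r.profile)
        )
        for r in df.itertuples(index=False)
    ]
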