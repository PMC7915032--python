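"""Feature co-occurrence (Jaccard) and the HAP40-likeness filter cascade.

Presence vectors are built from raw per-sequence features — one binary entry
per (feature kind, individual sequence), orthologs included — and all pairs
of kinds are compared by the Jaccard score. Consolidated tables feed only
the filter cascade, which mirrors how HAP40's diagnostic combination of a
conserved diffuse A-rich region plus a polyP is mined from the corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .consolidate import ConsolidatedFeature
from .seqio import KINDS, SequenceFeature

log = logging.getLogger("lcrevol")


def presence_vectors(
    features: Mapping[str, Iterable[SequenceFeature]],
    kinds: Iterable[str] = KINDS,
) -> pd.DataFrame:
    """Binary presence/absence matrix: rows = kinds, columns = sequences.

    Entry (kind, sequence) is 1 iff the sequence carries >= 1 feature of the
    kind. Column order follows the (sorted) sequence ids for determinism.
    """
    kinds = list(kinds)
    seq_ids = sorted(features)
    mat = pd.DataFrame(0, index=kinds, columns=seq_ids, dtype=np.int8)
    for sid in seq_ids:
        for f in features[sid]:
            if f.kind in mat.index:
                mat.loc[f.kind, sid] = 1
    return mat


def jaccard(u: np.ndarray, v: np.ndarray) -> float:
    """|u AND v| / |u OR v| for binary vectors; 0 when the union is empty."""
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch {u.shape} vs {v.shape}")
    union = int(np.logical_or(u, v).sum())
    if union == 0:
        return 0.0
    return float(np.logical_and(u, v).sum() / union)


def cooccurrence_matrix(pm: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Jaccard over the rows of a presence matrix.

    Symmetric, values in [0, 1]; the diagonal is 1 for any kind present at
    least once and 0 for all-zero rows.
    """
    m = pm.to_numpy(dtype=np.int64)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("presence matrix entries must be binary")
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return pd.DataFrame(jac, index=pm.index, columns=pm.index)


@dataclass
class CascadeResult:
    """Stage-by-stage output of the HAP40-likeness filter.

    s1: groups with >= 1 consolidated A-rich CBR;
    s2: those where some A-rich CBR is conserved in >= ``min_conserved_species``
        species (count of '1' in its profile, human included);
    s3: s2 minus groups whose every qualifying A-rich CBR overlaps a
        consolidated polyA (a diffuse bias explained by a pure homorepeat is
        disqualified no matter how conserved the polyA is);
    s4: s3 groups that additionally contain >= 1 consolidated polyP,
        regardless of its conservation.
    """

    s1: list[str]
    s2: list[str]
    s3: list[str]
    s4: list[str]
    supporting: dict[str, list[ConsolidatedFeature]] = field(default_factory=dict)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (len(self.s1), len(self.s2), len(self.s3), len(self.s4))


def hap40_like_filter(
    consolidated: Mapping[str, Iterable[ConsolidatedFeature]],
    min_conserved_species: int = 4,
) -> CascadeResult:
    """Run the A-rich/polyA/polyP filter cascade over consolidated tables.

    ``consolidated`` maps group id -> all consolidated features of that
    group (at least the CBR:A, polyX:A and polyX:P kinds must have been
    consolidated; an empty list is a valid value for a group with none).
    """
    s1, s2, s3, s4 = [], [], [], []
    supporting: dict[str, list[ConsolidatedFeature]] = {}
    for gid in sorted(consolidated):
        feats = list(consolidated[gid])
        cbr_a = [f for f in feats if f.kind == "CBR:A"]
        poly_a = [f for f in feats if f.kind == "polyX:A"]
        poly_p = [f for f in feats if f.kind == "polyX:P"]
        if not cbr_a:
            continue
        s1.append(gid)
        qualifying = [f for f in cbr_a if f.n_conserved >= min_conserved_species]
        if not qualifying:
            continue
        s2.append(gid)
        diffuse = [
            f
            for f in qualifying
            if not any(f.interval.overlaps(a.interval) for a in poly_a)
        ]
        if not diffuse:
            continue
        s3.append(gid)
        if not poly_p:
            continue
        s4.append(gid)
        supporting[gid] = diffuse + poly_p
    return CascadeResult(s1, s2, s3, s4, supporting)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a presence or co-occurrence matrix as TSV with headers."""
    df.to_csv(path, sep="\t", index_label="kind")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="kind")


def write_cascade_report(result: CascadeResult, path: str | Path) -> None:
    rows = []
    for stage, groups in zip(("s1", "s2", "s3", "s4"), (result.s1, result.s2, result.s3, result.s4)):
        for gid in groups:
            rows.append({"stage": stage, "group": gid})
    pd.DataFrame(rows, columns=["stage", "group"]).to_csv(path, sep="\t", index=False)
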