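"""Synthetic ortholog groups with planted low-complexity features and
deterministic ground truth for every pipeline stage.

Synthetic "alignments" are built in a shared column frame: plants and indels
are specified in alignment columns, indels are realized as gap blocks, and
no aligner ever runs — the alignment is exact by construction. Plants are
deterministic patterns (a pure run for polyX, an evenly interspersed
Bresenham pattern for diffuse CBRs that stays below the homorepeat
window rule); only the background residues are random. The generator
insulates plant flanks (no positively scoring residues against the planted
residue within ten columns) so that planted boundaries are recovered
essentially exactly, and the truth table is derived purely from the plan by
column arithmetic, never by calling the detectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np

from .detectors import DisorderProfile, _BLOSUM62
from .seqio import (
    AA20,
    AlignedMember,
    Interval,
    OrthologGroup,
    Sequence,
    SequenceFeature,
    SpeciesPanel,
    species_tag,
)

#: Columns of insulation kept clean around polyX/CBR plants.
FLANK = 10

#: Minimal column separation enforced between residue-touching plants
#: (polyX/CBR) of the same species, keeping planted signals independent.
MIN_PLANT_SEPARATION = 20

#: Roughly human-proteome amino-acid frequencies (UniProtKB/Swiss-Prot order
#: of magnitude; used when composition="human").
HUMAN_COMPOSITION = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.036,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}


@dataclass(frozen=True)
class Plant:
    """One planted feature: kind, target species, column interval, knobs.

    ``purity`` — fraction of the repeated residue inside a polyX plant
    (1.0 = pure run). ``bias`` — fraction of the biased residue in a diffuse
    CBR plant (kept <= 0.7 so the plant never trips the 8-in-10 homorepeat
    rule). ``level`` — disorder score inside an IDR plant.
    """

    kind: str
    species: tuple[str, ...]
    interval: Interval
    purity: float = 1.0
    bias: float = 0.6
    level: float = 0.9


@dataclass(frozen=True)
class Indel:
    """A gap block: the listed species carry gaps over the column interval."""

    species: tuple[str, ...]
    interval: Interval


@dataclass(frozen=True)
class GroupPlan:
    group_id: str
    seed: int
    length: int
    species_present: tuple[str, ...] = ()
    plants: tuple[Plant, ...] = ()
    indels: tuple[Indel, ...] = ()
    composition: str = "uniform"

    def validate(self, panel: SpeciesPanel) -> None:
        present = self.species_present or tuple(panel)
        for s in present:
            if s not in panel:
                raise ValueError(f"{self.group_id}: unknown species {s!r}")
        touching: dict[str, list[Plant]] = {}
        for p in self.plants:
            if not (1 <= p.interval.start and p.interval.end <= self.length):
                raise ValueError(f"{self.group_id}: plant {p} outside columns")
            if not set(p.species) <= set(present):
                raise ValueError(f"{self.group_id}: plant species not present")
            if not (0 < p.purity <= 1):
                raise ValueError("purity must be in (0, 1]")
            if p.kind.startswith("CBR:") and p.bias > 0.7:
                raise ValueError("CBR plant bias must be <= 0.7 (homorepeat rule)")
            if p.kind.startswith(("polyX:", "CBR:")):
                for s in p.species:
                    touching.setdefault(s, []).append(p)
        for s, plist in touching.items():
            plist = sorted(plist, key=lambda p: p.interval.start)
            for a, b in zip(plist, plist[1:]):
                if a.kind == b.kind and a.interval.overlaps(b.interval):
                    raise ValueError(
                        f"{self.group_id}: overlapping {a.kind} plants in {s}"
                    )
                if b.interval.start - a.interval.end - 1 < MIN_PLANT_SEPARATION:
                    raise ValueError(
                        f"{self.group_id}: plants closer than "
                        f"{MIN_PLANT_SEPARATION} columns in {s}"
                    )


@dataclass
class TruthTable:
    """Ground truth derived deterministically from a :class:`GroupPlan`."""

    group_id: str
    #: expected per-sequence features (sequence coordinates), keyed by seq id
    features: dict[str, list[SequenceFeature]] = field(default_factory=dict)
    #: expected consolidated intervals and profiles, keyed by kind
    consolidated: dict[str, list[tuple[Interval, str]]] = field(default_factory=dict)
    #: expected presence entries: set of (kind, sequence id)
    presence: set[tuple[str, str]] = field(default_factory=set)
    #: highest HAP40-cascade stage this group reaches (0 = not even s1)
    cascade_stage: int = 0


@dataclass
class GroupResult:
    group: OrthologGroup
    truth: TruthTable
    disorder: dict[str, DisorderProfile]
    cc_annotations: dict[str, list[SequenceFeature]]


def _bresenham_positions(n: int, fraction: float) -> np.ndarray:
    """Evenly interspersed positions (0-based) covering ``fraction`` of 0..n-1,
    anchored at both ends."""
    idx = np.flatnonzero(
        np.floor(np.arange(1, n + 1) * fraction) > np.floor(np.arange(n) * fraction)
    )
    return np.union1d(idx, [0, n - 1]) if n > 0 else idx


def _negative_fillers(residue: str) -> list[str]:
    """Residues scoring < 0 against ``residue`` under BLOSUM62."""
    return [a for a in AA20 if a != residue and _BLOSUM62[a, residue] < 0]


def _unit_penalty_fillers(residue: str) -> list[str]:
    """Residues scoring exactly -1 against ``residue`` (CBR plant filler;
    keeps the planted segment score an exact arithmetic function of the
    bias). Falls back to the mildest negative scorers."""
    exact = [a for a in AA20 if a != residue and _BLOSUM62[a, residue] == -1]
    if exact:
        return exact
    neg = _negative_fillers(residue)
    best = max(_BLOSUM62[a, residue] for a in neg)
    return [a for a in neg if _BLOSUM62[a, residue] == best]


def _sample_background(rng: np.random.Generator, n: int, composition: str) -> np.ndarray:
    letters = np.array(list(AA20))
    if composition == "uniform":
        return letters[rng.integers(0, 20, size=n)]
    if composition == "human":
        probs = np.array([HUMAN_COMPOSITION[a] for a in AA20])
        probs = probs / probs.sum()
        return rng.choice(letters, size=n, p=probs)
    raise ValueError(f"unknown composition {composition!r}")


def _seq_id(group_id: str, species: str) -> str:
    return f"{group_id}_{species_tag(species)}"


def gen_group(plan: GroupPlan, panel: SpeciesPanel | None = None) -> GroupResult:
    """Realize a plan into an aligned group plus its truth table.

    Deterministic under ``plan.seed`` at byte level. Planted polyX regions at
    purity 1.0 satisfy the 8-in-10 rule in every window; planted CBRs carry
    the stated bias; planted IDRs receive disorder scores above 0.5 inside
    and below outside; indels become per-species gap blocks in the shared
    column frame.
    """
    panel = panel or SpeciesPanel()
    plan.validate(panel)
    present = plan.species_present or tuple(panel)
    rng = np.random.default_rng(plan.seed)
    L = plan.length

    gap_masks = {s: np.zeros(L, dtype=bool) for s in present}
    for indel in plan.indels:
        for s in indel.species:
            if s in gap_masks:
                gap_masks[s][indel.interval.start - 1 : indel.interval.end] = True

    rows = {s: _sample_background(rng, L, plan.composition) for s in present}

    # per-species column roles: -1 background, >=0 index of the touching
    # plant whose pattern owns the column; locked marks planted X positions
    roles = {s: np.full(L, -1, dtype=np.int64) for s in present}
    locked = {s: np.zeros(L, dtype=bool) for s in present}
    touching = [p for p in plan.plants if p.kind.startswith(("polyX:", "CBR:"))]

    for pi, p in enumerate(touching):
        x = p.kind.split(":", 1)[1]
        fillers = np.array(_negative_fillers(x))
        s0, e0 = p.interval.start - 1, p.interval.end  # 0-based half-open
        n = e0 - s0
        if p.kind.startswith("polyX:"):
            pattern = np.full(n, x)
            if p.purity < 1.0:
                impure = rng.random(n) >= p.purity
                pattern[impure] = fillers[rng.integers(0, fillers.size, impure.sum())]
        else:
            unit = np.array(_unit_penalty_fillers(x))
            pattern = unit[rng.integers(0, unit.size, n)]
            pattern[_bresenham_positions(n, p.bias)] = x
        for s in p.species:
            rows[s][s0:e0] = pattern
            roles[s][s0:e0] = pi
            locked[s][s0:e0] = pattern == x
            _insulate(rows[s], s0, e0, x, fillers, rng, L)

    truth = _derive_truth(plan, panel, gap_masks, present)
    for s in present:
        spans = [
            (p.kind.split(":", 1)[1], iv)
            for p in touching
            if s in p.species
            and (iv := _seq_interval(p.interval, gap_masks[s])) is not None
        ]
        _scrub_background(
            rows[s], roles[s], locked[s], gap_masks[s], touching, spans, plan, rng
        )

    members = []
    for s in present:
        chars = rows[s].copy()
        chars[gap_masks[s]] = "-"
        members.append(AlignedMember(_seq_id(plan.group_id, s), s, "".join(chars)))
    group = OrthologGroup(plan.group_id, members, panel=panel)

    # disorder score files: level inside planted IDRs, 0.1 outside
    disorder: dict[str, DisorderProfile] = {}
    for s in present:
        sid = _seq_id(plan.group_id, s)
        seq_len = int((~gap_masks[s]).sum())
        scores = np.full(seq_len, 0.1)
        for p in plan.plants:
            if p.kind != "IDR" or s not in p.species:
                continue
            iv = _seq_interval(p.interval, gap_masks[s])
            if iv is not None:
                scores[iv.start - 1 : iv.end] = p.level
        disorder[sid] = DisorderProfile(sid, scores)

    cc: dict[str, list[SequenceFeature]] = {}
    for p in plan.plants:
        if p.kind != "CC":
            continue
        for s in p.species:
            sid = _seq_id(plan.group_id, s)
            iv = _seq_interval(p.interval, gap_masks[s])
            if iv is not None:
                cc.setdefault(sid, []).append(SequenceFeature(sid, "CC", iv))
    return GroupResult(group, truth, disorder, cc)


def _insulate(
    row: np.ndarray, s0: int, e0: int, x: str, fillers: np.ndarray,
    rng: np.random.Generator, L: int,
) -> None:
    """Keep the FLANK columns around a plant free of residues scoring >= 0
    against the planted residue, so detected boundaries stay put."""
    for lo, hi in ((max(0, s0 - FLANK), s0), (e0, min(L, e0 + FLANK))):
        for i in range(lo, hi):
            if _BLOSUM62[str(row[i]), x] >= 0:
                row[i] = fillers[rng.integers(0, fillers.size)]


def _scrub_background(
    row: np.ndarray,
    role: np.ndarray,
    locked: np.ndarray,
    gap_mask: np.ndarray,
    touching: list[Plant],
    plant_spans: list[tuple[str, Interval]],
    plan: GroupPlan,
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> None:
    """Rejection-condition one row on containing no detectable polyX/CBR
    outside its plants.

    Random backgrounds occasionally harbour genuine compositional bias
    (four tryptophans in five positions already score 41 under BLOSUM62);
    the generator resamples the offending columns — planted X positions are
    never touched — until the scanners find nothing beyond the planted
    truth. Deterministic under the plan seed.
    """
    from .detectors import DetectorConfig, scan_cbr_cast, scan_polyx

    cfg = DetectorConfig(disorder_source="adapter")
    nongap = np.flatnonzero(~gap_mask)
    for _ in range(max_rounds):
        seq = Sequence("scrub", "unknown", "".join(row[nongap]))
        observed = scan_polyx(seq, cfg) + scan_cbr_cast(seq, cfg)
        # anything of a plant's residue overlapping that plant is the plant's
        # own signal (e.g. a pure homorepeat is also a CAST-detectable CBR)
        spurious = [
            f
            for f in observed
            if not any(
                f.residue == r and f.interval.overlaps(iv) for r, iv in plant_spans
            )
        ]
        if not spurious:
            return
        for f in spurious:
            cols = nongap[f.interval.start - 1 : f.interval.end]
            for c in cols:
                if locked[c]:
                    continue
                pi = role[c]
                if pi >= 0:
                    x = touching[pi].kind.split(":", 1)[1]
                    pool = (
                        _unit_penalty_fillers(x)
                        if touching[pi].kind.startswith("CBR:")
                        else _negative_fillers(x)
                    )
                    row[c] = pool[rng.integers(0, len(pool))]
                else:
                    row[c] = _sample_background(rng, 1, plan.composition)[0]
        # keep this row's plant flanks insulated after resampling
        for pi in sorted(set(int(i) for i in role[role >= 0])):
            p = touching[pi]
            x = p.kind.split(":", 1)[1]
            fillers = np.array(_negative_fillers(x))
            _insulate(row, p.interval.start - 1, p.interval.end, x, fillers, rng, row.size)
    raise RuntimeError(
        f"{plan.group_id}: could not scrub spurious background features"
    )


def _seq_interval(cols: Interval, gap_mask: np.ndarray) -> Interval | None:
    """Column interval -> 1-based ungapped sequence interval (None if all-gap)."""
    nongap = ~gap_mask
    inside = nongap[cols.start - 1 : cols.end]
    n_inside = int(inside.sum())
    if n_inside == 0:
        return None
    before = int(nongap[: cols.start - 1].sum())
    return Interval(before + 1, before + n_inside)


def _plant_columns(p: Plant, gap_mask: np.ndarray) -> np.ndarray:
    """Non-gap 0-based columns a plant occupies in one species."""
    cols = np.arange(p.interval.start - 1, p.interval.end)
    return cols[~gap_mask[cols]]


def _expected_features(p: Plant, sid: str, gap_mask: np.ndarray) -> list[SequenceFeature]:
    """Detector-rule arithmetic on the planted pattern (no detectors called)."""
    iv = _seq_interval(p.interval, gap_mask)
    if iv is None:
        return []
    length = len(iv)
    out = []
    if p.kind == "IDR":
        if length >= 30:
            out.append(SequenceFeature(sid, "IDR", iv))
    elif p.kind == "CC":
        out.append(SequenceFeature(sid, "CC", iv))
    elif p.kind.startswith("polyX:"):
        x = p.kind.split(":", 1)[1]
        if p.purity == 1.0:
            diag = float(_BLOSUM62[x, x])
            if length >= 8:
                out.append(SequenceFeature(sid, p.kind, iv))
            if length * diag >= 40:  # a pure run is also a CAST-detectable CBR
                out.append(SequenceFeature(sid, f"CBR:{x}", iv, length * diag))
        else:
            out.append(SequenceFeature(sid, p.kind, iv))  # intended, not assured
    elif p.kind.startswith("CBR:"):
        x = p.kind.split(":", 1)[1]
        diag = float(_BLOSUM62[x, x])
        # count planted X positions that survive the species' gaps
        n_cols = len(p.interval)
        xpos = set(int(i) for i in _bresenham_positions(n_cols, p.bias))
        cols = np.arange(p.interval.start - 1, p.interval.end)
        keep = ~gap_mask[cols]
        n_x = sum(1 for i, k in enumerate(keep) if k and i in xpos)
        score_lb = n_x * diag - (length - n_x)  # fillers score <= -1
        if score_lb >= 40:
            out.append(SequenceFeature(sid, p.kind, iv, score_lb))
    return out


def _derive_truth(
    plan: GroupPlan,
    panel: SpeciesPanel,
    gap_masks: Mapping[str, np.ndarray],
    present: tuple[str, ...],
) -> TruthTable:
    truth = TruthTable(plan.group_id)
    for s in present:
        truth.features[_seq_id(plan.group_id, s)] = []
    for p in plan.plants:
        for s in p.species:
            sid = _seq_id(plan.group_id, s)
            truth.features[sid].extend(_expected_features(p, sid, gap_masks[s]))
    for sid, feats in truth.features.items():
        feats.sort(key=lambda f: (f.interval.start, f.kind))
        for f in feats:
            truth.presence.add((f.kind, sid))

    # consolidation truth: union of expected features' column footprints
    kinds = sorted({f.kind for feats in truth.features.values() for f in feats})
    L = plan.length
    for kind in kinds:
        covered = np.zeros(L, dtype=bool)
        species_cols: dict[str, np.ndarray] = {}
        for s in present:
            sid = _seq_id(plan.group_id, s)
            cov = np.zeros(L, dtype=bool)
            nongap_cols = np.flatnonzero(~gap_masks[s])
            for f in truth.features[sid]:
                if f.kind != kind:
                    continue
                cov[nongap_cols[f.interval.start - 1 : f.interval.end]] = True
            if cov.any():
                species_cols[s] = cov
                covered |= cov
        runs = np.flatnonzero(np.diff(np.concatenate([[0], covered.view(np.int8), [0]])))
        entries = []
        for a, b in zip(runs[::2], runs[1::2]):
            profile = []
            for s in panel:
                if s not in present:
                    profile.append("-")
                elif s in species_cols and species_cols[s][a:b].any():
                    profile.append("1")
                else:
                    profile.append("0")
            entries.append((Interval(int(a) + 1, int(b)), "".join(profile)))
        truth.consolidated[kind] = entries

    truth.cascade_stage = _cascade_stage(truth)
    return truth


def _cascade_stage(truth: TruthTable) -> int:
    cbr_a = truth.consolidated.get("CBR:A", [])
    if not cbr_a:
        return 0
    poly_a = [iv for iv, _ in truth.consolidated.get("polyX:A", [])]
    qualifying = [iv for iv, prof in cbr_a if prof.count("1") >= 4]
    if not qualifying:
        return 1
    diffuse = [iv for iv in qualifying if not any(iv.overlaps(a) for a in poly_a)]
    if not diffuse:
        return 2
    if not truth.consolidated.get("polyX:P"):
        return 3
    return 4


# ---------------------------------------------------------------------------
# Presence matrices with target co-occurrence


def gen_presence_matrix(
    kinds: TypingSequence[str],
    n_seqs: int,
    marginals: Mapping[str, float],
    pair_targets: Iterable[tuple[str, str, float]] = (),
    seed: int = 0,
) -> tuple["pd.DataFrame", dict[tuple[str, str], float]]:
    """Bernoulli presence matrix with prescribed marginals and pairwise
    Jaccard targets.

    For a target Jaccard J between kinds A and B with marginals pA, pB the
    joint probability p11 = J (pA + pB) / (1 + J) is used; it must respect
    the Frechet bounds, otherwise the target is infeasible and raises. Each
    kind may appear in at most one target pair; unpaired kinds are drawn
    independently.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    targets = list(pair_targets)
    in_pair: set[str] = set()
    for a, b, j in targets:
        if a in in_pair or b in in_pair:
            raise ValueError("each kind may appear in at most one target pair")
        in_pair.update((a, b))
        if not (0 <= j <= 1):
            raise ValueError("target Jaccard must be in [0, 1]")
    mat = pd.DataFrame(
        0, index=list(kinds), columns=[f"seq{i:05d}" for i in range(n_seqs)], dtype=np.int8
    )
    for a, b, j in targets:
        pa, pb = marginals[a], marginals[b]
        p11 = j * (pa + pb) / (1 + j) if (pa + pb) > 0 else 0.0
        lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
        if not (lo - 1e-12 <= p11 <= hi + 1e-12):
            raise ValueError(
                f"target Jaccard {j} infeasible for marginals ({pa}, {pb})"
            )
        probs = np.array([p11, pa - p11, pb - p11, 1 - pa - pb + p11])
        if (probs < -1e-12).any():
            raise ValueError("infeasible joint distribution")
        draw = rng.choice(4, size=n_seqs, p=np.clip(probs, 0, None) / probs.clip(0).sum())
        mat.loc[a] = ((draw == 0) | (draw == 1)).astype(np.int8)
        mat.loc[b] = ((draw == 0) | (draw == 2)).astype(np.int8)
    for kind in kinds:
        if kind not in in_pair:
            p = marginals.get(kind, 0.0)
            mat.loc[kind] = (rng.random(n_seqs) < p).astype(np.int8)
    return mat, {(a, b): j for a, b, j in targets}


# ---------------------------------------------------------------------------
# Profile archetypes for clustering tests


def gen_profile_archetypes(
    archetypes: TypingSequence[np.ndarray],
    n_per: int,
    noise: float,
    seed: int = 0,
    n_pairs: int = 45,
) -> tuple[list, dict[str, int]]:
    """Pair-score profiles around planted archetypes plus iid noise.

    Returns (profiles, labels); labels map profile id -> archetype index.
    """
    from .coevolve import PairScoreProfile

    rng = np.random.default_rng(seed)
    profiles, labels = [], {}
    for ai, base in enumerate(archetypes):
        base = np.asarray(base, dtype=float)
        if base.size != n_pairs:
            raise ValueError("archetype length must equal the number of pairs")
        for k in range(n_per):
            noisy = np.clip(base + rng.normal(0, noise, size=n_pairs), 0, 1)
            noisy[np.isnan(base)] = np.nan
            pid = f"arch{ai}_{k:02d}"
            profiles.append(PairScoreProfile(pid, noisy))
            labels[pid] = ai
    return profiles, labels


# ---------------------------------------------------------------------------
# Recovery metrics


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / len(a), inter / len(b))


def _match_intervals(
    expected: list[tuple[str, Interval]],
    observed: list[tuple[str, Interval]],
    min_overlap: float = 0.9,
) -> tuple[float, float, int]:
    """Greedy one-to-one matching; returns (precision, recall, n_matched)."""
    unmatched = list(range(len(observed)))
    matched = 0
    for key, iv in expected:
        best, best_ov = None, 0.0
        for j in unmatched:
            okey, oiv = observed[j]
            if okey != key:
                continue
            ov = _reciprocal_overlap(iv, oiv)
            if ov > best_ov:
                best, best_ov = j, ov
        if best is not None and best_ov >= min_overlap:
            unmatched.remove(best)
            matched += 1
    precision = matched / len(observed) if observed else 1.0
    recall = matched / len(expected) if expected else 1.0
    return precision, recall, matched


def rand_index(labels_a: Mapping[str, int], labels_b: Mapping[str, int]) -> float:
    """Plain Rand index of two labelings over the same items."""
    items = sorted(labels_a)
    if sorted(labels_b) != items:
        raise ValueError("labelings cover different items")
    a = np.array([labels_a[i] for i in items])
    b = np.array([labels_b[i] for i in items])
    n = len(items)
    if n < 2:
        return 1.0
    agree = 0
    for i in range(n):
        same_a = a[i + 1 :] == a[i]
        same_b = b[i + 1 :] == b[i]
        agree += int((same_a == same_b).sum())
    return agree / (n * (n - 1) / 2)


@dataclass
class RecoveryReport:
    feature_precision: float | None = None
    feature_recall: float | None = None
    consolidated_precision: float | None = None
    consolidated_recall: float | None = None
    profile_match_rate: float | None = None
    presence_agreement: float | None = None
    cascade_agreement: float | None = None
    cluster_rand_index: float | None = None


def evaluate_recovery(
    truths: TypingSequence[TruthTable],
    observed_features: Mapping[str, Mapping[str, list[SequenceFeature]]] | None = None,
    observed_consolidated: Mapping[str, list] | None = None,
    observed_presence=None,
    observed_cascade: Mapping[str, int] | None = None,
    cluster_labels: tuple[Mapping[str, int], Mapping[str, int]] | None = None,
    min_overlap: float = 0.9,
) -> RecoveryReport:
    """Score observed pipeline outputs against planted truth.

    ``observed_features``/``observed_consolidated``/``observed_cascade`` are
    keyed by group id; an interval matches its planted counterpart at
    reciprocal overlap >= ``min_overlap``.
    """
    by_id = {t.group_id: t for t in truths}
    report = RecoveryReport()

    if observed_features is not None:
        exp, obs = [], []
        for gid, t in by_id.items():
            got = observed_features.get(gid)
            if got is None:
                raise KeyError(f"no observed features for group {gid}")
            for sid, feats in t.features.items():
                exp.extend(((sid, f.kind), f.interval) for f in feats)
            for sid, feats in got.items():
                obs.extend(((sid, f.kind), f.interval) for f in feats)
        p, r, _ = _match_intervals(exp, obs, min_overlap)
        report.feature_precision, report.feature_recall = p, r

    if observed_consolidated is not None:
        exp, obs = [], []
        exp_prof: dict[tuple[str, str, int, int], str] = {}
        obs_prof = {}
        for gid, t in by_id.items():
            for kind, entries in t.consolidated.items():
                for iv, prof in entries:
                    exp.append(((gid, kind), iv))
                    exp_prof[(gid, kind, iv.start, iv.end)] = prof
            for cf in observed_consolidated.get(gid, []):
                obs.append(((gid, cf.kind), cf.interval))
                obs_prof[(gid, cf.kind, cf.interval.start, cf.interval.end)] = cf.profile
        p, r, _ = _match_intervals(exp, obs, min_overlap)
        report.consolidated_precision, report.consolidated_recall = p, r
        shared = set(exp_prof) & set(obs_prof)
        if shared:
            report.profile_match_rate = float(
                np.mean([exp_prof[k] == obs_prof[k] for k in sorted(shared)])
            )

    if observed_presence is not None:
        expected_entries = set()
        for t in by_id.values():
            expected_entries |= t.presence
        observed_entries = {
            (kind, sid)
            for kind in observed_presence.index
            for sid in observed_presence.columns
            if observed_presence.loc[kind, sid] == 1
        }
        universe = {
            (kind, sid)
            for kind in observed_presence.index
            for sid in observed_presence.columns
        }
        agree = sum(
            ((e in expected_entries) == (e in observed_entries)) for e in universe
        )
        report.presence_agreement = agree / len(universe) if universe else 1.0

    if observed_cascade is not None:
        agree = [
            observed_cascade.get(gid, 0) == t.cascade_stage for gid, t in by_id.items()
        ]
        report.cascade_agreement = float(np.mean(agree)) if agree else 1.0

    if cluster_labels is not None:
        report.cluster_rand_index = rand_index(*cluster_labels)

    return report


# ---------------------------------------------------------------------------
# Reference-style fixtures


def hap40_standin() -> Sequence:
    """SYNTHETIC stand-in for human HAP40 (UniProt P23610) — not the real
    sequence.

    A deterministic 371-residue sequence that embeds the documented anchors
    of the real protein: the decamer ``PPPPPPAPQP`` at positions 223-232,
    the motifs VAEAG at 43-47 and AALGA at 257-261 bounding the A-rich
    region, and the C-terminal valine V371. The proline-free cyclic
    background guarantees the decamer is the only homorepeat signal, making
    the stand-in suitable for exercising polyP localization when the real
    database record is unavailable.
    """
    cycle = "ACDEFGHIKLMNQRSTVWY"  # 19 letters, proline-free, no repeats
    chars = [cycle[i % len(cycle)] for i in range(371)]
    chars[42:47] = "VAEAG"
    chars[222:232] = "PPPPPPAPQP"
    chars[256:261] = "AALGA"
    chars[370] = "V"
    return Sequence("P23610_SYNTHETIC", "Homo sapiens", "".join(chars))


def demo_corpus_plans(seed: int = 0, panel: SpeciesPanel | None = None) -> list[GroupPlan]:
    """A small corpus exercising every cascade stage with known truth.

    Groups: g1 is HAP40-like (conserved diffuse A-rich CBR + polyP, stage 4);
    g2 reaches stage 3 (no polyP); g3 stops at stage 2 (its conserved A-rich
    CBR overlaps a polyA); g4 stops at stage 1 (A-rich CBR in 3 species
    only); g5 has no A-rich CBR at all; g6 is HAP40-like again but with two
    species absent, mirroring an 8-of-10 alignment.
    """
    panel = panel or SpeciesPanel()
    sp = list(panel)
    rng = np.random.default_rng(seed)

    def seeds():
        return int(rng.integers(0, 2**31 - 1))

    five, three = tuple(sp[:5]), tuple(sp[:3])
    plans = [
        GroupPlan(
            "g1", seeds(), 400, tuple(sp),
            plants=(
                Plant("CBR:A", five, Interval(60, 140), bias=0.6),
                Plant("polyX:P", (sp[0], sp[1]), Interval(170, 181)),
                Plant("IDR", five, Interval(50, 150)),
            ),
        ),
        GroupPlan(
            "g2", seeds(), 400, tuple(sp),
            plants=(Plant("CBR:A", five, Interval(80, 160), bias=0.6),),
        ),
        GroupPlan(
            "g3", seeds(), 400, tuple(sp),
            plants=(
                Plant("CBR:A", five, Interval(100, 170), bias=0.6),
                Plant("polyX:A", (sp[0],), Interval(200, 211)),
            ),
            # the polyA must overlap the CBR:A interval at consolidation
            # level to disqualify it: plant a second polyA inside the CBR
            # region in a species that has no CBR:A plant
        ),
        GroupPlan(
            "g4", seeds(), 400, tuple(sp),
            plants=(Plant("CBR:A", three, Interval(90, 150), bias=0.6),),
        ),
        GroupPlan("g5", seeds(), 400, tuple(sp)),
        GroupPlan(
            "g6", seeds(), 400, tuple(sp[:4] + sp[6:]),
            plants=(
                Plant("CBR:A", tuple(sp[:4]), Interval(110, 190), bias=0.6),
                Plant("polyX:P", (sp[0],), Interval(220, 231)),
            ),
        ),
    ]
    # fix g3: overlap the conserved CBR:A with a polyA in a sixth species
    g3 = plans[2]
    plans[2] = replace(
        g3,
        plants=(
            g3.plants[0],
            Plant("polyX:A", (sp[5],), Interval(120, 131)),
        ),
    )
    return plans
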