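"""Detection of the four low-complexity feature classes on ungapped sequences.

* polyX homorepeats: sliding-window rule — at least 8 identical residues in a
  window of 10; overlapping/adjacent candidate windows are merged and the
  merged span is trimmed so it starts and ends on the repeated residue.
* Compositionally biased regions (CBRs): CAST-style iterated maximal-segment
  scoring of the sequence against each residue's homopolymer under BLOSUM62,
  emitting segments scoring >= 40 and masking the biased residue between
  iterations.
* Intrinsically disordered regions (IDRs): thresholded runs of length >= 30
  over a per-residue disorder profile, either ingested from an external
  predictor's output file (adapter) or from a bundled propensity-scale
  fallback meant for testing pipelines, not for production disorder calls.
* Coiled coils (CCs): ingested as interval annotations, never predicted here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import (
    AA20,
    Interval,
    OrthologGroup,
    Sequence,
    SequenceFeature,
)

log = logging.getLogger("lcrevol")

#: Neutral masking symbol used during CAST iteration; scores 0 against every
#: target residue, which guarantees a strict score decrease and termination.
MASK = "#"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# residues missing from BLOSUM62 are scored via the ambiguity row X
_MATRIX_FALLBACK = {"U": "X", "O": "X", "J": "X"}


def load_matrix(path: str | Path | None = None):
    """Return the substitution matrix (default: biopython's BLOSUM62).

    ``path`` may point to a plain-text square table in the standard NCBI
    matrix format for non-default scoring.
    """
    if path is None:
        return _BLOSUM62
    with open(path) as fh:
        return substitution_matrices.read(fh)


def _score_row(residues: str, target: str, matrix) -> np.ndarray:
    """Per-position scores of ``residues`` against a homopolymer of ``target``."""
    alpha = matrix.alphabet
    lut = {}
    for c in set(residues):
        if c == MASK:
            lut[c] = 0.0
        else:
            cc = c if c in alpha else _MATRIX_FALLBACK.get(c, "X")
            lut[c] = float(matrix[cc, target])
    return np.array([lut[c] for c in residues])


@dataclass(frozen=True)
class DetectorConfig:
    """Detection thresholds.

    polyx_min_count/polyx_window: the 8-in-10 homorepeat rule.
    cast_threshold: minimal maximal-segment score for a CBR call (40 under
    BLOSUM62, i.e. ten alanines or eight glutamates).
    idr_min_length: minimal disordered run (30 residues).
    idr_score_threshold: disorder-score cutoff (0.5, the conventional cutoff
    of predictors scaled to [0, 1]).
    disorder_source: ``"adapter"`` (external per-residue score files) or
    ``"fallback"`` (bundled propensity scale; for pipeline tests).
    """

    polyx_min_count: int = 8
    polyx_window: int = 10
    cast_threshold: float = 40.0
    cast_matrix_path: str | None = None
    idr_min_length: int = 30
    idr_score_threshold: float = 0.5
    disorder_source: str = "adapter"

    def __post_init__(self):
        if not (1 <= self.polyx_min_count <= self.polyx_window):
            raise ValueError("require 1 <= polyx_min_count <= polyx_window")
        if self.cast_threshold <= 0:
            raise ValueError("cast_threshold must be positive")
        if self.idr_min_length < 1:
            raise ValueError("idr_min_length must be >= 1")
        if self.disorder_source not in ("adapter", "fallback"):
            raise ValueError("disorder_source must be 'adapter' or 'fallback'")

    def matrix(self):
        return load_matrix(self.cast_matrix_path)


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] for one sequence."""

    sequence_id: str
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D array")
        if np.any(scores < 0) or np.any(scores > 1):
            raise ValueError("disorder scores must lie in [0, 1]")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.scores.size


# ---------------------------------------------------------------------------
# polyX


def scan_polyx(seq: Sequence, cfg: DetectorConfig = DetectorConfig()) -> list[SequenceFeature]:
    """Detect homorepeats with the count-in-window rule.

    For each residue type X, every window of ``polyx_window`` consecutive
    positions holding at least ``polyx_min_count`` copies of X is a candidate;
    overlapping or directly adjacent candidate windows are merged, and each
    merged span is trimmed to the first/last occurrence of X inside it.
    Sequences shorter than the window are scanned as one truncated window
    when they are at least ``polyx_min_count`` long.
    """
    residues = seq.residues
    n = len(residues)
    W, C = cfg.polyx_window, cfg.polyx_min_count
    features: list[SequenceFeature] = []
    if n < C:
        return features
    arr = np.frombuffer(residues.encode(), dtype="S1")
    for x in sorted(set(residues) & set(AA20)):
        hits = (arr == x.encode()).astype(np.int64)
        spans: list[tuple[int, int]] = []  # candidate windows, 0-based incl.
        if n < W:
            if int(hits.sum()) >= C:
                spans.append((0, n - 1))
        else:
            counts = np.convolve(hits, np.ones(W, dtype=np.int64), mode="valid")
            for i in np.flatnonzero(counts >= C):
                spans.append((int(i), int(i) + W - 1))
        if not spans:
            continue
        # merge windows overlapping by >=1 position or directly adjacent
        merged = [spans[0]]
        for s, e in spans[1:]:
            ps, pe = merged[-1]
            if s <= pe + 1:
                merged[-1] = (ps, max(pe, e))
            else:
                merged.append((s, e))
        for s, e in merged:
            inside = np.flatnonzero(hits[s : e + 1]) + s
            features.append(
                SequenceFeature(
                    seq.identifier,
                    f"polyX:{x}",
                    Interval(int(inside[0]) + 1, int(inside[-1]) + 1),
                )
            )
    features.sort(key=lambda f: (f.interval.start, f.kind))
    return features


# ---------------------------------------------------------------------------
# CAST-style CBRs


def max_homopolymer_segment(
    seq: Sequence | str, residue: str, matrix=None
) -> tuple[float, Interval] | None:
    """Best-scoring contiguous segment of ``seq`` against poly-``residue``.

    Uses the maximal-segment rule (running sum reset at zero). Returns
    ``(score, interval)`` or None when no segment scores positively. Ties are
    broken in favour of the leftmost segment.
    """
    if residue not in AA20:
        raise ValueError(f"{residue!r} is not a standard amino acid")
    residues = seq.residues if isinstance(seq, Sequence) else seq
    matrix = _BLOSUM62 if matrix is None else matrix
    scores = _score_row(residues, residue, matrix)
    best = 0.0
    best_iv: tuple[int, int] | None = None
    running = 0.0
    start = 0
    for i, s in enumerate(scores):
        if running <= 0:
            running = 0.0
            start = i
        running += s
        if running > best:
            best = running
            best_iv = (start, i)
    if best_iv is None:
        return None
    return best, Interval(best_iv[0] + 1, best_iv[1] + 1)


def scan_cbr_cast(
    seq: Sequence, cfg: DetectorConfig = DetectorConfig()
) -> list[SequenceFeature]:
    """CAST-style compositional-bias detection.

    For each residue type independently: repeatedly find the maximal-scoring
    homopolymer segment; while it reaches ``cast_threshold``, emit it as a
    CBR and mask the biased residue inside the emitted interval with a
    neutral symbol (score 0 against everything), then rescan. Masking makes
    the attainable score strictly decrease, so the iteration terminates.
    """
    matrix = cfg.matrix()
    features: list[SequenceFeature] = []
    for x in sorted(set(seq.residues) & set(AA20)):
        work = list(seq.residues)
        while True:
            hit = max_homopolymer_segment("".join(work), x, matrix)
            if hit is None or hit[0] < cfg.cast_threshold:
                break
            score, iv = hit
            masked = [i for i in range(iv.start - 1, iv.end) if work[i] == x]
            if not masked:
                # a threshold segment without a single copy of x (possible
                # through residues scoring positively against x) is not an
                # x-rich region, and masking could not reduce it: stop
                break
            features.append(
                SequenceFeature(seq.identifier, f"CBR:{x}", iv, float(score))
            )
            for i in masked:
                work[i] = MASK
    features.sort(key=lambda f: (f.interval.start, f.kind))
    return features


# ---------------------------------------------------------------------------
# Disorder


def disorder_adapter(path: str | Path, seq: Sequence) -> DisorderProfile:
    """Ingest an external predictor's per-residue output.

    Expected format: whitespace-separated ``position residue score`` lines,
    ``#`` comments allowed — the common long-disorder predictor output.
    Positions must run 1..len(seq) and residues must match the sequence.
    """
    path = Path(path)
    scores = np.full(len(seq), np.nan)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'pos res score'")
            pos, res, val = int(parts[0]), parts[1].upper(), float(parts[2])
            if not (1 <= pos <= len(seq)):
                raise ValueError(
                    f"{path}:{lineno}: position {pos} outside sequence "
                    f"{seq.identifier} (length {len(seq)})"
                )
            if res != seq.residues[pos - 1]:
                raise ValueError(
                    f"{path}:{lineno}: residue {res} does not match sequence "
                    f"{seq.identifier} ({seq.residues[pos - 1]} at {pos})"
                )
            scores[pos - 1] = val
    if np.isnan(scores).any():
        missing = int(np.isnan(scores).sum())
        raise ValueError(f"{path}: {missing} positions missing for {seq.identifier}")
    return DisorderProfile(seq.identifier, scores)


def write_disorder_scores(profile: DisorderProfile, seq: Sequence, path: str | Path) -> None:
    """Write a per-residue score file in the adapter's 3-column format."""
    with open(path, "w") as fh:
        fh.write(f"# disorder scores for {seq.identifier}\n")
        for i, (res, sc) in enumerate(zip(seq.residues, profile.scores), start=1):
            fh.write(f"{i}\t{res}\t{sc:.4f}\n")


#: TOP-IDP disorder propensity scale (Campen et al. 2008); higher = more
#: disorder-promoting. Spans [-0.884 (W), 0.987 (P)].
TOP_IDP = {
    "A": 0.06, "C": 0.02, "D": 0.192, "E": 0.736, "F": -0.697,
    "G": 0.166, "H": 0.303, "I": -0.486, "K": 0.586, "L": -0.326,
    "M": -0.397, "N": 0.007, "P": 0.987, "Q": 0.318, "R": 0.180,
    "S": 0.341, "T": 0.059, "V": -0.121, "W": -0.884, "Y": -0.510,
}
_SCALE_LO = min(TOP_IDP.values())
_SCALE_HI = max(TOP_IDP.values())

#: Smoothing window of the fallback predictor (centered moving average,
#: truncated at the sequence ends).
FALLBACK_SMOOTHING = 21


def fallback_disorder_scores(
    seq: Sequence, cfg: DetectorConfig = DetectorConfig()
) -> DisorderProfile:
    """Propensity-scale disorder profile (testing stand-in, not a predictor).

    Raw TOP-IDP values are mapped affinely from the scale's range onto
    [0, 1], then smoothed with a centered moving average of width
    :data:`FALLBACK_SMOOTHING` truncated at the ends.
    """
    try:
        raw = np.array([TOP_IDP[c] for c in seq.residues])
    except KeyError as e:
        raise ValueError(
            f"{seq.identifier}: no propensity-scale entry for residue {e.args[0]!r}"
        ) from None
    scaled = (raw - _SCALE_LO) / (_SCALE_HI - _SCALE_LO)
    half = FALLBACK_SMOOTHING // 2
    csum = np.concatenate([[0.0], np.cumsum(scaled)])
    n = scaled.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return DisorderProfile(seq.identifier, np.clip(smoothed, 0.0, 1.0))


def predict_idr(
    profile: DisorderProfile, cfg: DetectorConfig = DetectorConfig()
) -> list[SequenceFeature]:
    """IDRs = maximal runs of scores >= threshold, at least 30 residues long."""
    above = profile.scores >= cfg.idr_score_threshold
    features = []
    boundaries = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    for s, e in zip(boundaries[::2], boundaries[1::2]):
        if e - s >= cfg.idr_min_length:
            features.append(
                SequenceFeature(profile.sequence_id, "IDR", Interval(int(s) + 1, int(e)))
            )
    return features


# ---------------------------------------------------------------------------
# Orchestration


def detect_all(
    group: OrthologGroup,
    cfg: DetectorConfig = DetectorConfig(),
    annotations: Mapping[str, Iterable[SequenceFeature]] | None = None,
    disorder: Mapping[str, "str | Path | DisorderProfile"] | None = None,
) -> dict[str, list[SequenceFeature]]:
    """Detect all feature classes for every sequence of an ortholog group.

    ``annotations`` carries ingested coiled-coil intervals keyed by sequence
    id; ``disorder`` maps sequence ids to external score files (or profiles)
    when ``cfg.disorder_source == "adapter"``. Annotation ids that do not
    belong to the group are skipped with a warning. Returns features in
    sequence coordinates keyed by sequence id.
    """
    annotations = dict(annotations or {})
    disorder = dict(disorder or {})
    known_ids = set(group.sequence_ids())
    for stray in sorted(set(annotations) - known_ids):
        log.warning(
            "%s: annotation for unknown sequence %r skipped", group.group_id, stray
        )
    result: dict[str, list[SequenceFeature]] = {}
    for species in group.present_species:
        seq = group.ungapped_sequence(species)
        feats: list[SequenceFeature] = []
        feats.extend(scan_polyx(seq, cfg))
        feats.extend(scan_cbr_cast(seq, cfg))
        if cfg.disorder_source == "fallback":
            prof = fallback_disorder_scores(seq, cfg)
            feats.extend(predict_idr(prof, cfg))
        elif seq.identifier in disorder:
            src = disorder[seq.identifier]
            prof = src if isinstance(src, DisorderProfile) else disorder_adapter(src, seq)
            if len(prof) != len(seq):
                raise ValueError(
                    f"{seq.identifier}: disorder profile length {len(prof)} != "
                    f"sequence length {len(seq)}"
                )
            feats.extend(predict_idr(prof, cfg))
        for cc in annotations.get(seq.identifier, []):
            if cc.kind != "CC":
                raise ValueError(
                    f"{seq.identifier}: ingested annotations must be CC, got {cc.kind}"
                )
            if cc.interval.end > len(seq):
                raise ValueError(
                    f"{seq.identifier}: CC interval {cc.interval} outside sequence"
                )
            feats.append(cc)
        feats.sort(key=lambda f: (f.interval.start, f.kind))
        result[seq.identifier] = feats
    return result
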