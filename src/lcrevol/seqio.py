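"""Sequence, alignment and feature-table I/O with gap-aware coordinate mapping.

All user-facing coordinates are 1-based inclusive (the UniProt convention);
0-based half-open indexing appears only at internal numpy boundaries. The gap
character is ``-``; ``.`` is normalized to ``-`` on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger("lcrevol")

GAP = "-"

#: The 20 standard residues, alphabetical one-letter order.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in input sequences: the 20 standard ones plus ambiguity
#: codes (X unknown, B = D/N, Z = E/Q, J = I/L) and the rare U/O.
ALPHABET = frozenset(AA20 + "XBZJUO*")

#: Fixed species panel: human first, then increasingly distant vertebrates
#: (chimpanzee, two rodents, a marsupial, two Sauria, a frog and two fish).
#: Conservation profile strings are always written in this order.
DEFAULT_PANEL = (
    "Homo sapiens",
    "Pan troglodytes",
    "Mus musculus",
    "Rattus norvegicus",
    "Sarcophilus harrisii",
    "Gallus gallus",
    "Anolis carolinensis",
    "Xenopus tropicalis",
    "Danio rerio",
    "Takifugu rubripes",
)

#: Default FASTA header convention: ``accession|Species_tag`` with underscores
#: standing in for spaces in the species name.
DEFAULT_HEADER_REGEX = re.compile(r"^(?P<id>[^|\s]+)\|(?P<species>[^|\s]+)")

#: Controlled vocabulary of feature kinds: intrinsically disordered regions,
#: coiled coils, 20 compositionally biased region types and 20 homorepeats.
KINDS = ("IDR", "CC") + tuple(f"CBR:{a}" for a in AA20) + tuple(
    f"polyX:{a}" for a in AA20
)
_KIND_SET = frozenset(KINDS)


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def species_tag(species: str) -> str:
    """``Homo sapiens`` -> ``Homo_sapiens`` (used in FASTA headers)."""
    return species.replace(" ", "_")


@dataclass(frozen=True)
class Interval:
    """1-based inclusive residue or alignment-column interval."""

    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class SequenceFeature:
    """One detected low-complexity feature on one (ungapped) sequence.

    ``kind`` is one of :data:`KINDS`; for ``polyX:X`` features the interval
    begins and ends on the repeated residue X.
    """

    sequence_id: str
    kind: str
    interval: Interval
    score: float | None = None

    def __post_init__(self):
        if self.kind not in _KIND_SET:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def residue(self) -> str | None:
        """The biased residue for CBR:X / polyX:X kinds, else None."""
        return self.kind.split(":", 1)[1] if ":" in self.kind else None


@dataclass(frozen=True)
class Sequence:
    identifier: str
    species: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.identifier}: empty sequence")
        residues = self.residues.upper()
        bad = set(residues) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.identifier}: non-amino-acid characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


class SpeciesPanel:
    """Fixed, ordered species panel (human first).

    The order is load-bearing: every conservation profile string is written
    and parsed in panel order.
    """

    def __init__(self, species: TypingSequence[str] = DEFAULT_PANEL):
        if len(set(species)) != len(species):
            raise ValueError("duplicate species in panel")
        self.species = tuple(species)
        self._index = {s: i for i, s in enumerate(self.species)}
        self._by_tag = {species_tag(s): s for s in self.species}

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def __contains__(self, s: str) -> bool:
        return s in self._index

    def index(self, s: str) -> int:
        return self._index[s]

    def from_tag(self, tag: str) -> str | None:
        """Resolve a header tag like ``Danio_rerio`` to the panel name."""
        if tag in self._by_tag:
            return self._by_tag[tag]
        return tag if tag in self._index else None

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered species pairs in fixed (panel) order."""
        return [
            (self.species[i], self.species[j])
            for i in range(len(self.species))
            for j in range(i + 1, len(self.species))
        ]


class CoordinateMap:
    """Bidirectional map between 1-based ungapped sequence positions and
    1-based alignment columns of one aligned sequence."""

    def __init__(self, aligned: str):
        cols = np.flatnonzero(np.frombuffer(aligned.encode(), dtype="S1") != b"-")
        if cols.size == 0:
            raise ValueError("all-gap sequence has no coordinate map")
        self._seq2col = cols + 1  # seq pos i (1-based) -> column _seq2col[i-1]
        self._col2seq = np.zeros(len(aligned), dtype=np.int64)
        self._col2seq[cols] = np.arange(1, cols.size + 1)
        self.alignment_length = len(aligned)
        self.sequence_length = int(cols.size)

    def to_column(self, pos: int) -> int:
        if not (1 <= pos <= self.sequence_length):
            raise IndexError(f"sequence position {pos} out of range")
        return int(self._seq2col[pos - 1])

    def to_position(self, column: int) -> int:
        """Sequence position at a column; raises on gap columns."""
        if not (1 <= column <= self.alignment_length):
            raise IndexError(f"column {column} out of range")
        pos = int(self._col2seq[column - 1])
        if pos == 0:
            raise IndexError(f"column {column} is a gap in this sequence")
        return pos

    def is_gap(self, column: int) -> bool:
        if not (1 <= column <= self.alignment_length):
            raise IndexError(f"column {column} out of range")
        return int(self._col2seq[column - 1]) == 0

    def map_interval(self, iv: Interval) -> Interval:
        """Sequence interval -> contiguous column interval.

        Interior gap columns are spanned, so a feature stays a single range
        in column space.
        """
        return Interval(self.to_column(iv.start), self.to_column(iv.end))

    def columns_of(self, iv: Interval) -> np.ndarray:
        """The (sorted) set of non-gap columns covered by a sequence interval."""
        if not (1 <= iv.start and iv.end <= self.sequence_length):
            raise IndexError(f"interval {iv} out of sequence range")
        return self._seq2col[iv.start - 1 : iv.end]


@dataclass
class AlignedMember:
    identifier: str
    species: str
    aligned: str

    def ungapped(self) -> str:
        return self.aligned.replace(GAP, "")


class OrthologGroup:
    """One aligned ortholog family over (a subset of) the species panel."""

    def __init__(
        self,
        group_id: str,
        members: Iterable[AlignedMember],
        panel: SpeciesPanel | None = None,
        leading_species: str = "Homo sapiens",
    ):
        self.group_id = group_id
        self.panel = panel or SpeciesPanel()
        self.leading_species = leading_species
        self.members: dict[str, AlignedMember] = {}
        lengths = set()
        for m in members:
            if m.species not in self.panel:
                raise ValueError(
                    f"{group_id}: species {m.species!r} not in the panel"
                )
            if m.species in self.members:
                raise ValueError(f"{group_id}: duplicate species {m.species!r}")
            self.members[m.species] = m
            lengths.add(len(m.aligned))
        if len(lengths) > 1:
            raise ValueError(
                f"{group_id}: aligned sequences have unequal lengths {sorted(lengths)}"
            )
        self.alignment_length = lengths.pop() if lengths else 0

    @property
    def present_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.panel if s in self.members)

    @property
    def absent_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.panel if s not in self.members)

    def member(self, species: str) -> AlignedMember:
        return self.members[species]

    def member_by_id(self, identifier: str) -> AlignedMember:
        for m in self.members.values():
            if m.identifier == identifier:
                return m
        raise KeyError(identifier)

    def sequence_ids(self) -> tuple[str, ...]:
        return tuple(self.members[s].identifier for s in self.present_species)

    def coordinate_map(self, species: str) -> CoordinateMap:
        return CoordinateMap(self.members[species].aligned)

    def ungapped_sequence(self, species: str) -> Sequence:
        m = self.members[species]
        return Sequence(m.identifier, m.species, m.ungapped())

    def human(self) -> AlignedMember:
        if self.leading_species not in self.members:
            raise KeyError(
                f"{self.group_id}: leading species {self.leading_species!r} absent"
            )
        return self.members[self.leading_species]


# ---------------------------------------------------------------------------
# FASTA


def _validate_fasta_lines(path: Path) -> None:
    with open(path) as fh:
        saw_header = False
        for i, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                saw_header = True
                if len(s) == 1:
                    raise ParseError("empty FASTA header", line=i)
            elif not saw_header:
                raise ParseError("sequence data before first FASTA header", line=i)
    if not saw_header:
        raise ParseError(f"{path}: empty or headerless FASTA file")


def _parse_header(
    header: str, header_regex: re.Pattern, panel: SpeciesPanel | None
) -> tuple[str, str]:
    m = header_regex.match(header)
    if m is None:
        log.warning("FASTA header %r lacks a species token; species=unknown", header)
        return header.split()[0], "unknown"
    identifier = m.group("id")
    tag = m.group("species")
    species = tag.replace("_", " ")
    if panel is not None and species not in panel:
        resolved = panel.from_tag(tag)
        if resolved is None:
            log.warning("species tag %r not in panel; species=unknown", tag)
            return identifier, "unknown"
        species = resolved
    return identifier, species


def read_fasta(
    path: str | Path,
    header_regex: re.Pattern = DEFAULT_HEADER_REGEX,
    panel: SpeciesPanel | None = None,
) -> list[Sequence]:
    """Read ungapped protein sequences; species parsed from headers.

    Records whose headers do not match ``header_regex`` are kept with
    species ``"unknown"`` (a warning is logged).
    """
    path = Path(path)
    _validate_fasta_lines(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        identifier, species = _parse_header(rec.description, header_regex, panel)
        residues = str(rec.seq).upper().replace(".", GAP).replace(GAP, "")
        out.append(Sequence(identifier, species, residues))
    return out


def write_fasta(sequences: Iterable[Sequence], path: str | Path) -> None:
    """Write sequences with the ``id|Species_tag`` header convention."""
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.identifier}|{species_tag(s.species)}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


def read_alignment(
    path: str | Path,
    panel: SpeciesPanel | None = None,
    group_id: str | None = None,
    header_regex: re.Pattern = DEFAULT_HEADER_REGEX,
) -> OrthologGroup:
    """Read one ortholog-group alignment (gapped FASTA, equal lengths).

    Absent panel species are simply recorded as missing; duplicate species
    or ragged lengths raise.
    """
    path = Path(path)
    panel = panel or SpeciesPanel()
    _validate_fasta_lines(path)
    members = []
    for rec in SeqIO.parse(str(path), "fasta"):
        identifier, species = _parse_header(rec.description, header_regex, panel)
        if species == "unknown":
            raise ParseError(
                f"{path}: cannot assign record {rec.description!r} to a panel species"
            )
        aligned = str(rec.seq).upper().replace(".", GAP)
        members.append(AlignedMember(identifier, species, aligned))
    return OrthologGroup(group_id or path.stem, members, panel=panel)


def write_alignment(group: OrthologGroup, path: str | Path) -> None:
    with open(path, "w") as fh:
        for species in group.present_species:
            m = group.members[species]
            fh.write(f">{m.identifier}|{species_tag(species)}\n")
            for i in range(0, len(m.aligned), 60):
                fh.write(m.aligned[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Feature tables

_FEATURE_COLUMNS = ["group", "sequence", "kind", "start", "end", "score", "profile"]


def read_feature_annotations(path: str | Path) -> dict[str, list[SequenceFeature]]:
    """Read a per-sequence feature TSV (sequence, kind, start, end[, score]).

    Returns features grouped by sequence identifier. Unknown kinds and
    inverted intervals raise.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    required = {"sequence", "kind", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[SequenceFeature]] = {}
    for row in df.itertuples(index=False):
        kind = str(row.kind)
        if kind not in _KIND_SET:
            raise ParseError(f"{path}: unknown feature kind {kind!r}")
        start, end = int(row.start), int(row.end)
        if start > end:
            raise ParseError(f"{path}: start {start} > end {end}")
        score = getattr(row, "score", None)
        score = None if score is None or pd.isna(score) else float(score)
        feat = SequenceFeature(str(row.sequence), kind, Interval(start, end), score)
        out.setdefault(feat.sequence_id, []).append(feat)
    return out


def write_feature_table(
    features: Iterable[SequenceFeature],
    path: str | Path,
    group_ids: Mapping[str, str] | None = None,
) -> None:
    """Write a deterministic, sorted per-sequence feature TSV.

    ``group_ids`` optionally maps sequence id -> ortholog group id. The
    ``profile`` column is left empty here; consolidated tables fill it
    (see :func:`lcrevol.consolidate.write_consolidated_table`).
    """
    rows = []
    for f in features:
        rows.append(
            {
                "group": (group_ids or {}).get(f.sequence_id, ""),
                "sequence": f.sequence_id,
                "kind": f.kind,
                "start": f.interval.start,
                "end": f.interval.end,
                "score": "" if f.score is None else f.score,
                "profile": "",
            }
        )
    df = pd.DataFrame(rows, columns=_FEATURE_COLUMNS)
    df = df.sort_values(["group", "sequence", "kind", "start"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> dict[str, list[SequenceFeature]]:
    """Inverse of :func:`write_feature_table` (profile column ignored)."""
    return read_feature_annotations(path)
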