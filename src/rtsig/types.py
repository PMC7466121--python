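"""Core value types shared across the pipeline.

Coordinates are 1-based and fully closed throughout the public API: position
``pos`` on a reference of length ``L`` satisfies ``1 <= pos <= L``, and the 3'
neighbour of ``pos`` is ``pos + 1`` (reverse transcription walks the template
from its 3' end toward the 5' end, i.e. from high positions to low ones).
Any 0-based bookkeeping stays inside the I/O layer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import ValidationError

#: Canonical template alphabet (RNA ``U`` is normalized to ``T`` on input).
DNA_BASES = "ACGT"
#: Alphabet of sequenced (cDNA) bases; ``N`` is an unresolved base call.
READ_BASES = "ACGTN"


class OpKind(enum.Enum):
    """Alignment operation kinds, a minimal CIGAR vocabulary."""

    ALIGNED = "M"    # consumes query and reference
    DELETION = "D"   # consumes reference only (a "jump" in RT terms)
    INSERTION = "I"  # consumes query only
    SOFTCLIP = "S"   # consumes query only


class Orientation(enum.Enum):
    """Read orientation within a pair.

    FORWARD reads (first in pair) are tallied into the capital-letter base
    counters of the profile file (A, C, G, T, N); REVERSE reads (second in
    pair) into the small-letter counters (a, c, g, t, n).
    """

    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class CigarOp:
    kind: OpKind
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"CIGAR op length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class AlignedRead:
    """A minimal alignment record.

    Attributes
    ----------
    read_id : str
        Query name; mates of a pair share it.
    ref_seg : str
        Reference identifier (pipe-delimited tRNA ids in practice).
    start : int
        1-based leftmost reference position of the alignment footprint.
    ops : tuple of CigarOp
        Ordered alignment operations; must start and end with a
        query-consuming op (never a deletion).
    query : str
        Read bases over A/C/G/T/N, covering all query-consuming ops.
    orientation : Orientation
        FORWARD (R1) or REVERSE (R2) counting convention.
    """

    read_id: str
    ref_seg: str
    start: int
    ops: tuple[CigarOp, ...]
    query: str
    orientation: Orientation = Orientation.FORWARD

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"{self.read_id}: start must be >= 1, got {self.start}")
        if not self.ops:
            raise ValidationError(f"{self.read_id}: empty op list")
        if self.ops[0].kind is OpKind.DELETION or self.ops[-1].kind is OpKind.DELETION:
            raise ValidationError(f"{self.read_id}: alignment may not begin or end with a deletion")
        q_len = sum(op.length for op in self.ops if op.kind is not OpKind.DELETION)
        if q_len != len(self.query):
            raise ValidationError(
                f"{self.read_id}: query length {len(self.query)} does not match "
                f"query-consuming op total {q_len}"
            )
        bad = set(self.query) - set(READ_BASES)
        if bad:
            raise ValidationError(f"{self.read_id}: query bases outside ACGTN: {sorted(bad)}")

    @property
    def ref_span(self) -> int:
        """Number of reference positions covered (aligned or deleted)."""
        return sum(op.length for op in self.ops if op.kind in (OpKind.ALIGNED, OpKind.DELETION))

    @property
    def end(self) -> int:
        """1-based rightmost reference position of the footprint (inclusive)."""
        return self.start + self.ref_span - 1

    def aligned_pairs(self) -> Iterator[tuple[int, str]]:
        """Yield (reference position, query base) for every ALIGNED base."""
        pos = self.start
        qi = 0
        for op in self.ops:
            if op.kind is OpKind.ALIGNED:
                for k in range(op.length):
                    yield pos + k, self.query[qi + k]
                pos += op.length
                qi += op.length
            elif op.kind is OpKind.DELETION:
                pos += op.length
            else:  # INSERTION / SOFTCLIP consume query only
                qi += op.length

    def deleted_positions(self) -> Iterator[int]:
        """Yield reference positions skipped by DELETION ops."""
        pos = self.start
        for op in self.ops:
            if op.kind is OpKind.DELETION:
                yield from range(pos, pos + op.length)
                pos += op.length
            elif op.kind is OpKind.ALIGNED:
                pos += op.length


@dataclass
class ReferenceSet:
    """Reference sequences keyed by their (unique) identifiers.

    Sequences are stored in the DNA alphabet; ``U`` is normalized to ``T`` at
    construction time.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for name, seq in self.entries.items():
            if not name:
                raise ValidationError("empty reference identifier")
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - set(DNA_BASES)
            if bad:
                raise ValidationError(f"reference {name!r}: non-nucleotide characters {sorted(bad)}")
            if not seq:
                raise ValidationError(f"reference {name!r}: empty sequence")
            normalized[name] = seq
        self.entries = normalized

    def __getitem__(self, name: str) -> str:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def length(self, name: str) -> int:
        return len(self.entries[name])

    def base_at(self, name: str, pos: int) -> str:
        """Reference base at 1-based position ``pos``."""
        return self.entries[name][pos - 1]


@dataclass(frozen=True)
class ModificationAnnotation:
    """One annotated modified site: (reference, 1-based position, short code)."""

    ref_seg: str
    pos: int
    mod: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.ref_seg}: annotation position must be >= 1, got {self.pos}")
        if not self.mod:
            raise ValidationError(f"{self.ref_seg}:{self.pos}: empty modification code")


def annotation_index(
    annotations: list[ModificationAnnotation],
    refs: ReferenceSet | None = None,
) -> dict[tuple[str, int], str]:
    """Index annotations by (ref_seg, pos), enforcing uniqueness.

    When ``refs`` is given, positions are validated against sequence lengths.
    """
    index: dict[tuple[str, int], str] = {}
    for ann in annotations:
        key = (ann.ref_seg, ann.pos)
        if key in index:
            raise ValidationError(f"duplicate annotation for {ann.ref_seg} position {ann.pos}")
        if refs is not None:
            if ann.ref_seg not in refs:
                raise ValidationError(f"annotation references unknown sequence {ann.ref_seg!r}")
            if ann.pos > refs.length(ann.ref_seg):
                raise ValidationError(
                    f"annotation position {ann.pos} exceeds length "
                    f"{refs.length(ann.ref_seg)} of {ann.ref_seg!r}"
                )
        index[key] = ann.mod
    return index


#: Exact column order of the profile file (tab-separated, one row per position).
PROFILE_COLUMNS = (
    "ref_seg", "mod", "pos", "ref_base", "cov", "pre_base", "mism_rate",
    "A", "G", "T", "C", "N", "a", "g", "t", "c", "n",
    "single_jump_rate_direct", "single_jump_rate_delayed", "double_jump_rate",
    "arrest_rate",
)

#: Base-counter columns in profile order: capitals = FORWARD, small = REVERSE.
COUNT_COLUMNS = ("A", "G", "T", "C", "N", "a", "g", "t", "c", "n")


@dataclass
class PositionProfile:
    """One row of the per-position profile file.

    ``cov`` counts aligned bases only (a read deleting the position does not
    contribute), split by incorporated base and read orientation in the ten
    counters. ``pre_base`` is the reference base 3' of the position — the base
    the reverse transcriptase reads immediately before reaching it — or the
    empty string at the 3' terminus. All rates are fractions in [0, 1].
    """

    ref_seg: str
    mod: str
    pos: int
    ref_base: str
    cov: int
    pre_base: str
    mism_rate: float
    A: int
    G: int
    T: int
    C: int
    N: int
    a: int
    g: int
    t: int
    c: int
    n: int
    single_jump_rate_direct: float
    single_jump_rate_delayed: float
    double_jump_rate: float
    arrest_rate: float

    def base_counts(self) -> dict[str, int]:
        """The ten orientation-split base counters, keyed by column name."""
        return {name: getattr(self, name) for name in COUNT_COLUMNS}

    def validate(self) -> None:
        total = sum(self.base_counts().values())
        if total != self.cov:
            raise ValidationError(
                f"{self.ref_seg}:{self.pos}: cov {self.cov} != base counter sum {total}"
            )
        if self.pos < 1:
            raise ValidationError(f"{self.ref_seg}: pos must be >= 1")
        if self.ref_base not in DNA_BASES:
            raise ValidationError(f"{self.ref_seg}:{self.pos}: bad ref_base {self.ref_base!r}")
        for name in ("mism_rate", "single_jump_rate_direct", "single_jump_rate_delayed",
                     "double_jump_rate", "arrest_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.ref_seg}:{self.pos}: {name}={v} outside [0, 1]")


FeatureValues = Mapping[str, float]
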