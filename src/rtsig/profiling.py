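"""Turn alignments into the per-position profile table.

The profile assigns every reference position four signature features:

* **coverage** — number of aligned bases (orientation-split into ten
  counters; a read deleting the position does not count);
* **mismatch rate** — fraction of aligned bases differing from the
  reference base (``N`` counts as a mismatch and sits in the denominator);
* **arrest rate** — relative coverage drop from the 3' neighbour,
  ``clamp((cov(N+1) - cov(N)) / cov(N+1), 0, 1)``; reverse transcription
  proceeds 3'->5', so coverage can only fall (in expectation) toward 5';
* **jump rates** — over reads *spanning* the position (aligned or deleted),
  the fractions with a deletion at the position only (single jump direct),
  at the 5' neighbour N-1 only (single jump delayed, attributed to N), or
  at both (double jump).

Positions with coverage below ``min_cov`` (default 20) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError
from .types import (
    COUNT_COLUMNS,
    AlignedRead,
    ModificationAnnotation,
    Orientation,
    PositionProfile,
    ReferenceSet,
    annotation_index,
)

#: Row order of the forward counters within the accumulator (profile order).
_BASE_ORDER = "AGTCN"
_BASE_ROW = {b: i for i, b in enumerate(_BASE_ORDER)}


@dataclass
class _RefPileup:
    """Counters for one reference; all arrays are indexed 1..L (slot 0 unused)."""

    length: int
    counts: np.ndarray = field(init=False)       # (10, L+1): rows AGTCN (fwd) + agtcn (rev)
    span: np.ndarray = field(init=False)         # reads whose footprint covers pos
    del_direct: np.ndarray = field(init=False)   # deletion at pos only
    del_delayed: np.ndarray = field(init=False)  # deletion at pos-1 only
    del_double: np.ndarray = field(init=False)   # deletions at both pos and pos-1

    def __post_init__(self) -> None:
        self.counts = np.zeros((10, self.length + 1), dtype=np.int64)
        self.span = np.zeros(self.length + 1, dtype=np.int64)
        self.del_direct = np.zeros(self.length + 1, dtype=np.int64)
        self.del_delayed = np.zeros(self.length + 1, dtype=np.int64)
        self.del_double = np.zeros(self.length + 1, dtype=np.int64)

    @property
    def coverage(self) -> np.ndarray:
        """Aligned-base coverage per position (both orientations), index 1..L."""
        return self.counts.sum(axis=0)


class PileupAccumulator:
    """Single-pass pileup over a read stream.

    Maintains, per reference position: the ten orientation-split base
    counters, the number of spanning reads, and the deletion-pattern tallies
    the jump classification needs.
    """

    def __init__(self, refs: ReferenceSet) -> None:
        self.refs = refs
        self.pileups: dict[str, _RefPileup] = {
            name: _RefPileup(refs.length(name)) for name in refs
        }
        self.n_reads = 0
        self.n_aligned_bases = 0

    def add(self, read: AlignedRead) -> None:
        if read.ref_seg not in self.pileups:
            raise ValidationError(f"read {read.read_id!r} references unknown sequence {read.ref_seg!r}")
        pile = self.pileups[read.ref_seg]
        if read.end > pile.length:
            raise ValidationError(
                f"read {read.read_id!r} footprint {read.start}..{read.end} exceeds "
                f"reference length {pile.length}"
            )
        row_offset = 0 if read.orientation is Orientation.FORWARD else 5
        for pos, base in read.aligned_pairs():
            pile.counts[row_offset + _BASE_ROW[base], pos] += 1
            self.n_aligned_bases += 1
        fs, fe = read.start, read.end
        pile.span[fs:fe + 1] += 1
        deleted = set(read.deleted_positions())
        checked = deleted | {d + 1 for d in deleted if d + 1 <= fe}
        for pos in checked:
            here = pos in deleted
            prev = (pos - 1) in deleted
            if here and prev:
                pile.del_double[pos] += 1
            elif here:
                pile.del_direct[pos] += 1
            elif prev:
                pile.del_delayed[pos] += 1
        self.n_reads += 1

    def counters_at(self, ref_seg: str, pos: int) -> dict[str, int]:
        """The ten base counters at a position, keyed by profile column name."""
        pile = self.pileups[ref_seg]
        return {name: int(pile.counts[i, pos]) for i, name in enumerate(COUNT_COLUMNS)}


def accumulate(reads: Iterable[AlignedRead], refs: ReferenceSet) -> PileupAccumulator:
    """Accumulate a read stream into per-position counters."""
    acc = PileupAccumulator(refs)
    for read in reads:
        acc.add(read)
    return acc


def mismatch_rate(counts: Mapping[str, int], ref_base: str) -> float:
    """Fraction of aligned bases not matching the reference base.

    ``counts`` holds the ten orientation-split counters (profile column
    names). Matches are the reference base's capital and small counters;
    ``N`` never matches but stays in the denominator. Requires coverage > 0.
    """
    cov = sum(counts.values())
    if cov <= 0:
        raise ValidationError("mismatch rate undefined at zero coverage")
    matches = counts[ref_base.upper()] + counts[ref_base.lower()]
    return (cov - matches) / cov


def arrest_rate(coverage: np.ndarray | list[int]) -> np.ndarray:
    """Per-position arrest rates from a coverage vector.

    ``coverage[i]`` is the aligned-base coverage at 1-based position ``i+1``.
    ``arrest(N) = clamp((cov(N+1) - cov(N)) / cov(N+1), 0, 1)`` where
    ``cov(N+1) > 0``, else 0; the 3'-terminal position has arrest 0 (there is
    no downstream neighbour to compare against).
    """
    cov = np.asarray(coverage, dtype=float)
    out = np.zeros_like(cov)
    if len(cov) < 2:
        return out
    nxt = cov[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(nxt > 0, (nxt - cov[:-1]) / np.where(nxt > 0, nxt, 1.0), 0.0)
    out[:-1] = np.clip(raw, 0.0, 1.0)
    return out


def jump_rates(acc: PileupAccumulator, ref_seg: str, pos: int) -> tuple[float, float, float]:
    """(direct, delayed, double) jump rates at one position.

    Denominator: reads spanning the position, including deletion-bearing
    reads (which have no aligned base there and would otherwise be invisible
    in the denominator). At position 1 delayed and double are 0 by
    construction; zero span yields (0, 0, 0).
    """
    pile = acc.pileups[ref_seg]
    span = pile.span[pos]
    if span == 0:
        return 0.0, 0.0, 0.0
    return (
        pile.del_direct[pos] / span,
        pile.del_delayed[pos] / span,
        pile.del_double[pos] / span,
    )


def profiles_from_accumulator(
    acc: PileupAccumulator,
    annotations: list[ModificationAnnotation] | None = None,
    min_cov: int = 20,
) -> list[PositionProfile]:
    """Profile rows (one per position with coverage >= ``min_cov``).

    Arrest rates are computed from the full unfiltered coverage vector before
    the filter is applied, so a retained position keeps its true 3'-neighbour
    comparison. Rows are ordered by (ref_seg, pos).
    """
    ann_idx = annotation_index(annotations or [], acc.refs)
    rows: list[PositionProfile] = []
    for ref_seg in sorted(acc.refs):
        seq = acc.refs[ref_seg]
        L = len(seq)
        pile = acc.pileups[ref_seg]
        cov = pile.coverage[1:]  # index 0 -> position 1
        arrest = arrest_rate(cov)
        for pos in range(1, L + 1):
            c = int(cov[pos - 1])
            if c < min_cov:
                continue
            counters = acc.counters_at(ref_seg, pos)
            direct, delayed, double = jump_rates(acc, ref_seg, pos)
            rows.append(PositionProfile(
                ref_seg=ref_seg,
                mod=ann_idx.get((ref_seg, pos), ""),
                pos=pos,
                ref_base=seq[pos - 1],
                cov=c,
                pre_base=seq[pos] if pos < L else "",
                mism_rate=mismatch_rate(counters, seq[pos - 1]),
                **counters,
                single_jump_rate_direct=direct,
                single_jump_rate_delayed=delayed,
                double_jump_rate=double,
                arrest_rate=float(arrest[pos - 1]),
            ))
    return rows


def build_profiles(
    reads: Iterable[AlignedRead],
    refs: ReferenceSet,
    annotations: list[ModificationAnnotation] | None = None,
    min_cov: int = 20,
) -> list[PositionProfile]:
    """Full pipeline step: pileup a read stream and emit profile rows."""
    return profiles_from_accumulator(accumulate(reads, refs), annotations, min_cov)
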