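"""Shared test utilities: read builders, an independent brute-force profiler
(the oracle build_profiles is checked against), and hypothesis strategies."""

from __future__ import annotations

import re

import numpy as np
from hypothesis import strategies as st

from rtsig import (
    AlignedRead,
    CigarOp,
    ModificationAnnotation,
    OpKind,
    Orientation,
    PositionProfile,
    ReferenceSet,
)

_CIGAR_RE = re.compile(r"(\d+)([MDIS])")
_KIND = {"M": OpKind.ALIGNED, "D": OpKind.DELETION, "I": OpKind.INSERTION, "S": OpKind.SOFTCLIP}


def mk_read(
    ref_seg: str,
    start: int,
    cigar: str,
    query: str,
    orientation: Orientation = Orientation.FORWARD,
    read_id: str = "r",
) -> AlignedRead:
    """Build an AlignedRead from a CIGAR-like string such as '10M1D5M'."""
    ops = tuple(CigarOp(_KIND[kind], int(length)) for length, kind in _CIGAR_RE.findall(cigar))
    return AlignedRead(read_id=read_id, ref_seg=ref_seg, start=start, ops=ops,
                       query=query, orientation=orientation)


# ---------------------------------------------------------------------------
# Brute-force reference profiler: for every position, re-walk every read.
# Deliberately structured unlike the single-pass accumulator it checks.

def _read_map(read: AlignedRead) -> dict[int, tuple[str, str | None]]:
    """Reference position -> ('base', b) for aligned, ('del', None) for deleted."""
    out: dict[int, tuple[str, str | None]] = {}
    pos, qi = read.start, 0
    for op in read.ops:
        if op.kind is OpKind.ALIGNED:
            for k in range(op.length):
                out[pos + k] = ("base", read.query[qi + k])
            pos += op.length
            qi += op.length
        elif op.kind is OpKind.DELETION:
            for k in range(op.length):
                out[pos + k] = ("del", None)
            pos += op.length
        else:
            qi += op.length
    return out


def bruteforce_profiles(
    reads: list[AlignedRead],
    refs: ReferenceSet,
    annotations: list[ModificationAnnotation],
    min_cov: int = 20,
) -> list[PositionProfile]:
    ann_idx = {(a.ref_seg, a.pos): a.mod for a in annotations}
    rows: list[PositionProfile] = []
    for ref_seg in sorted(refs.entries):
        seq = refs[ref_seg]
        L = len(seq)
        maps = [(_read_map(r), r.orientation) for r in reads if r.ref_seg == ref_seg]
        per_pos = []
        for pos in range(1, L + 1):
            counters = dict.fromkeys(["A", "G", "T", "C", "N", "a", "g", "t", "c", "n"], 0)
            span = direct = delayed = double = 0
            for rmap, orientation in maps:
                entry = rmap.get(pos)
                if entry is None:
                    continue
                span += 1
                kind, base = entry
                if kind == "base":
                    key = base if orientation is Orientation.FORWARD else base.lower()
                    counters[key] += 1
                here = kind == "del"
                prev_entry = rmap.get(pos - 1)
                prev = prev_entry is not None and prev_entry[0] == "del"
                if here and prev:
                    double += 1
                elif here:
                    direct += 1
                elif prev:
                    delayed += 1
            per_pos.append((counters, span, direct, delayed, double))
        cov = [sum(c.values()) for c, *_ in per_pos]
        for pos in range(1, L + 1):
            counters, span, direct, delayed, double = per_pos[pos - 1]
            c = cov[pos - 1]
            if c < min_cov:
                continue
            ref_base = seq[pos - 1]
            matches = counters[ref_base] + counters[ref_base.lower()]
            if pos < L and cov[pos] > 0:
                arrest = max(0.0, min(1.0, (cov[pos] - c) / cov[pos]))
            else:
                arrest = 0.0
            rows.append(PositionProfile(
                ref_seg=ref_seg, mod=ann_idx.get((ref_seg, pos), ""), pos=pos,
                ref_base=ref_base, cov=c,
                pre_base=seq[pos] if pos < L else "",
                mism_rate=(c - matches) / c,
                **counters,
                single_jump_rate_direct=direct / span if span else 0.0,
                single_jump_rate_delayed=delayed / span if span else 0.0,
                double_jump_rate=double / span if span else 0.0,
                arrest_rate=arrest,
            ))
    return rows


# ---------------------------------------------------------------------------
# Hypothesis strategies

@st.composite
def read_for_reference(draw, ref_seg: str, length: int) -> AlignedRead:
    """A structurally valid read: aligned runs separated by deletions, with
    optional soft clips and an internal insertion."""
    n_seg = draw(st.integers(1, 3))
    parts: list[tuple[str, int]] = []
    for i in range(n_seg):
        parts.append(("M", draw(st.integers(1, 6))))
        if i < n_seg - 1:
            parts.append(("D", draw(st.integers(1, 2))))
    if draw(st.booleans()) and len(parts) > 1:
        parts.insert(1, ("I", draw(st.integers(1, 2))))
    pre_clip = draw(st.integers(0, 2))
    post_clip = draw(st.integers(0, 2))
    if pre_clip:
        parts.insert(0, ("S", pre_clip))
    if post_clip:
        parts.append(("S", post_clip))
    span = sum(n for kind, n in parts if kind in "MD")
    if span > length:
        # shrink the first aligned run so the footprint fits
        overshoot = span - length
        parts = [(k, n - overshoot) if k == "M" and n - overshoot >= 1 else (k, n)
                 for k, n in parts]
        span = sum(n for kind, n in parts if kind in "MD")
        if span > length:
            parts = [("M", 1)]
            span = 1
    start = draw(st.integers(1, length - span + 1))
    q_len = sum(n for kind, n in parts if kind != "D")
    query = draw(st.text(alphabet="ACGTN", min_size=q_len, max_size=q_len))
    orientation = draw(st.sampled_from([Orientation.FORWARD, Orientation.REVERSE]))
    cigar = "".join(f"{n}{k}" for k, n in parts)
    return mk_read(ref_seg, start, cigar, query, orientation=orientation,
                   read_id=f"h{draw(st.integers(0, 10_000))}")


@st.composite
def read_set_with_reference(draw, max_reads: int = 50):
    """(ReferenceSet, reads) with up to ``max_reads`` randomized reads."""
    length = draw(st.integers(10, 30))
    seq = draw(st.text(alphabet="ACGT", min_size=length, max_size=length))
    ref_seg = "hyp|ref"
    refs = ReferenceSet({ref_seg: seq})
    reads = draw(st.lists(read_for_reference(ref_seg, length), min_size=0,
                          max_size=max_reads))
    reads = [
        AlignedRead(read_id=f"r{i}", ref_seg=r.ref_seg, start=r.start, ops=r.ops,
                    query=r.query, orientation=r.orientation)
        for i, r in enumerate(reads)
    ]
    return refs, reads
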