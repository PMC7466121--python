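"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (references), SAM/BAM (alignments, via pysam), TSV
(modification annotations; the 21-column profile file), YAML (simulator
condition parameters). All coordinate conversion between the 0-based
alignment world and the package's 1-based closed coordinates happens here.
"""

from __future__ import annotations

import csv
import io as _stdio
import logging
from pathlib import Path
from typing import IO, Iterable, Iterator

import pysam
import yaml
from Bio import SeqIO

from .errors import FormatError, ValidationError
from .types import (
    COUNT_COLUMNS,
    PROFILE_COLUMNS,
    AlignedRead,
    CigarOp,
    ModificationAnnotation,
    OpKind,
    Orientation,
    PositionProfile,
    ReferenceSet,
)

logger = logging.getLogger(__name__)

_RATE_COLUMNS = ("mism_rate", "single_jump_rate_direct", "single_jump_rate_delayed",
                 "double_jump_rate", "arrest_rate")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> ReferenceSet:
    """Read reference sequences from a FASTA file.

    Identifiers are taken verbatim up to the first whitespace (so the
    pipe-delimited tRNA ids survive intact); ``U`` is normalized to ``T``.
    Duplicate identifiers or non-nucleotide characters raise ``FormatError``.
    """
    entries: dict[str, str] = {}
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        if record.id in entries:
            raise FormatError(f"{path}: duplicate FASTA identifier {record.id!r}")
        try:
            refs = ReferenceSet({record.id: str(record.seq)})
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        entries[record.id] = refs[record.id]
    if not entries:
        raise FormatError(f"{path}: no FASTA records found")
    logger.info("read %d reference sequences from %s", n, path)
    return ReferenceSet(entries)


def write_fasta(refs: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name in refs:
            handle.write(f">{name}\n{refs[name]}\n")


# ---------------------------------------------------------------------------
# SAM / BAM

_CIGAR_DECODE = {
    0: OpKind.ALIGNED,    # M
    7: OpKind.ALIGNED,    # =
    8: OpKind.ALIGNED,    # X
    1: OpKind.INSERTION,  # I
    2: OpKind.DELETION,   # D
    4: OpKind.SOFTCLIP,   # S
}
_CIGAR_ENCODE = {OpKind.ALIGNED: 0, OpKind.INSERTION: 1, OpKind.DELETION: 2, OpKind.SOFTCLIP: 4}


def read_alignments(path: str | Path, refs: ReferenceSet) -> Iterator[AlignedRead]:
    """Stream mapped primary alignment records as ``AlignedRead``.

    Unmapped, secondary and supplementary records are skipped. Orientation is
    taken from the read-pairing flags: first-in-pair -> FORWARD,
    second-in-pair -> REVERSE, unpaired -> FORWARD. (The capital/small-letter
    split of the profile counters reflects forward vs. reverse reads of a
    paired-end run, not genomic strand; tRNA references are single-stranded.)
    """
    n_emitted = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.reference_name
            if name not in refs:
                raise FormatError(f"{path}: alignment references unknown sequence {name!r}")
            if rec.query_sequence is None:
                raise FormatError(f"{path}: read {rec.query_name!r} has no query sequence")
            ops: list[CigarOp] = []
            for code, length in rec.cigartuples or ():
                if code == 5:  # hard clip: consumes neither query nor reference
                    continue
                kind = _CIGAR_DECODE.get(code)
                if kind is None:
                    raise FormatError(
                        f"{path}: read {rec.query_name!r} has unsupported CIGAR op code {code}"
                    )
                ops.append(CigarOp(kind, length))
            orientation = (
                Orientation.REVERSE if rec.is_paired and rec.is_read2 else Orientation.FORWARD
            )
            try:
                read = AlignedRead(
                    read_id=rec.query_name,
                    ref_seg=name,
                    start=rec.reference_start + 1,
                    ops=tuple(ops),
                    query=rec.query_sequence.upper(),
                    orientation=orientation,
                )
            except ValidationError as exc:
                raise FormatError(f"{path}: malformed record {rec.query_name!r}: {exc}") from exc
            if read.end > refs.length(name):
                raise FormatError(
                    f"{path}: read {rec.query_name!r} footprint ends at {read.end}, "
                    f"beyond reference {name!r} of length {refs.length(name)}"
                )
            n_emitted += 1
            yield read
    logger.info("ingested %d mapped primary alignments from %s", n_emitted, path)


def write_alignments(reads: Iterable[AlignedRead], refs: ReferenceSet, path: str | Path) -> int:
    """Write reads as a SAM file (text) with a header naming every reference.

    FORWARD reads carry the paired + first-in-pair flags (0x41), REVERSE reads
    paired + second-in-pair (0x81), so orientation round-trips through
    ``read_alignments``. Returns the number of records written.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": refs.length(name)} for name in refs],
    }
    tid = {name: i for i, name in enumerate(refs)}
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.flag = 0x41 if read.orientation is Orientation.FORWARD else 0x81
            rec.reference_id = tid[read.ref_seg]
            rec.reference_start = read.start - 1
            rec.mapping_quality = 255
            rec.cigartuples = [(_CIGAR_ENCODE[op.kind], op.length) for op in read.ops]
            rec.query_sequence = read.query
            out.write(rec)
            n += 1
    logger.info("wrote %d alignments to %s", n, path)
    return n


# ---------------------------------------------------------------------------
# Annotation TSV (columns: ref_seg, pos, mod)

def read_annotation(
    path: str | Path, refs: ReferenceSet | None = None
) -> list[ModificationAnnotation]:
    """Read a modification annotation table (TSV with header ref_seg/pos/mod).

    Positions are 1-based. Duplicate (ref_seg, pos) pairs raise; when ``refs``
    is supplied, positions are validated against sequence lengths.
    """
    annotations: list[ModificationAnnotation] = []
    seen: set[tuple[str, int]] = set()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"ref_seg", "pos", "mod"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: annotation header must contain ref_seg, pos, mod")
        for i, row in enumerate(reader, start=2):
            try:
                pos = int(row["pos"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{i}: non-integer position {row['pos']!r}") from exc
            try:
                ann = ModificationAnnotation(ref_seg=row["ref_seg"], pos=pos, mod=row["mod"])
            except ValidationError as exc:
                raise FormatError(f"{path}:{i}: {exc}") from exc
            key = (ann.ref_seg, ann.pos)
            if key in seen:
                raise FormatError(f"{path}:{i}: duplicate annotation for {key}")
            seen.add(key)
            if refs is not None:
                if ann.ref_seg not in refs:
                    raise FormatError(f"{path}:{i}: unknown reference {ann.ref_seg!r}")
                if ann.pos > refs.length(ann.ref_seg):
                    raise FormatError(
                        f"{path}:{i}: position {ann.pos} beyond reference length "
                        f"{refs.length(ann.ref_seg)}"
                    )
            annotations.append(ann)
    logger.info("read %d annotated sites from %s", len(annotations), path)
    return annotations


def write_annotation(annotations: Iterable[ModificationAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["ref_seg", "pos", "mod"])
        for ann in annotations:
            writer.writerow([ann.ref_seg, ann.pos, ann.mod])


# ---------------------------------------------------------------------------
# Profile TSV (the 21-column per-position table)

def write_profile(rows: Iterable[PositionProfile], path_or_buf: str | Path | IO[str]) -> int:
    """Write profile rows as TSV with the exact 21-column header.

    Rates are serialized with 5 decimal places, counts as plain integers.
    Returns the number of rows written.
    """
    own = isinstance(path_or_buf, (str, Path))
    handle: IO[str] = open(path_or_buf, "w", newline="") if own else path_or_buf  # type: ignore[arg-type]
    n = 0
    try:
        handle.write("\t".join(PROFILE_COLUMNS) + "\n")
        for row in rows:
            row.validate()
            fields = [
                row.ref_seg, row.mod, str(row.pos), row.ref_base, str(row.cov), row.pre_base,
                f"{row.mism_rate:.5f}",
                *(str(getattr(row, c)) for c in COUNT_COLUMNS),
                f"{row.single_jump_rate_direct:.5f}",
                f"{row.single_jump_rate_delayed:.5f}",
                f"{row.double_jump_rate:.5f}",
                f"{row.arrest_rate:.5f}",
            ]
            handle.write("\t".join(fields) + "\n")
            n += 1
    finally:
        if own:
            handle.close()
    return n


def read_profile(path_or_buf: str | Path | IO[str], validate: bool = True) -> list[PositionProfile]:
    """Read a profile TSV back into ``PositionProfile`` rows.

    The inverse of ``write_profile`` and lossless at 5-decimal precision. A
    header deviating from the canonical column order raises ``FormatError``
    naming the first offending column.
    """
    own = isinstance(path_or_buf, (str, Path))
    handle: IO[str] = open(path_or_buf, newline="") if own else path_or_buf  # type: ignore[arg-type]
    try:
        header_line = handle.readline().rstrip("\n")
        header = header_line.split("\t") if header_line else []
        for i, expected in enumerate(PROFILE_COLUMNS):
            got = header[i] if i < len(header) else "<missing>"
            if got != expected:
                raise FormatError(
                    f"profile header mismatch at column {i + 1}: expected {expected!r}, got {got!r}"
                )
        if len(header) != len(PROFILE_COLUMNS):
            raise FormatError(f"profile header has {len(header)} columns, expected {len(PROFILE_COLUMNS)}")
        rows: list[PositionProfile] = []
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(PROFILE_COLUMNS):
                raise FormatError(f"line {lineno}: {len(fields)} fields, expected {len(PROFILE_COLUMNS)}")
            d = dict(zip(PROFILE_COLUMNS, fields))
            try:
                row = PositionProfile(
                    ref_seg=d["ref_seg"], mod=d["mod"], pos=int(d["pos"]),
                    ref_base=d["ref_base"], cov=int(d["cov"]), pre_base=d["pre_base"],
                    mism_rate=float(d["mism_rate"]),
                    **{c: int(d[c]) for c in COUNT_COLUMNS},
                    single_jump_rate_direct=float(d["single_jump_rate_direct"]),
                    single_jump_rate_delayed=float(d["single_jump_rate_delayed"]),
                    double_jump_rate=float(d["double_jump_rate"]),
                    arrest_rate=float(d["arrest_rate"]),
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            if validate:
                try:
                    row.validate()
                except ValidationError as exc:
                    raise FormatError(f"line {lineno}: {exc}") from exc
            rows.append(row)
        return rows
    finally:
        if own:
            handle.close()


def profile_from_string(text: str, validate: bool = True) -> list[PositionProfile]:
    """Parse a profile TSV held in a string."""
    return read_profile(_stdio.StringIO(text), validate=validate)


# ---------------------------------------------------------------------------
# Condition parameter YAML

def load_condition(path: str | Path):
    """Load one simulator condition from a YAML parameter file."""
    from .simulate import RTConditionParams

    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: condition file must hold a mapping")
    try:
        return RTConditionParams.from_dict(data)
    except (KeyError, TypeError, ValidationError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def dump_condition(cond, path: str | Path) -> None:
    """Write one simulator condition as a YAML parameter file."""
    with open(path, "w") as handle:
        yaml.safe_dump(cond.to_dict(), handle, sort_keys=False)
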