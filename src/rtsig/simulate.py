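"""Synthetic reverse-transcription simulator.

Emulates cDNA synthesis over modified tRNA templates. The enzyme walks the
template from its 3' end toward the 5' end; at every position it either

* **arrests** — primer extension terminates, and the cDNA covers positions
  strictly 3' of the blocking site (the site itself is left uncovered, which
  is what makes the coverage-drop arrest estimator asymptotically unbiased);
* **jumps directly** — skips the site, visible as a 1-nt deletion at N;
* **jumps delayed** — incorporates at N, then skips the 5' neighbour,
  visible as a 1-nt deletion at N-1 (attributed to N in the ground truth);
* **jumps double** — skips both, a 2-nt deletion spanning N-1..N; or
* **reads through** — incorporates a base drawn from the site's
  incorporation distribution (misincorporation included).

Event probabilities come from a per-modification table (``per_mod``) at
annotated sites and a single shared ``background`` elsewhere. Each library is
deterministic for a fixed seed; per-reference substreams are derived from
(seed, CRC32(ref_seg)) so adding a reference leaves others' reads unchanged.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .types import (
    DNA_BASES,
    READ_BASES,
    AlignedRead,
    CigarOp,
    ModificationAnnotation,
    OpKind,
    Orientation,
    ReferenceSet,
    annotation_index,
)

_PROB_TOL = 1e-9

#: internal per-position synthesis states
_NONE = -1
_DEL = -2


class EventClass(enum.Enum):
    ARREST = "arrest"
    JUMP_DIRECT = "jump_direct"
    JUMP_DELAYED = "jump_delayed"
    JUMP_DOUBLE = "jump_double"
    READ_THROUGH = "read_through"


@dataclass(frozen=True)
class ModEventParams:
    """Event probabilities for one site class (a modification, or background).

    ``p_arrest`` + the three jump probabilities must not exceed 1; the
    remainder is read-through with incorporation. Misincorporation is
    parameterized by a total mass ``p_mismatch`` (the probability that the
    incorporated base differs from the reference, N included) split over the
    three non-reference bases plus N:

    * ``n_fraction`` of the mismatch mass goes to N;
    * the rest follows ``substitution_weights`` (uniform thirds by default);
    * with ``prebase_bias`` set, a site whose 3' neighbour (prebase) differs
      from its reference base sends that share of the substitution mass to
      the prebase base — misincorporations tend to mirror the base the
      enzyme has just read, a slippage-like effect.

    ``mismatch_dist(ref_base, prebase)`` materializes the incorporation
    probability vector over A/C/G/T/N; the reference base's own entry is the
    correct-incorporation mass ``1 - p_mismatch`` and the vector sums to 1.
    """

    p_arrest: float = 0.0
    p_jump_direct: float = 0.0
    p_jump_delayed: float = 0.0
    p_jump_double: float = 0.0
    p_mismatch: float = 0.0
    n_fraction: float = 0.0
    prebase_bias: float | None = None
    substitution_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("p_arrest", "p_jump_direct", "p_jump_delayed", "p_jump_double",
                     "p_mismatch", "n_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        total = self.p_arrest + self.p_jump_direct + self.p_jump_delayed + self.p_jump_double
        if total > 1.0 + _PROB_TOL:
            raise ValidationError(f"arrest+jump probabilities sum to {total} > 1")
        if self.prebase_bias is not None and not 0.0 <= self.prebase_bias <= 1.0:
            raise ValidationError(f"prebase_bias={self.prebase_bias} outside [0, 1]")
        if self.substitution_weights is not None:
            if any(w < 0 for w in self.substitution_weights.values()):
                raise ValidationError("negative substitution weight")
            if set(self.substitution_weights) - set(DNA_BASES):
                raise ValidationError("substitution weights keyed by non-ACGT base")

    @property
    def p_jump_total(self) -> float:
        return self.p_jump_direct + self.p_jump_delayed + self.p_jump_double

    @property
    def event_probabilities(self) -> dict[EventClass, float]:
        p_rt = 1.0 - self.p_arrest - self.p_jump_total
        return {
            EventClass.ARREST: self.p_arrest,
            EventClass.JUMP_DIRECT: self.p_jump_direct,
            EventClass.JUMP_DELAYED: self.p_jump_delayed,
            EventClass.JUMP_DOUBLE: self.p_jump_double,
            EventClass.READ_THROUGH: p_rt,
        }

    def mismatch_dist(self, ref_base: str, prebase: str | None = None) -> dict[str, float]:
        """Incorporation distribution over A/C/G/T/N at a site.

        The entry for ``ref_base`` is the correct-incorporation mass; the
        vector sums to 1 (within 1e-9).
        """
        if ref_base not in DNA_BASES:
            raise ValidationError(f"ref_base {ref_base!r} not one of {DNA_BASES}")
        dist = dict.fromkeys(READ_BASES, 0.0)
        dist[ref_base] = 1.0 - self.p_mismatch
        dist["N"] = self.p_mismatch * self.n_fraction
        sub_mass = self.p_mismatch * (1.0 - self.n_fraction)
        others = [b for b in DNA_BASES if b != ref_base]
        if self.prebase_bias is not None and prebase in others:
            rest = [b for b in others if b != prebase]
            dist[prebase] += sub_mass * self.prebase_bias
            for b in rest:
                dist[b] += sub_mass * (1.0 - self.prebase_bias) / len(rest)
        elif self.substitution_weights:
            weights = {b: self.substitution_weights.get(b, 0.0) for b in others}
            total = sum(weights.values())
            if total <= 0:
                for b in others:
                    dist[b] += sub_mass / len(others)
            else:
                for b in others:
                    dist[b] += sub_mass * weights[b] / total
        else:
            for b in others:
                dist[b] += sub_mass / len(others)
        assert abs(sum(dist.values()) - 1.0) < _PROB_TOL
        return dist

    def to_dict(self) -> dict:
        d = {
            "p_arrest": self.p_arrest,
            "p_jump_direct": self.p_jump_direct,
            "p_jump_delayed": self.p_jump_delayed,
            "p_jump_double": self.p_jump_double,
            "p_mismatch": self.p_mismatch,
            "n_fraction": self.n_fraction,
        }
        if self.prebase_bias is not None:
            d["prebase_bias"] = self.prebase_bias
        if self.substitution_weights is not None:
            d["substitution_weights"] = dict(self.substitution_weights)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModEventParams":
        return cls(**{k: v for k, v in data.items()})


@dataclass(frozen=True)
class RTConditionParams:
    """Parameters of one simulated reverse-transcription reaction condition.

    ``background`` applies at every unannotated position and must stay small
    (every probability < 0.1): non-modified sites show only low-level changes
    in real libraries. ``paired_fraction`` of the molecules are additionally
    emitted as a REVERSE-orientation mate covering the 3'-proximal
    ``read_length`` window, mirroring a 2 x 75 bp paired-end run.
    """

    label: str
    per_mod: Mapping[str, ModEventParams] = field(default_factory=dict)
    background: ModEventParams = field(default_factory=ModEventParams)
    n_molecules_per_ref: int = 10_000
    read_length: int = 75
    paired_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_molecules_per_ref < 0:
            raise ValidationError("n_molecules_per_ref must be >= 0")
        if self.read_length < 1:
            raise ValidationError("read_length must be >= 1")
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValidationError("paired_fraction outside [0, 1]")
        bg = self.background
        for name in ("p_arrest", "p_jump_direct", "p_jump_delayed", "p_jump_double",
                     "p_mismatch"):
            v = getattr(bg, name)
            if v >= 0.1:
                raise ValidationError(
                    f"background {name}={v} >= 0.1; background events must stay small"
                )

    def params_at(self, mod: str | None) -> ModEventParams:
        """Event parameters for a site annotated with ``mod`` (None = background)."""
        if mod is not None and mod in self.per_mod:
            return self.per_mod[mod]
        return self.background

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_molecules_per_ref": self.n_molecules_per_ref,
            "read_length": self.read_length,
            "paired_fraction": self.paired_fraction,
            "background": self.background.to_dict(),
            "per_mod": {mod: p.to_dict() for mod, p in self.per_mod.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RTConditionParams":
        return cls(
            label=data["label"],
            per_mod={m: ModEventParams.from_dict(p) for m, p in (data.get("per_mod") or {}).items()},
            background=ModEventParams.from_dict(data.get("background") or {}),
            n_molecules_per_ref=int(data.get("n_molecules_per_ref", 10_000)),
            read_length=int(data.get("read_length", 75)),
            paired_fraction=float(data.get("paired_fraction", 0.0)),
        )


# ---------------------------------------------------------------------------
# Ground truth bookkeeping

_EVENT_ORDER = (EventClass.ARREST, EventClass.JUMP_DIRECT, EventClass.JUMP_DELAYED,
                EventClass.JUMP_DOUBLE, EventClass.READ_THROUGH)


@dataclass
class SiteTruth:
    """Realized event tallies plus generating parameters for one site."""

    ref_seg: str
    pos: int
    mod: str | None
    params: ModEventParams
    n_arrest: int = 0
    n_jump_direct: int = 0
    n_jump_delayed: int = 0
    n_jump_double: int = 0
    n_read_through: int = 0
    n_mismatch: int = 0  # incorporations (read-through or delayed) differing from ref

    @property
    def n_reached(self) -> int:
        """Molecules whose synthesis drew an event at this position."""
        return (self.n_arrest + self.n_jump_direct + self.n_jump_delayed
                + self.n_jump_double + self.n_read_through)


class GroundTruth:
    """Per-(ref_seg, pos) event tallies for a simulated library."""

    def __init__(self) -> None:
        self.sites: dict[tuple[str, int], SiteTruth] = {}

    def register(self, ref_seg: str, pos: int, mod: str | None, params: ModEventParams) -> None:
        self.sites[(ref_seg, pos)] = SiteTruth(ref_seg, pos, mod, params)

    def tally(self, ref_seg: str, pos: int, event: EventClass, mismatched: bool) -> None:
        site = self.sites[(ref_seg, pos)]
        attr = "n_" + event.value
        setattr(site, attr, getattr(site, attr) + 1)
        if mismatched:
            site.n_mismatch += 1

    def __getitem__(self, key: tuple[str, int]) -> SiteTruth:
        return self.sites[key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site in self.sites.values():
            rows.append({
                "ref_seg": site.ref_seg, "pos": site.pos, "mod": site.mod or "",
                "n_reached": site.n_reached, "n_arrest": site.n_arrest,
                "n_jump_direct": site.n_jump_direct, "n_jump_delayed": site.n_jump_delayed,
                "n_jump_double": site.n_jump_double, "n_read_through": site.n_read_through,
                "n_mismatch": site.n_mismatch,
                "p_arrest": site.params.p_arrest,
                "p_jump_direct": site.params.p_jump_direct,
                "p_jump_delayed": site.params.p_jump_delayed,
                "p_jump_double": site.params.p_jump_double,
                "p_mismatch": site.params.p_mismatch,
            })
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Core synthesis walk

@dataclass
class SimulatedMolecule:
    """Outcome of one synthesis attempt.

    ``read`` is None when no aligned base survives (e.g. arrest at the very
    first template position). ``events`` lists (pos, EventClass, base) draws
    in synthesis order, base being the incorporated base or None.
    """

    read: AlignedRead | None
    arrested_at: int | None
    events: list[tuple[int, EventClass, str | None]]


def _compile_tables(
    ref_seq: str, mods: Mapping[int, str], cond: RTConditionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position cumulative event and incorporation probabilities."""
    L = len(ref_seq)
    ev_cum = np.empty((L, 4))
    inc_cum = np.empty((L, 5))
    for pos in range(1, L + 1):
        p = cond.params_at(mods.get(pos))
        ref_base = ref_seq[pos - 1]
        prebase = ref_seq[pos] if pos < L else None
        ev_cum[pos - 1] = np.cumsum([p.p_arrest, p.p_jump_direct, p.p_jump_delayed,
                                     p.p_jump_double])
        dist = p.mismatch_dist(ref_base, prebase)
        inc_cum[pos - 1] = np.cumsum([dist[b] for b in READ_BASES])
    return ev_cum, inc_cum


def _walk(
    L: int, ev_cum: np.ndarray, inc_cum: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, EventClass, str | None]], int | None]:
    """Simulate one molecule; returns (state, events, arrested_at).

    ``state[pos]`` for pos 1..L is an index into READ_BASES (incorporated
    base), _DEL (skipped) or _NONE (not reached / 3' of an arrest site).
    """
    u_ev = rng.random(L)
    u_base = rng.random(L)
    state = np.full(L + 1, _NONE, dtype=np.int8)
    events: list[tuple[int, EventClass, str | None]] = []
    arrested_at: int | None = None
    pos = L
    while pos >= 1:
        i = pos - 1
        c = ev_cum[i]
        u = u_ev[i]
        if u < c[0]:
            events.append((pos, EventClass.ARREST, None))
            arrested_at = pos
            break
        if u < c[1]:
            state[pos] = _DEL
            events.append((pos, EventClass.JUMP_DIRECT, None))
            pos -= 1
        elif u < c[2]:
            b = int(np.searchsorted(inc_cum[i], u_base[i], side="right"))
            state[pos] = b
            if pos == 1:  # no 5' neighbour to skip: degrades to read-through
                events.append((pos, EventClass.READ_THROUGH, READ_BASES[b]))
                pos -= 1
            else:
                state[pos - 1] = _DEL
                events.append((pos, EventClass.JUMP_DELAYED, READ_BASES[b]))
                pos -= 2
        elif u < c[3]:
            state[pos] = _DEL
            if pos == 1:  # no 5' neighbour: degrades to a direct jump
                events.append((pos, EventClass.JUMP_DIRECT, None))
                pos -= 1
            else:
                state[pos - 1] = _DEL
                events.append((pos, EventClass.JUMP_DOUBLE, None))
                pos -= 2
        else:
            b = int(np.searchsorted(inc_cum[i], u_base[i], side="right"))
            state[pos] = b
            events.append((pos, EventClass.READ_THROUGH, READ_BASES[b]))
            pos -= 1
    return state, events, arrested_at


def _read_from_state(
    state: np.ndarray,
    ref_seg: str,
    read_id: str,
    arrested_at: int | None,
    read_length: int,
    orientation: Orientation,
    keep_3prime: bool = False,
) -> AlignedRead | None:
    """Build an AlignedRead from the synthesis state array.

    Truncation to ``read_length`` aligned bases keeps the 5'-most end for
    FORWARD reads (``keep_3prime=False``) — where the RT signature
    concentrates — and the 3'-proximal window for REVERSE mates.
    """
    L = len(state) - 1
    s = (arrested_at + 1) if arrested_at is not None else 1
    e = L
    while s <= e and state[s] == _DEL:
        s += 1
    while e >= s and state[e] == _DEL:
        e -= 1
    if s > e:
        return None
    aligned = [p for p in range(s, e + 1) if state[p] >= 0]
    if len(aligned) > read_length:
        if keep_3prime:
            s = aligned[len(aligned) - read_length]
        else:
            e = aligned[read_length - 1]
    ops: list[CigarOp] = []
    query: list[str] = []
    run_kind: OpKind | None = None
    run_len = 0
    for p in range(s, e + 1):
        kind = OpKind.DELETION if state[p] == _DEL else OpKind.ALIGNED
        if state[p] >= 0:
            query.append(READ_BASES[state[p]])
        if kind is run_kind:
            run_len += 1
        else:
            if run_kind is not None:
                ops.append(CigarOp(run_kind, run_len))
            run_kind, run_len = kind, 1
    ops.append(CigarOp(run_kind, run_len))  # type: ignore[arg-type]
    return AlignedRead(
        read_id=read_id, ref_seg=ref_seg, start=s, ops=tuple(ops),
        query="".join(query), orientation=orientation,
    )


def simulate_molecule(
    ref_seq: str,
    mods: Mapping[int, str],
    cond: RTConditionParams,
    rng: np.random.Generator,
) -> SimulatedMolecule:
    """Simulate reverse transcription of a single template molecule.

    ``mods`` maps 1-based positions to modification codes. The returned
    read's footprint is reported in reference coordinates; an arrested
    molecule yields the abortive fragment covering positions strictly 3' of
    the blocking site (or ``read=None`` if nothing was synthesized).
    """
    for pos in mods:
        if not 1 <= pos <= len(ref_seq):
            raise ValidationError(f"modification position {pos} outside template of length {len(ref_seq)}")
    ev_cum, inc_cum = _compile_tables(ref_seq, mods, cond)
    state, events, arrested_at = _walk(len(ref_seq), ev_cum, inc_cum, rng)
    read = _read_from_state(state, "ref", "mol", arrested_at, cond.read_length,
                            Orientation.FORWARD)
    return SimulatedMolecule(read=read, arrested_at=arrested_at, events=events)


def substream(seed: int, ref_seg: str) -> np.random.Generator:
    """Deterministic per-reference RNG substream for a global seed."""
    return np.random.default_rng([seed, zlib.crc32(ref_seg.encode())])


def simulate_library(
    refs: ReferenceSet,
    annotations: list[ModificationAnnotation],
    cond: RTConditionParams,
    seed: int,
) -> tuple[list[AlignedRead], GroundTruth]:
    """Simulate a whole library: ``n_molecules_per_ref`` molecules per reference.

    Returns the reads (FORWARD molecules plus, for ``paired_fraction`` of
    them, a REVERSE mate over the 3'-proximal window) and a ``GroundTruth``
    tallying every event draw. Deterministic for a fixed seed.
    """
    ann_idx = annotation_index(annotations, refs)
    reads: list[AlignedRead] = []
    truth = GroundTruth()
    for ref_seg in refs:
        seq = refs[ref_seg]
        L = len(seq)
        mods = {pos: mod for (r, pos), mod in ann_idx.items() if r == ref_seg}
        for pos in range(1, L + 1):
            truth.register(ref_seg, pos, mods.get(pos), cond.params_at(mods.get(pos)))
        rng = substream(seed, ref_seg)
        ev_cum, inc_cum = _compile_tables(seq, mods, cond)
        tag = f"{zlib.crc32(ref_seg.encode()):08x}"
        for i in range(cond.n_molecules_per_ref):
            state, events, arrested_at = _walk(L, ev_cum, inc_cum, rng)
            for pos, event, base in events:
                mismatched = base is not None and base != seq[pos - 1]
                truth.tally(ref_seg, pos, event, mismatched)
            read_id = f"{tag}:{i}"
            read = _read_from_state(state, ref_seg, read_id, arrested_at,
                                    cond.read_length, Orientation.FORWARD)
            if read is not None:
                reads.append(read)
            if rng.random() < cond.paired_fraction:
                mate = _read_from_state(state, ref_seg, read_id, arrested_at,
                                        cond.read_length, Orientation.REVERSE,
                                        keep_3prime=True)
                if mate is not None:
                    reads.append(mate)
    return reads, truth


# ---------------------------------------------------------------------------
# Built-in condition presets

def builtin_presets() -> dict[str, RTConditionParams]:
    """Built-in reaction-condition presets (EpiScript; Mg reference plus four
    MnCl2 concentrations).

    Headline parameters quote measured averages for m1A under EpiScript
    (arrest 82% -> 24%, misincorporation mass 54% -> 80% between the Mg 3 mM
    reference and Mn 3 mM); everything else is documented in the preset file
    ``data/presets.yaml``.
    """
    text = resources.files("rtsig.data").joinpath("presets.yaml").read_text()
    data = yaml.safe_load(text)
    return {name: RTConditionParams.from_dict(d) for name, d in data["presets"].items()}
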