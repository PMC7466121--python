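"""Deterministic synthetic fixtures binding the whole pipeline together.

All reference sequences here are *generated*, never copied from tRNA
databases; identifiers imitate the pipe-delimited style of real tRNA ids but
are flagged synthetic. The bundle gives tests and examples a small,
self-contained world: references, annotations, two reaction conditions and
the analytically expected zero-noise profile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import io_formats
from .simulate import ModEventParams, RTConditionParams, builtin_presets, simulate_library
from .types import ModificationAnnotation, PositionProfile, ReferenceSet

#: Target template base for each supported modification code.
MOD_TARGET_BASE = {"m1A": "A", "m22G": "G", "m1G": "G", "m3C": "C"}

_ISOTYPES = [
    ("Ala", "AGC"), ("Arg", "ACG"), ("Asn", "GTT"), ("Cys", "GCA"),
    ("Ile", "AAT"), ("Leu", "TAA"), ("Lys", "CTT"), ("Phe", "GAA"),
    ("Gly", "GCC"), ("Ser", "AGA"), ("Val", "AAC"), ("Trp", "CCA"),
]


def _synthetic_id(i: int, seed: int) -> str:
    aa, anticodon = _ISOTYPES[i % len(_ISOTYPES)]
    return f"synth{seed:04d}{i:03d}|Synthetic_tRNAlike|0000|{aa}|{anticodon}"


def make_references(
    n_refs: int, seed: int = 0, lengths: list[int] | None = None
) -> ReferenceSet:
    """Generate ``n_refs`` random tRNA-length templates (default 60-90 nt)."""
    rng = np.random.default_rng([seed, 0xF1D0])
    entries: dict[str, str] = {}
    for i in range(n_refs):
        length = lengths[i] if lengths else int(rng.integers(60, 91))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        entries[_synthetic_id(i, seed)] = seq
    return ReferenceSet(entries)


def place_sites(
    refs: ReferenceSet, site_specs: dict[str, list[tuple[int, str]]]
) -> tuple[ReferenceSet, list[ModificationAnnotation]]:
    """Force modified sites into the templates.

    ``site_specs`` maps ref id to a list of (1-based position, mod code);
    the template base at each site is overwritten with the modification's
    target base. Returns the edited references and matching annotations.
    """
    entries = dict(refs.entries)
    annotations: list[ModificationAnnotation] = []
    for ref_seg, sites in site_specs.items():
        seq = list(entries[ref_seg])
        for pos, mod in sites:
            seq[pos - 1] = MOD_TARGET_BASE[mod]
            annotations.append(ModificationAnnotation(ref_seg, pos, mod))
        entries[ref_seg] = "".join(seq)
    return ReferenceSet(entries), annotations


def make_panel(
    n_refs: int = 3,
    seed: int = 0,
    length: int = 76,
    sites: tuple[tuple[int, str], ...] = ((58, "m1A"),),
) -> tuple[ReferenceSet, list[ModificationAnnotation]]:
    """References of equal length, each bearing the same modified-site layout.

    Handy for parameter-recovery and calibration runs where several matched
    modified positions are needed.
    """
    refs = make_references(n_refs, seed=seed, lengths=[length] * n_refs)
    specs = {ref_seg: list(sites) for ref_seg in refs}
    return place_sites(refs, specs)


def zero_noise_condition(n_molecules: int = 40, read_length: int = 120) -> RTConditionParams:
    """A condition with no RT events at all: every molecule is a perfect
    full-length copy. The resulting profile is known analytically."""
    zero = ModEventParams()
    return RTConditionParams(
        label="zero_noise",
        per_mod={mod: zero for mod in MOD_TARGET_BASE},
        background=zero,
        n_molecules_per_ref=n_molecules,
        read_length=read_length,
        paired_fraction=0.0,
    )


@dataclass
class FixtureBundle:
    """Small self-consistent inputs for end-to-end runs."""

    refs: ReferenceSet
    annotations: list[ModificationAnnotation]
    conditions: dict[str, RTConditionParams]
    zero_noise: RTConditionParams
    expected_zero_noise: list[PositionProfile]

    def write(self, directory: str | Path, seed: int = 0) -> dict[str, Path]:
        """Emit the full file set (FASTA, annotation TSV, condition YAMLs,
        one simulated SAM + truth TSV per condition) into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["refs"] = directory / "references.fasta"
        io_formats.write_fasta(self.refs, paths["refs"])
        paths["annotation"] = directory / "annotation.tsv"
        io_formats.write_annotation(self.annotations, paths["annotation"])
        for name, cond in self.conditions.items():
            cond_path = directory / f"condition_{name}.yaml"
            io_formats.dump_condition(cond, cond_path)
            paths[f"condition_{name}"] = cond_path
            reads, truth = simulate_library(self.refs, self.annotations, cond, seed)
            sam_path = directory / f"{name}.sam"
            io_formats.write_alignments(reads, self.refs, sam_path)
            paths[f"alignments_{name}"] = sam_path
            truth_path = directory / f"{name}.truth.tsv"
            truth.write(truth_path)
            paths[f"truth_{name}"] = truth_path
        return paths


def make_fixture(seed: int = 0) -> FixtureBundle:
    """Three toy templates (76/64/88 nt) carrying one m1A, one m22G and one
    m3C site, two reaction conditions (Mg reference / Mn 3 mM treated, scaled
    to 2,000 molecules per reference), and the expected zero-noise profile."""
    refs = make_references(3, seed=seed, lengths=[76, 64, 88])
    ids = list(refs)
    refs, annotations = place_sites(refs, {
        ids[0]: [(58, "m1A")],
        ids[1]: [(26, "m22G")],
        ids[2]: [(32, "m3C")],
    })
    presets = builtin_presets()
    conditions = {
        "reference": replace(presets["EpiScript_Mg_3mM"],
                             n_molecules_per_ref=2000, read_length=120, paired_fraction=0.8),
        "treated": replace(presets["EpiScript_Mn_3mM"],
                           n_molecules_per_ref=2000, read_length=120, paired_fraction=0.8),
    }
    zero = zero_noise_condition()
    ann_idx = {(a.ref_seg, a.pos): a.mod for a in annotations}
    expected: list[PositionProfile] = []
    n = zero.n_molecules_per_ref
    for ref_seg in sorted(refs):
        seq = refs[ref_seg]
        for pos in range(1, len(seq) + 1):
            base = seq[pos - 1]
            counters = dict.fromkeys(["A", "G", "T", "C", "N", "a", "g", "t", "c", "n"], 0)
            counters[base] = n
            expected.append(PositionProfile(
                ref_seg=ref_seg, mod=ann_idx.get((ref_seg, pos), ""), pos=pos,
                ref_base=base, cov=n,
                pre_base=seq[pos] if pos < len(seq) else "",
                mism_rate=0.0, **counters,
                single_jump_rate_direct=0.0, single_jump_rate_delayed=0.0,
                double_jump_rate=0.0, arrest_rate=0.0,
            ))
    return FixtureBundle(
        refs=refs, annotations=annotations, conditions=conditions,
        zero_noise=zero, expected_zero_noise=expected,
    )
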