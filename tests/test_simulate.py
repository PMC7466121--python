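import dataclasses

import numpy as np
import pytest

from rtsig import (
    EventClass,
    ModEventParams,
    ModificationAnnotation,
    OpKind,
    Orientation,
    RTConditionParams,
    ReferenceSet,
    ValidationError,
    builtin_presets,
    dump_condition,
    load_condition,
    simulate_library,
    simulate_molecule,
    zero_noise_condition,
)

REF = ReferenceSet({"syn|A": "ACGTACGTACGTACGTACGTACGTACGTAGTT"})  # 32 nt
SEQ = REF["syn|A"]
L = len(SEQ)


def cond_with(params: ModEventParams, **kwargs) -> RTConditionParams:
    defaults = dict(label="test", per_mod={"m1A": params}, background=ModEventParams(),
                    n_molecules_per_ref=50, read_length=100, paired_fraction=0.0)
    defaults.update(kwargs)
    return RTConditionParams(**defaults)


class TestSimulateMolecule:
    def test_no_event_limit_gives_perfect_full_length_read(self):
        cond = cond_with(ModEventParams())
        mol = simulate_molecule(SEQ, {10: "m1A"}, cond, np.random.default_rng(0))
        read = mol.read
        assert read is not None
        assert [(op.kind, op.length) for op in read.ops] == [(OpKind.ALIGNED, L)]
        assert read.start == 1 and read.query == SEQ
        assert mol.arrested_at is None

    def test_certain_arrest_leaves_site_uncovered(self):
        # arrest terminates before incorporation opposite the site: the
        # abortive fragment covers positions strictly 3' of it
        cond = cond_with(ModEventParams(p_arrest=1.0))
        for seed in range(5):
            mol = simulate_molecule(SEQ, {10: "m1A"}, cond, np.random.default_rng(seed))
            assert mol.arrested_at == 10
            assert mol.read.start == 11 and mol.read.end == L

    def test_certain_double_jump_deletes_site_and_5prime_neighbour(self):
        cond = cond_with(ModEventParams(p_jump_double=1.0))
        mol = simulate_molecule(SEQ, {10: "m1A"}, cond, np.random.default_rng(1))
        read = mol.read
        assert sorted(read.deleted_positions()) == [9, 10]
        kinds = [(op.kind, op.length) for op in read.ops]
        assert (OpKind.DELETION, 2) in kinds
        assert read.start == 1 and read.end == L

    def test_certain_direct_jump_single_deletion_at_site(self):
        cond = cond_with(ModEventParams(p_jump_direct=1.0))
        mol = simulate_molecule(SEQ, {10: "m1A"}, cond, np.random.default_rng(1))
        assert sorted(mol.read.deleted_positions()) == [10]

    def test_delayed_jump_incorporates_at_site_deletes_neighbour(self):
        cond = cond_with(ModEventParams(p_jump_delayed=1.0))
        mol = simulate_molecule(SEQ, {10: "m1A"}, cond, np.random.default_rng(1))
        read = mol.read
        assert sorted(read.deleted_positions()) == [9]
        aligned = dict(read.aligned_pairs())
        assert 10 in aligned  # normal incorporation at the site itself

    def test_mods_outside_template_rejected(self):
        cond = cond_with(ModEventParams())
        with pytest.raises(ValidationError):
            simulate_molecule(SEQ, {L + 5: "m1A"}, cond, np.random.default_rng(0))

    def test_truncation_keeps_5prime_end(self):
        cond = cond_with(ModEventParams(), read_length=10)
        mol = simulate_molecule(SEQ, {}, cond, np.random.default_rng(0))
        assert mol.read.start == 1 and mol.read.end == 10
        assert len(mol.read.query) == 10


class TestSimulateLibrary:
    def test_deterministic_for_fixed_seed(self):
        cond = cond_with(ModEventParams(p_arrest=0.3, p_mismatch=0.2, p_jump_direct=0.05))
        ann = [ModificationAnnotation("syn|A", 10, "m1A")]
        reads1, truth1 = simulate_library(REF, ann, cond, seed=7)
        reads2, truth2 = simulate_library(REF, ann, cond, seed=7)
        assert reads1 == reads2
        assert truth1.to_frame().equals(truth2.to_frame())
        reads3, _ = simulate_library(REF, ann, cond, seed=8)
        assert reads1 != reads3

    def test_zero_molecules_empty_output(self):
        cond = cond_with(ModEventParams(), n_molecules_per_ref=0)
        reads, truth = simulate_library(REF, [], cond, seed=0)
        assert reads == []
        assert all(site.n_reached == 0 for site in truth.sites.values())

    def test_event_class_conservation(self):
        # at every site: arrest + jumps + read-through draws equal the number
        # of molecules whose synthesis reached it
        params = ModEventParams(p_arrest=0.2, p_jump_direct=0.05, p_jump_delayed=0.1,
                                p_jump_double=0.05, p_mismatch=0.3)
        cond = cond_with(params, n_molecules_per_ref=200)
        ann = [ModificationAnnotation("syn|A", 10, "m1A")]
        _, truth = simulate_library(REF, ann, cond, seed=3)
        assert truth[("syn|A", L)].n_reached == 200  # synthesis starts at the 3' end
        site = truth[("syn|A", 10)]
        assert site.n_reached == (site.n_arrest + site.n_jump_direct + site.n_jump_delayed
                                  + site.n_jump_double + site.n_read_through)
        # positions skipped by delayed/double jumps at 10 draw no event at 9
        reached_9 = truth[("syn|A", 9)].n_reached
        assert reached_9 == site.n_read_through + site.n_jump_direct

    def test_monotone_coverage_under_arrests(self):
        # arrests only remove molecules, so realized per-position synthesis
        # counts never increase toward the 5' end
        params = ModEventParams(p_arrest=0.3)
        cond = cond_with(params, n_molecules_per_ref=300,
                         background=ModEventParams(p_arrest=0.01))
        ann = [ModificationAnnotation("syn|A", 10, "m1A")]
        _, truth = simulate_library(REF, ann, cond, seed=5)
        reached = [truth[("syn|A", pos)].n_reached for pos in range(1, L + 1)]
        assert all(reached[i] >= reached[i - 1] for i in range(1, L))  # 5' -> 3'

    def test_paired_fraction_one_emits_reverse_mates(self):
        cond = cond_with(ModEventParams(), paired_fraction=1.0, read_length=10,
                         n_molecules_per_ref=20)
        reads, _ = simulate_library(REF, [], cond, seed=0)
        fwd = [r for r in reads if r.orientation is Orientation.FORWARD]
        rev = [r for r in reads if r.orientation is Orientation.REVERSE]
        assert len(fwd) == len(rev) == 20
        # mates cover the 3'-proximal window, forward reads the 5'-most one
        assert {(r.start, r.end) for r in fwd} == {(1, 10)}
        assert {(r.start, r.end) for r in rev} == {(L - 9, L)}
        assert {r.read_id for r in fwd} == {r.read_id for r in rev}

    def test_added_reference_leaves_other_substreams_unchanged(self):
        cond = cond_with(ModEventParams(p_arrest=0.3, p_mismatch=0.4))
        ann = [ModificationAnnotation("syn|A", 10, "m1A")]
        reads1, _ = simulate_library(REF, ann, cond, seed=11)
        bigger = ReferenceSet({**REF.entries, "syn|B": "ACGT" * 10})
        reads2, _ = simulate_library(bigger, ann, cond, seed=11)
        assert [r for r in reads2 if r.ref_seg == "syn|A"] == reads1


class TestParams:
    def test_mismatch_dist_sums_to_one_with_correct_mass(self):
        p = ModEventParams(p_mismatch=0.54, n_fraction=0.02)
        dist = p.mismatch_dist("A")
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
        assert dist["A"] == pytest.approx(0.46)
        assert dist["N"] == pytest.approx(0.54 * 0.02)

    def test_prebase_bias_routes_substitution_mass(self):
        p = ModEventParams(p_mismatch=0.6, prebase_bias=0.65)
        dist = p.mismatch_dist("A", prebase="G")
        sub = 0.6
        assert dist["G"] == pytest.approx(sub * 0.65)
        assert dist["C"] == pytest.approx(sub * 0.35 / 2)
        # prebase equal to the reference base: falls back to a uniform split
        uniform = p.mismatch_dist("A", prebase="A")
        assert uniform["C"] == uniform["G"] == uniform["T"] == pytest.approx(sub / 3)

    def test_event_probabilities_must_fit_in_unit_mass(self):
        with pytest.raises(ValidationError):
            ModEventParams(p_arrest=0.9, p_jump_direct=0.2)

    def test_background_must_stay_small(self):
        with pytest.raises(ValidationError, match="background"):
            RTConditionParams(label="x", background=ModEventParams(p_arrest=0.5))

    def test_condition_yaml_roundtrip(self, tmp_path):
        cond = builtin_presets()["EpiScript_Mn_3mM"]
        path = tmp_path / "cond.yaml"
        dump_condition(cond, path)
        assert load_condition(path) == cond


class TestPresets:
    def test_reference_and_treated_quote_measured_m1a_averages(self):
        presets = builtin_presets()
        assert presets["EpiScript_Mg_3mM"].per_mod["m1A"].p_arrest == 0.82
        assert presets["EpiScript_Mn_3mM"].per_mod["m1A"].p_arrest == 0.24
        assert presets["EpiScript_Mg_3mM"].per_mod["m1A"].p_mismatch == 0.54
        assert presets["EpiScript_Mn_3mM"].per_mod["m1A"].p_mismatch == 0.80

    def test_all_presets_validate_and_cover_buffer_series(self):
        presets = builtin_presets()
        assert len(presets) == 5  # Mg reference + 0.5/1/3/5 mM MnCl2
        for cond in presets.values():
            assert cond.read_length == 75
            for mod in ("m1A", "m22G", "m1G", "m3C"):
                assert mod in cond.per_mod

    def test_zero_noise_condition_validates(self):
        cond = zero_noise_condition()
        assert cond.background.p_arrest == 0.0
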