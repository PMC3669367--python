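"""Packer: design-task rules, annealing vs exhaustive oracle, determinism,
resfile round trips."""

import numpy as np
import pytest

from supercharge import (
    DesignTask,
    Packer,
    RotamerSet,
    SearchSpaceError,
    ValidationError,
    build_design_task,
    classify_surface,
    exhaustive_pack,
    pack,
    read_resfile,
    score_structure,
    write_resfile,
)
from supercharge.fixtures import FixtureSpec, make_hbond_motif, make_structure


def all_surface(structure):
    return classify_surface(structure, "atom_based", 1e9)


def restricted_task(task, sites):
    """Keep only the given designable sites; fix the rest."""
    return DesignTask(
        designable={s: task.designable[s] for s in sites},
        fixed={
            **task.fixed,
            **{s: "resfile_excluded" for s in task.designable if s not in sites},
        },
    )


class TestRotamerSet:
    def test_default_library_is_valid(self):
        rotamers = RotamerSet()
        for aa, entries in rotamers.library.items():
            assert entries
            assert sum(p for _, p in entries) == pytest.approx(1.0, abs=1e-9)

    def test_bad_probabilities_rejected(self):
        from supercharge.chemdata import ROTAMER_LIBRARY

        broken = dict(ROTAMER_LIBRARY)
        broken["K"] = [((180.0, 180.0, 180.0, 180.0), 0.7)]
        with pytest.raises(ValidationError):
            RotamerSet(library=broken)


class TestBuildDesignTask:
    def test_every_residue_appears_exactly_once(self, helix16, model):
        task = build_design_task(
            helix16, all_surface(helix16), "positive", model, include_types={"K"}
        )
        covered = set(task.designable) | set(task.fixed)
        assert covered == set(helix16.sites())

    def test_glycine_proline_cysteine_preserved(self, model):
        structure = make_structure(FixtureSpec("AGPCA", "extended"))
        task = build_design_task(
            structure, all_surface(structure) | {("A", 2, "")}, "positive", model,
            include_types={"K"},
        )
        for number in (2, 3, 4):
            assert task.fixed[("A", number, "")] == "glyprocys"

    def test_correct_charge_preserved_per_polarity(self, helix16, model):
        surface = all_surface(helix16)
        positive = build_design_task(helix16, surface, "positive", model, {"K"})
        negative = build_design_task(helix16, surface, "negative", model, {"E"})
        for res in helix16.residues:
            if res.aa in "RK":
                assert positive.fixed[res.site] == "correct_charge"
            if res.aa in "DE":
                assert negative.fixed[res.site] == "correct_charge"

    def test_hbonded_sidechain_preserved_and_rule_defeatable(self, loop_motif, model):
        surface = all_surface(loop_motif)
        task = build_design_task(loop_motif, surface, "positive", model, {"K"})
        assert task.fixed[("A", 3, "")] == "hbonded_sidechain"
        relaxed = build_design_task(
            loop_motif, surface, "positive", model, {"K"},
            preserve_hbonded_sidechains=False,
        )
        assert ("A", 3, "") in relaxed.designable
        assert set(task.designable) <= set(relaxed.designable)

    def test_non_surface_reason_and_allowed_types(self, helix16, model):
        surface = {("A", 7, "")}  # leucine
        task = build_design_task(
            helix16, surface, "positive", model, include_types={"K", "R"}
        )
        assert set(task.designable[("A", 7, "")]) == {"L", "K", "R"}
        for res in helix16.residues:
            if res.site != ("A", 7, ""):
                assert task.fixed[res.site] == "not_surface"

    def test_resfile_natro_and_pikaa(self, helix16, model, tmp_path):
        surface = all_surface(helix16)
        resfile = {("A", 7): ("NATRO", None), ("A", 8): ("PIKAA", frozenset("K"))}
        task = build_design_task(
            helix16, surface, "positive", model, {"K", "R"}, resfile=resfile
        )
        assert task.fixed[("A", 7, "")] == "resfile_excluded"
        assert set(task.designable[("A", 8, "")]) == {"S", "K"}  # native + PIKAA cap

    def test_resfile_unknown_site_rejected(self, helix16, model):
        with pytest.raises(ValidationError):
            build_design_task(
                helix16, all_surface(helix16), "positive", model, {"K"},
                resfile={("A", 99): ("NATRO", None)},
            )


class TestPacking:
    def test_zero_designable_sites_is_noop(self, helix8, model):
        task = DesignTask(
            designable={}, fixed={r.site: "not_surface" for r in helix8.residues}
        )
        packed, energy = pack(helix8, task, model, seed=0)
        assert packed.sequence() == helix8.sequence()
        assert energy == pytest.approx(score_structure(helix8, model).total)

    def test_clashing_rotamer_rejected(self, bundle, model):
        """One buried site, native vs bulky type: packing keeps whichever
        scores better, which for the most buried site is not a clash."""
        from supercharge import annotate_surface

        ann = annotate_surface(bundle)
        buried = max(
            (r.site for r in bundle.residues if r.sidechain_atoms),
            key=lambda s: ann.avnapsa[s],
        )
        task = DesignTask(
            designable={buried: (bundle.get(buried).aa, "W")},
            fixed={r.site: "not_surface" for r in bundle.residues if r.site != buried},
        )
        packer = Packer(bundle, task, model)
        packed, energy, assignment = packer.pack(seed=0)
        _, best_energy, best_assignment = packer.exhaustive()
        assert energy == pytest.approx(best_energy)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_instances_reach_exhaustive_optimum(self, helix8, model, seed):
        task = build_design_task(
            helix8, all_surface(helix8), "positive", model, {"K"}
        )
        sites = list(task.designable)[:3]
        small = restricted_task(task, sites)
        packer = Packer(helix8, small, model)
        _, packed_energy, _ = packer.pack(seed=seed)
        _, optimal_energy, _ = packer.exhaustive()
        assert packed_energy >= optimal_energy - 1e-9
        assert packed_energy == pytest.approx(optimal_energy)

    def test_pack_energy_equals_full_rescoring(self, helix8, model):
        task = build_design_task(
            helix8, all_surface(helix8), "positive", model, {"K"}
        )
        packed, energy = pack(helix8, task, model, seed=11)
        assert energy == pytest.approx(score_structure(packed, model).total)

    def test_seed_determinism_and_variation(self, helix8, model):
        task = build_design_task(
            helix8, all_surface(helix8), "positive", model, {"K"}
        )
        packer = Packer(helix8, task, model)
        a = packer.pack(seed=42)
        b = packer.pack(seed=42)
        assert a[2] == b[2]
        assert (a[0].all_atom_positions() == b[0].all_atom_positions()).all()

    def test_never_worse_than_native_assignment(self, helix8, model):
        task = build_design_task(
            helix8, all_surface(helix8), "positive", model, {"K"}
        )
        native_energy = score_structure(helix8, model).total
        for seed in range(4):
            _, energy = pack(helix8, task, model, seed=seed)
            assert energy <= native_energy + 1e-9

    def test_fixed_sites_never_change(self, helix8, model):
        task = build_design_task(
            helix8, all_surface(helix8), "positive", model, {"K"}
        )
        for seed in (0, 1):
            packed, _ = pack(helix8, task, model, seed=seed)
            for site, _reason in task.fixed.items():
                before, after = helix8.get(site), packed.get(site)
                assert before.aa == after.aa
                assert np.array_equal(
                    np.array([a.position for a in before.atoms]),
                    np.array([a.position for a in after.atoms]),
                )

    def test_exhaustive_refuses_large_search_space(self, helix16, model):
        task = build_design_task(
            helix16, all_surface(helix16), "positive", model, {"K", "R"}
        )
        packer = Packer(helix16, task, model)
        with pytest.raises(SearchSpaceError):
            packer.exhaustive(max_states=10)

    def test_exhaustive_single_site_is_min_over_choices(self, helix8, model):
        task = build_design_task(
            helix8, all_surface(helix8), "positive", model, {"K"}
        )
        single = restricted_task(task, list(task.designable)[:1])
        packer = Packer(helix8, single, model)
        _, optimum, _ = packer.exhaustive()
        energies = [
            packer.total_energy([c]) for c in range(len(packer.choices[0]))
        ]
        assert optimum == pytest.approx(min(energies))


class TestResfile:
    def test_round_trip_reproduces_designable_set(self, helix16, model, tmp_path):
        surface = all_surface(helix16)
        task = build_design_task(helix16, surface, "positive", model, {"K"})
        path = tmp_path / "design.resfile"
        write_resfile(task, path)
        entries = read_resfile(path)
        again = build_design_task(
            helix16, surface, "positive", model, {"K"}, resfile=entries
        )
        assert set(again.designable) == set(task.designable)
        for site in task.designable:
            assert set(again.designable[site]) == set(task.designable[site])

    def test_malformed_resfiles_rejected(self, tmp_path):
        bad_header = tmp_path / "a.resfile"
        bad_header.write_text("7 A NATRO\n")
        with pytest.raises(ValidationError):
            read_resfile(bad_header)
        bad_command = tmp_path / "b.resfile"
        bad_command.write_text("start\n7 A FREEZE\n")
        with pytest.raises(ValidationError):
            read_resfile(bad_command)
        bad_letters = tmp_path / "c.resfile"
        bad_letters.write_text("start\n7 A PIKAA KXZ\n")
        with pytest.raises(ValidationError):
            read_resfile(bad_letters)
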