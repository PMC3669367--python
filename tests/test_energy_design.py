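"""Energy-guided protocol: refweight control of net charge, ramping to a
target, preservation behavior."""

import numpy as np
import pytest

from supercharge import (
    DesignOptions,
    UnreachableChargeError,
    UsageError,
    net_formal_charge,
    supercharge_to_target,
    supercharge_with_refweights,
)
from supercharge.fixtures import FixtureSpec, make_structure


class TestOptions:
    def test_polarity_inference(self):
        assert DesignOptions(include_lys=True).polarity() == "positive"
        assert DesignOptions(include_arg=True, include_lys=True).polarity() == "positive"
        assert DesignOptions(include_glu=True).polarity() == "negative"

    def test_no_included_types_is_error(self):
        with pytest.raises(UsageError):
            DesignOptions().polarity()

    def test_mixed_signs_is_error(self):
        with pytest.raises(UsageError):
            DesignOptions(include_lys=True, include_glu=True).polarity()


class TestRefweights:
    def test_strong_penalty_gives_zero_charged_mutations(self, helix16, lys_options):
        result = supercharge_with_refweights(
            helix16, refweights={"K": 10.0}, options=lys_options, seed=0
        )
        assert all(m.new_aa != "K" for m in result.mutations)
        assert result.net_charge_after <= result.net_charge_before

    def test_strong_bonus_charges_every_designable_site(self, helix8, lys_options):
        result = supercharge_with_refweights(
            helix8, refweights={"K": -5.0}, options=lys_options, seed=0
        )
        # every designable site should now carry lysine
        designable = set(result.surface_sites) - {
            r.site for r in helix8.residues if r.aa in "RK"  # correct charge, fixed
        }
        for site in designable:
            assert result.structure.get(site).aa == "K"

    def test_refweights_for_non_included_types_rejected(self, helix16, lys_options):
        with pytest.raises(UsageError):
            supercharge_with_refweights(
                helix16, refweights={"R": -1.0}, options=lys_options
            )

    def test_explicit_polarity_must_match_included_types(self, helix16, lys_options):
        with pytest.raises(UsageError):
            supercharge_with_refweights(
                helix16, polarity="negative", refweights={}, options=lys_options
            )

    def test_more_negative_refweights_do_not_reduce_charge(self, helix16, lys_options):
        """Statistical trend over seeds: lowering the reference energy never
        lowers the mean achieved charge."""
        charges = {}
        for weight in (2.0, -0.65, -3.0):
            achieved = [
                supercharge_with_refweights(
                    helix16, refweights={"K": weight}, options=lys_options, seed=s
                ).net_charge_after
                for s in range(3)
            ]
            charges[weight] = np.mean(achieved)
        assert charges[2.0] <= charges[-0.65] <= charges[-3.0]

    def test_result_bookkeeping(self, helix16, lys_options):
        result = supercharge_with_refweights(
            helix16, refweights={}, options=lys_options, seed=1
        )
        assert result.net_charge_after == net_formal_charge(result.structure)
        diff = [
            (r1.site, r2.aa)
            for r1, r2 in zip(helix16.residues, result.structure.residues)
            if r1.aa != r2.aa
        ]
        assert {(m.site, m.new_aa) for m in result.mutations} == set(diff)
        assert result.final_reference_energies == {"K": -0.65}

    def test_empty_design_warns_not_errors(self, lys_options):
        """All surface sites preserved: a 0-mutation result with a warning."""
        structure = make_structure(FixtureSpec("GKGKG", "extended"))
        result = supercharge_with_refweights(
            structure, refweights={}, options=lys_options, seed=0
        )
        assert result.mutations == []
        assert result.warnings

    def test_mutations_only_at_designable_surface_sites(self, bundle, lys_options):
        result = supercharge_with_refweights(
            bundle, refweights={"K": -2.0}, options=lys_options, seed=2
        )
        assert result.mutations  # something was designed
        surface = set(result.surface_sites)
        for m in result.mutations:
            assert m.site in surface
            assert m.site[0] == "A"  # design restricted to the first chain

    def test_correct_charge_natives_never_touched(self, helix16, lys_options):
        result = supercharge_with_refweights(
            helix16, refweights={"K": -5.0}, options=lys_options, seed=0
        )
        for res in helix16.residues:
            if res.aa in "RK":
                assert result.structure.get(res.site).aa == res.aa

    def test_nstruct_picks_best_of_seeds(self, helix8):
        options = DesignOptions(include_lys=True, nstruct=3)
        multi = supercharge_with_refweights(
            helix8, refweights={}, options=options, seed=5
        )
        assert len(multi.seeds) == 3


class TestTargetRamp:
    def test_reaches_target_and_records_final_weights(self, helix8, lys_options):
        current = net_formal_charge(helix8)
        result = supercharge_to_target(
            helix8, target_charge=current + 3, options=lys_options, seed=9
        )
        assert result.net_charge_after >= current + 3
        assert result.net_charge_after == net_formal_charge(result.structure)
        assert set(result.final_reference_energies) == {"K"}
        assert result.ramp_history

    def test_ramp_weights_monotonically_non_increasing(self, bundle):
        options = DesignOptions(include_glu=True, include_asp=True)
        current = net_formal_charge(bundle)
        result = supercharge_to_target(
            bundle, target_charge=current - 4, options=options, seed=4
        )
        for aa in ("D", "E"):
            weights = [refs[aa] for refs, _charge in result.ramp_history]
            assert all(b <= a for a, b in zip(weights, weights[1:]))
        # the two included types keep their default offset along the ramp
        for refs, _charge in result.ramp_history:
            assert refs["E"] - refs["D"] == pytest.approx(-0.81 - (-0.67))

    def test_invalid_targets_rejected(self, helix16, lys_options):
        current = net_formal_charge(helix16)
        with pytest.raises(UsageError):
            supercharge_to_target(
                helix16, target_charge=current, options=lys_options
            )
        with pytest.raises(UsageError):
            supercharge_to_target(
                helix16, target_charge=current - 2, options=lys_options
            )

    def test_unreachable_target_reports_best_and_weights(self, lys_options):
        structure = make_structure(FixtureSpec("GAGAG", "extended"))
        options = DesignOptions(include_lys=True, ramp_cap=3)
        with pytest.raises(UnreachableChargeError) as err:
            supercharge_to_target(structure, target_charge=5, options=options, seed=0)
        assert err.value.best_achievable == 0
        assert err.value.final_refweights == {"K": pytest.approx(-0.65 - 3 * 0.05)}

    def test_disabling_hbond_preservation_enlarges_designable_set(self, loop_motif, model):
        from supercharge.energy_design import _make_task

        strict = DesignOptions(include_lys=True)
        relaxed = DesignOptions(include_lys=True, preserve_hbonded_sidechains=False)
        task_strict = _make_task(loop_motif, "positive", strict, model)
        task_relaxed = _make_task(loop_motif, "positive", relaxed, model)
        assert set(task_strict.designable) < set(task_relaxed.designable)
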