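"""Hydrogen-bond detection and β-bulge-loop classification."""

import numpy as np
import pytest

from rglatch.errors import ConfigurationError, LoopTaxonomyError
from rglatch.hbonds import (
    backbone_hbonds,
    classify_loop,
    find_beta_hairpins,
    infer_amide_hydrogens,
    kabsch_sander_energy,
)
from rglatch.synthetic import MotifBlueprint, build_hairpin, build_ideal_strand

from conftest import make_structure, random_rotation


class TestAmideHydrogens:
    def test_h_placement_follows_preceding_carbonyl(self):
        strand = build_ideal_strand(5)
        with_h = infer_amide_hydrogens(strand)
        residues = with_h.chains[0].residues
        assert "H" not in residues[0].atoms  # chain start has no amide H
        for i in range(1, 5):
            res = residues[i]
            prev = residues[i - 1]
            assert "H" in res.atoms
            np.testing.assert_allclose(
                np.linalg.norm(res.atoms["H"] - res.atoms["N"]), 1.0, atol=1e-9
            )
            # direction is anti to the preceding carbonyl oxygen
            expected = prev.atoms["C"] - prev.atoms["O"]
            expected /= np.linalg.norm(expected)
            np.testing.assert_allclose(
                res.atoms["H"] - res.atoms["N"], expected, atol=1e-9
            )

    def test_proline_gets_no_h(self):
        strand = build_ideal_strand(3)
        strand.chains[0].residues[1].name = "PRO"
        with_h = infer_amide_hydrogens(strand)
        assert "H" not in with_h.chains[0].residues[1].atoms
        assert "H" in with_h.chains[0].residues[2].atoms

    def test_missing_carbonyl_warns_and_skips(self):
        strand = build_ideal_strand(3)
        del strand.chains[0].residues[0].atoms["O"]
        with pytest.warns(UserWarning, match="missing preceding carbonyl"):
            with_h = infer_amide_hydrogens(strand)
        assert "H" not in with_h.chains[0].residues[1].atoms


class TestBackboneHbonds:
    def test_distant_residues_make_no_bond(self, toy_chain):
        # consecutive toy residues are 3.8 Å apart but sequence-adjacent;
        # all non-adjacent pairs are ≥ 7.6 Å apart -> nothing detected
        assert len(backbone_hbonds(toy_chain)) == 0

    def test_nonnegative_cutoff_rejected(self, toy_chain):
        with pytest.raises(ConfigurationError):
            backbone_hbonds(toy_chain, energy_cutoff=0.0)

    @pytest.mark.parametrize("loop_length", [4, 5, 6])
    def test_blueprint_bonds_all_detected_on_ideal_hairpin(self, loop_length):
        bp = MotifBlueprint(loop_length=loop_length)
        st, truth = build_hairpin(bp)
        hb = backbone_hbonds(st)
        residues = st.chains[0].residues
        for donor_pos, acceptor_pos in truth["hbond_blueprint"]:
            donor = residues[donor_pos - 1]
            acceptor = residues[acceptor_pos - 1]
            if donor_pos == 1:
                continue  # chain start carries no amide H
            assert hb.has(donor.id, acceptor.id), (
                f"planted bond {donor_pos}->{acceptor_pos} missing"
            )

    def test_energy_invariant_under_rigid_motion(self):
        st, _ = build_hairpin(MotifBlueprint(loop_length=6))
        rng = np.random.default_rng(7)
        R = random_rotation(rng)
        t = rng.normal(0, 50, 3)
        moved = st.transformed(R, t)
        e0 = sorted(
            (b.donor, b.acceptor, b.energy) for b in backbone_hbonds(st)
        )
        e1 = sorted(
            (b.donor, b.acceptor, b.energy) for b in backbone_hbonds(moved)
        )
        assert len(e0) == len(e1)
        for (d0, a0, v0), (d1, a1, v1) in zip(e0, e1):
            assert (d0, a0) == (d1, a1)
            assert abs(v0 - v1) < 1e-9

    def test_energy_formula_on_constructed_geometry(self):
        """A textbook-geometry bond (N···O = 2.9 Å, linear N-H···O) has a
        Kabsch–Sander energy of a few kcal/mol below zero."""
        from rglatch.structures import Residue

        donor = Residue(
            name="ALA", number=2, chain_id="A",
            atoms={"N": np.array([0.0, 0.0, 0.0]), "H": np.array([1.0, 0.0, 0.0])},
        )
        acceptor = Residue(
            name="ALA", number=10, chain_id="A",
            atoms={"O": np.array([2.9, 0.0, 0.0]), "C": np.array([4.13, 0.0, 0.0])},
        )
        energy, r_no, r_ho = kabsch_sander_energy(donor, acceptor)
        assert r_no == pytest.approx(2.9)
        assert r_ho == pytest.approx(1.9)
        expected = 0.084 * 332 * (1 / 2.9 + 1 / 3.13 - 1 / 1.9 - 1 / 4.13)
        assert energy == pytest.approx(expected)
        assert energy < -2.0


class TestFindBetaHairpins:
    def test_ideal_hairpin_found_with_planted_loop_length(self):
        for loop_length in (4, 5, 6):
            st, _ = build_hairpin(MotifBlueprint(loop_length=loop_length))
            hb = backbone_hbonds(st)
            motifs = find_beta_hairpins(st, hb)
            assert len(motifs) == 1
            assert motifs[0].loop_length == loop_length
            assert motifs[0].orientation == "antiparallel"

    def test_helix_yields_no_hairpin(self):
        # an α-helix has i→i-4 bonds but no antiparallel bridges
        helix = build_ideal_strand(12, phi=-57.0, psi=-47.0)
        hb = backbone_hbonds(helix)
        assert find_beta_hairpins(helix, hb) == []

    def test_isolated_strand_yields_no_hairpin(self):
        strand = build_ideal_strand(8)
        assert find_beta_hairpins(strand, backbone_hbonds(strand)) == []


class TestClassifyLoop:
    @pytest.mark.parametrize(
        "loop_length,label",
        [(4, "beta_turn"), (5, "type1_bulge_loop"), (6, "type2_bulge_loop")],
    )
    def test_noiseless_blueprints_classify_as_planted(self, loop_length, label):
        st, _ = build_hairpin(MotifBlueprint(loop_length=loop_length))
        hb = backbone_hbonds(st)
        (motif,) = find_beta_hairpins(st, hb)
        cls = classify_loop(motif, st, hb)
        assert cls.label == label
        assert cls.loop_length == loop_length

    def test_strict_mode_accepts_doubly_bonded_type2(self):
        st, _ = build_hairpin(
            MotifBlueprint(loop_length=6, include_second_hbond=True)
        )
        hb = backbone_hbonds(st)
        (motif,) = find_beta_hairpins(st, hb)
        cls = classify_loop(motif, st, hb, relaxed=False)
        assert cls.label == "type2_bulge_loop"
        assert cls.characteristic_hbond.present
        assert cls.second_hbond.present

    def test_strict_mode_rejects_single_bond_type2(self):
        st, _ = build_hairpin(
            MotifBlueprint(loop_length=6, include_second_hbond=False)
        )
        hb = backbone_hbonds(st)
        (motif,) = find_beta_hairpins(st, hb)
        relaxed = classify_loop(motif, st, hb, relaxed=True)
        strict = classify_loop(motif, st, hb, relaxed=False)
        assert relaxed.label == "type2_bulge_loop"
        assert strict.label == "non_canonical"
        assert not strict.second_hbond.present

    def test_residue_i_is_first_loop_residue(self):
        st, _ = build_hairpin(MotifBlueprint(loop_length=6, strand_length=4))
        hb = backbone_hbonds(st)
        (motif,) = find_beta_hairpins(st, hb)
        cls = classify_loop(motif, st, hb)
        assert cls.residue_i == motif.loop[0].id
        # characteristic bond runs from i to the last loop residue (i+5)
        assert cls.characteristic_hbond.donor == motif.loop[0].id
        assert cls.characteristic_hbond.acceptor == motif.loop[-1].id

    def test_out_of_taxonomy_loop_refused(self):
        st, _ = build_hairpin(MotifBlueprint(loop_length=6))
        hb = backbone_hbonds(st)
        (motif,) = find_beta_hairpins(st, hb)
        motif.loop = motif.loop[:2]  # force a 2-residue "loop"
        with pytest.raises(LoopTaxonomyError):
            classify_loop(motif, st, hb)

    def test_label_length_consistency_enforced(self):
        from rglatch.hbonds import LoopClassification
        from rglatch.structures import ResidueId

        with pytest.raises(ValueError):
            LoopClassification(
                label="beta_turn",
                loop_length=6,
                residue_i=ResidueId("A", 5),
                characteristic_hbond=None,
                second_hbond=None,
            )
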