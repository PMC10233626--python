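"""Kabsch superposition, outlier rejection, probes and contacts."""

import numpy as np
import pytest

from rglatch.errors import (
    DegeneracyError,
    PairingError,
    RejectionCollapseError,
    SelectionError,
)
from rglatch.structures import ResidueId, ResidueSelection
from rglatch.superpose import (
    AtomPairing,
    contacts,
    kabsch_superpose,
    pair_atoms,
    probe_displacement,
    refine_superpose,
)

from conftest import make_structure, random_rotation


def cloud_pairing(rng, n=10, displace=None):
    a = rng.normal(0, 10, (n, 3))
    b = a.copy()
    if displace is not None:
        b = b + displace
    labels = [(ResidueId("A", i + 1), "CA") for i in range(n)]
    return AtomPairing(coords_a=a, coords_b=b, labels=labels)


class TestPairAtoms:
    def test_identical_structures_ca_mode(self):
        st = make_structure(25)
        pairing = pair_atoms(st, st, atom_mode="CA")
        assert len(pairing) == 25

    def test_gap_in_mobile_structure_is_excluded(self):
        ref = make_structure(500)
        mov = make_structure(500)
        # remove residues 395-455 (61 residues) from the mobile copy
        mov.chains[0].residues = [
            r for r in mov.chains[0].residues if not (395 <= r.number <= 455)
        ]
        pairing = pair_atoms(ref, mov, atom_mode="CA")
        assert len(pairing) == 439
        assert pairing.n_unmatched_residues == 61

    def test_insertion_code_mismatch_reported_not_aligned(self):
        ref = make_structure(10)
        mov = make_structure(10)
        mov.chains[0].residues[4].icode = "A"
        pairing = pair_atoms(ref, mov, atom_mode="CA")
        assert len(pairing) == 9
        assert pairing.n_unmatched_residues == 2  # one orphan on each side

    def test_empty_pairing_raises(self):
        a = make_structure(5)
        b = make_structure(5, chain_id="B")
        with pytest.raises((PairingError, SelectionError)):
            pair_atoms(a, b, ResidueSelection.parse("A:1-5"), "CA")


class TestKabschSuperpose:
    def test_self_superposition_is_zero(self):
        rng = np.random.default_rng(0)
        res = kabsch_superpose(cloud_pairing(rng))
        assert res.rmsd < 1e-12
        assert res.n_atoms_used == 10

    def test_recovers_applied_rigid_transform(self):
        rng = np.random.default_rng(1)
        pairing = cloud_pairing(rng, n=30)
        R = random_rotation(rng)
        t = rng.normal(0, 20, 3)
        # move B away; the fit must bring it back exactly
        pairing.coords_b = pairing.coords_b @ R.T + t
        res = kabsch_superpose(pairing)
        assert res.rmsd < 1e-9
        np.testing.assert_allclose(res.rotation @ R, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-9

    def test_matches_rotation_grid_oracle(self):
        from oracles import grid_search_rmsd

        rng = np.random.default_rng(42)
        a = rng.normal(0, 5, (20, 3))
        b = a + rng.normal(0, 1.0, (20, 3))
        pairing = AtomPairing(
            coords_a=a, coords_b=b,
            labels=[(ResidueId("A", i), "CA") for i in range(20)],
        )
        res = kabsch_superpose(pairing)
        oracle = grid_search_rmsd(a, b)
        assert res.rmsd <= oracle + 1e-9  # analytic optimum can't be beaten
        assert abs(res.rmsd - oracle) < 1e-3

    def test_collinear_points_degenerate(self):
        pts = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        pairing = AtomPairing(
            coords_a=pts, coords_b=pts.copy(),
            labels=[(ResidueId("A", i), "CA") for i in range(5)],
        )
        with pytest.raises(DegeneracyError):
            kabsch_superpose(pairing)

    def test_rmsd_symmetric_and_rigid_invariant(self):
        rng = np.random.default_rng(3)
        pairing = cloud_pairing(rng, n=15, displace=rng.normal(0, 0.5, (15, 3)))
        fwd = kabsch_superpose(pairing).rmsd
        rev = kabsch_superpose(
            AtomPairing(pairing.coords_b, pairing.coords_a, pairing.labels)
        ).rmsd
        assert abs(fwd - rev) < 1e-9
        R = random_rotation(rng)
        moved = AtomPairing(
            pairing.coords_a, pairing.coords_b @ R.T + 5.0, pairing.labels
        )
        assert abs(kabsch_superpose(moved).rmsd - fwd) < 1e-9


class TestRefineSuperpose:
    def test_no_outliers_identical_to_plain_fit(self):
        rng = np.random.default_rng(4)
        pairing = cloud_pairing(rng, n=20, displace=rng.normal(0, 0.3, (20, 3)))
        plain = kabsch_superpose(pairing)
        refined = refine_superpose(pairing, reject_cutoff=2.0)
        assert refined.n_rejected == 0
        assert refined.rmsd == pytest.approx(plain.rmsd)

    def test_planted_outliers_rejected(self):
        rng = np.random.default_rng(5)
        n = 50
        a = rng.normal(0, 10, (n, 3))
        b = a + rng.normal(0, 0.2, (n, 3))
        outliers = rng.choice(n, 5, replace=False)
        b[outliers] += 8.0  # 8 Å planted displacement
        pairing = AtomPairing(a, b, [(ResidueId("A", i), "CA") for i in range(n)])
        res = refine_superpose(pairing, reject_cutoff=2.0)
        rejected = {lab[0].number for lab in pairing.labels} - {
            lab[0].number for lab in res.atom_pairing
        }
        # every planted outlier must go; the first (outlier-biased) fit may
        # additionally push a few genuine pairs over the cutoff
        assert set(outliers) <= rejected
        assert res.n_rejected < n // 2
        assert res.rmsd < 0.5  # retained rmsd back at the noise level

    def test_refined_rmsd_never_worse(self):
        rng = np.random.default_rng(6)
        for trial in range(5):
            a = rng.normal(0, 8, (30, 3))
            b = a + rng.normal(0, 1.5, (30, 3))
            pairing = AtomPairing(
                a, b, [(ResidueId("A", i), "CA") for i in range(30)]
            )
            assert (
                refine_superpose(pairing, 2.0).rmsd
                <= kabsch_superpose(pairing).rmsd + 1e-12
            )

    def test_rejection_collapse_raises(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 10, (10, 3))
        b = a + rng.normal(0, 3.0, (10, 3)) + 20.0
        # cutoff far below the noise floor: everything gets rejected
        pairing = AtomPairing(a, b, [(ResidueId("A", i), "CA") for i in range(10)])
        with pytest.raises(RejectionCollapseError):
            refine_superpose(pairing, reject_cutoff=1e-6)


class TestProbeDisplacement:
    def test_self_displacement_zero(self):
        st = make_structure(20)
        out = probe_displacement(
            st, st, ResidueSelection.parse("A:1-20"), [(ResidueId("A", 10), "CA")]
        )
        assert out[0].distance == pytest.approx(0.0, abs=1e-12)

    def test_planted_shift_recovered_exactly(self):
        st = make_structure(40)
        moved = st.copy()
        # translate one residue by exactly 7.5 Å after an otherwise rigid copy
        probe_res = moved.chain("A").residues[19]
        shift = np.array([0.0, 7.5, 0.0])
        for name in probe_res.atoms:
            probe_res.atoms[name] = probe_res.atoms[name] + shift
        out = probe_displacement(
            st,
            moved,
            ResidueSelection.from_spans([("A", 1, 19), ("A", 21, 40)]),
            [(ResidueId("A", 20), "CA")],
        )
        assert out[0].distance == pytest.approx(7.5, abs=1e-6)

    def test_missing_probe_flagged_not_fatal(self):
        st = make_structure(10)
        out = probe_displacement(
            st, st, ResidueSelection.parse("A:1-10"),
            [(ResidueId("A", 5), "OH"), (ResidueId("A", 99), "CA")],
        )
        assert out[0].distance is None and out[0].missing_in == "both"
        assert out[1].distance is None


class TestContacts:
    def _two_region_structure(self, gap: float):
        st = make_structure(4)
        # move residues 3-4 to a parallel chain segment `gap` Å away in y
        for res in st.chains[0].residues[2:]:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + np.array([-2 * 3.8, gap, 0.0])
        return st

    def test_single_pair_within_cutoff(self):
        st = self._two_region_structure(gap=3.5)
        cset = contacts(
            st, ResidueSelection.parse("A:1-2"), ResidueSelection.parse("A:3-4"), 4.5
        )
        assert len(cset) > 0
        assert all(c.distance <= 4.5 for c in cset.pairs)

    def test_distant_regions_empty(self):
        st = self._two_region_structure(gap=10.0)
        cset = contacts(
            st, ResidueSelection.parse("A:1-2"), ResidueSelection.parse("A:3-4"), 4.5
        )
        assert len(cset) == 0
        assert cset.residues_a == [] and cset.residues_b == []

    def test_overlapping_regions_rejected(self):
        st = make_structure(10)
        with pytest.raises(SelectionError):
            contacts(
                st, ResidueSelection.parse("A:1-5"), ResidueSelection.parse("A:5-9"), 4.5
            )

    def test_contact_count_monotone_in_cutoff(self):
        st = self._two_region_structure(gap=4.0)
        counts = [
            len(
                contacts(
                    st,
                    ResidueSelection.parse("A:1-2"),
                    ResidueSelection.parse("A:3-4"),
                    cutoff,
                )
            )
            for cutoff in (3.0, 4.0, 5.0, 6.0, 8.0)
        ]
        assert counts == sorted(counts)
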