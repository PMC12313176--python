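"""Buried surface area, contact footprints and polar-bridge detection."""

import dataclasses

import numpy as np
import pytest

from pmhclens import (
    AnnotatedStructure,
    compare_footprints,
    compute_bsa,
    contact_footprint,
    detect_polar_bridges,
    fingerprint,
    partition_bsa,
)
from pmhclens.interface import InterfaceError
from pmhclens.synthetic import ContactSpec, ToyComplexPlan, generate_toy_complex
from pmhclens.structures import assign_roles, load_structure


def _shift_chain(
    s: AnnotatedStructure, chain_id: str, shift=(0.0, 0.0, 200.0)
) -> AnnotatedStructure:
    """Move one chain far away from everything else."""
    offset = np.asarray(shift, float)
    chains = {}
    for cid, residues in s.chains.items():
        if cid == chain_id:
            chains[cid] = [
                dataclasses.replace(r, atoms=[
                    dataclasses.replace(a, coords=a.coords + offset)
                    for a in r.atoms
                ])
                for r in residues
            ]
        else:
            chains[cid] = residues
    return AnnotatedStructure(chains=chains, roles=dict(s.roles), source_id=s.source_id)


def _separated(s: AnnotatedStructure) -> AnnotatedStructure:
    return _shift_chain(s, "B")


class TestBsa:
    def test_separated_chains_bury_nothing(self, bridge_complex):
        s, _, _ = bridge_complex
        apart = _separated(s)
        bsa = compute_bsa(apart, ("binder",), ("peptide",))
        assert bsa.bsa_total == pytest.approx(0.0, abs=1e-9)
        assert all(v == 0 for v in bsa.per_residue_a.values())

    def test_interface_buries_area_with_consistent_partition(self, bridge_complex):
        s, _, _ = bridge_complex
        bsa = compute_bsa(s, ("binder",), ("peptide",))
        assert bsa.bsa_total > 0
        assert sum(bsa.per_residue_b.values()) == pytest.approx(
            bsa.buried_side_b, rel=1e-6
        )
        assert bsa.bsa_total == pytest.approx(
            0.5 * (bsa.buried_side_a + bsa.buried_side_b), rel=1e-6
        )

    def test_swap_sides_leaves_total_unchanged(self, mhc_complex):
        s, _, _ = mhc_complex
        fwd = compute_bsa(s, ("binder",), ("mhc_heavy", "peptide"))
        rev = compute_bsa(s, ("mhc_heavy", "peptide"), ("binder",))
        assert fwd.bsa_total == pytest.approx(rev.bsa_total, rel=1e-9)

    def test_symmetric_dimer_buries_equally(self, tmp_path):
        # two identical parallel strands: burial must be mirror-symmetric
        from pmhclens.structures import write_pdb
        from pmhclens.synthetic import _strand_residues

        a = _strand_residues("A", "AAAAAAAAA", np.zeros(3), np.array([1.0, 0, 0]))
        b = [
            dataclasses.replace(r, chain_id="B", atoms=[
                dataclasses.replace(at, coords=at.coords * np.array([1, -1, 1])
                                    + np.array([0.0, 4.5, 0.0]))
                for at in r.atoms
            ])
            for r in a
        ]
        s = AnnotatedStructure(
            chains={"A": a, "B": b}, roles={"A": "binder", "B": "peptide"}
        )
        bsa = compute_bsa(s, ("binder",), ("peptide",))
        # congruent sides bury equal area up to sphere-quadrature resolution
        assert bsa.buried_side_a == pytest.approx(bsa.buried_side_b, rel=2e-2)

    def test_overlapping_sides_raise(self, bridge_complex):
        s, _, _ = bridge_complex
        with pytest.raises(InterfaceError, match="overlap"):
            compute_bsa(s, ("binder",), ("binder", "peptide"))


class TestPartition:
    def test_peptide_only_contact_gives_fraction_one(self, bridge_complex):
        s, _, _ = bridge_complex   # toy has no MHC chain at all
        bsa = compute_bsa(s, ("binder",), ("peptide",))
        bsa_pep, bsa_mhc, frac = partition_bsa(bsa.per_residue_b, s)
        assert bsa_mhc == 0.0
        assert frac == pytest.approx(1.0)

    def test_mhc_only_contact_gives_fraction_zero(self, mhc_complex):
        s, _, _ = mhc_complex
        # with the peptide moved out of the groove only MHC contacts remain
        apart = _shift_chain(s, "P", (0.0, 0.0, -200.0))
        bsa = compute_bsa(apart, ("binder",), ("mhc_heavy", "peptide"))
        bsa_pep, bsa_mhc, frac = partition_bsa(bsa.per_residue_b, apart)
        assert bsa_mhc > 0
        assert frac == pytest.approx(0.0, abs=1e-9)

    def test_mixed_interface_fraction_in_between(self, mhc_complex):
        s, _, _ = mhc_complex
        bsa = compute_bsa(s, ("binder",), ("mhc_heavy", "peptide"))
        _, _, frac = partition_bsa(bsa.per_residue_b, s)
        assert 0.0 < frac < 1.0

    def test_zero_burial_is_an_error(self, bridge_complex):
        s, _, _ = bridge_complex
        apart = _separated(s)
        bsa = compute_bsa(apart, ("binder",), ("peptide",))
        with pytest.raises(InterfaceError, match="undefined|zero"):
            partition_bsa(bsa.per_residue_b, apart)


class TestFootprint:
    def test_constructed_contacts_recovered_exactly(self, bridge_complex):
        s, manifest, _ = bridge_complex
        binder_set, _, pep_set = contact_footprint(s, cutoff=4.5)
        truth = manifest["contact_pairs_4p5"]["B:P"]
        true_binder = {pair[0] for pair in truth}
        true_pep = {pair[1] for pair in truth}
        assert {num for (_, num, _) in binder_set} == true_binder
        assert pep_set == true_pep

    def test_tiny_cutoff_empties_footprint(self, bridge_complex):
        s, _, _ = bridge_complex
        binder_set, mhc_set, pep_set = contact_footprint(s, cutoff=0.1)
        assert binder_set == set() and mhc_set == set() and pep_set == set()

    @pytest.mark.parametrize("lo,hi", [(3.5, 4.5), (4.5, 6.0)])
    def test_growing_cutoff_never_shrinks_contacts(self, mhc_complex, lo, hi):
        s, _, _ = mhc_complex
        b_lo, m_lo, p_lo = contact_footprint(s, lo)
        b_hi, m_hi, p_hi = contact_footprint(s, hi)
        assert b_lo <= b_hi and m_lo <= m_hi and p_lo <= p_hi


class TestPolarBridges:
    def test_constructed_hbond_and_salt_bridge_found(self, bridge_complex):
        s, _, _ = bridge_complex
        hbonds, bridges = detect_polar_bridges(s)
        # Ser-OG at 2.8 A from a backbone O across the interface
        assert any(
            {h.donor[1], h.acceptor[1]} == {"OG", "O"}
            and h.distance == pytest.approx(2.8, abs=0.05)
            for h in hbonds
        )
        # Lys-NZ at 3.5 A from Glu-OE1
        assert len(bridges) == 1
        sb = bridges[0]
        assert "LYS" in sb.basic_residue and "GLU" in sb.acidic_residue
        assert sb.min_distance == pytest.approx(3.5, abs=0.05)
        assert not sb.histidine_mediated

    def test_bridges_outside_cutoff_are_dropped(self, bridge_complex):
        s, _, _ = bridge_complex
        hbonds, bridges = detect_polar_bridges(s, hb_cutoff=2.0, sb_cutoff=2.0)
        assert hbonds == [] and bridges == []

    def test_each_bond_listed_once(self, bridge_complex):
        s, _, _ = bridge_complex
        hbonds, _ = detect_polar_bridges(s)
        keys = [frozenset({h.donor, h.acceptor}) for h in hbonds]
        assert len(keys) == len(set(keys))


class TestFingerprintAndComparison:
    def test_rigid_motion_leaves_fingerprint_unchanged(self, tmp_path):
        from scipy.spatial.transform import Rotation

        # 3.6 A keeps the salt bridge clear of the 3.5 A H-bond boundary,
        # where file rounding could flip the census between twins
        base = ToyComplexPlan(
            designed_angle=0.0,
            designed_contacts=[
                ContactSpec(5, "OG", "peptide", 5, "O", 2.8, "SER", "ALA"),
                ContactSpec(23, "NZ", "peptide", 7, "OE1", 3.6, "LYS", "GLU"),
            ],
        )
        R = Rotation.from_euler("zyx", [40.0, -25.0, 70.0], degrees=True).as_matrix()
        moved = dataclasses.replace(
            base, rigid_motion=(R, np.array([7.0, -3.0, 12.0]))
        )
        fps = []
        for name, plan in (("still", base), ("moved", moved)):
            pdb, _ = generate_toy_complex(plan, tmp_path / name)
            s = assign_roles(load_structure(pdb))
            fps.append(fingerprint(s))
        a, b = fps
        # twins pass through PDB files, whose coordinates carry 3 decimals;
        # exact 1e-6 invariance of in-memory transforms is covered in the
        # SASA canonical-frame test
        assert b.bsa_total == pytest.approx(a.bsa_total, rel=1e-3)
        assert b.peptide_fraction == pytest.approx(a.peptide_fraction, rel=1e-3)
        assert b.peptide_contact_positions == a.peptide_contact_positions
        assert {n for (_, n, _) in b.binder_contact_residues} == {
            n for (_, n, _) in a.binder_contact_residues
        }
        assert len(b.hbonds) == len(a.hbonds)
        assert len(b.salt_bridges) == len(a.salt_bridges)

    def test_identical_fingerprints_share_everything(self, mhc_complex):
        s, _, _ = mhc_complex
        fp = fingerprint(s)
        shared, table = compare_footprints([fp, fp])
        assert shared == fp.mhc_contact_numbers()
        assert table["shared_by_all"].all()

    def test_disjoint_footprints_share_nothing(self, mhc_complex):
        s, _, _ = mhc_complex
        fp1 = fingerprint(s)
        fp2 = dataclasses.replace(
            fp1,
            source_id="other",
            mhc_contact_residues={("M", 999, "")},
        )
        shared, table = compare_footprints([fp1, fp2])
        assert shared == set()
        assert table.loc[table.binder == "other", "exclusive"].all()

    def test_allele_mismatch_warns(self, mhc_complex):
        s, _, _ = mhc_complex
        fp = fingerprint(s)
        with pytest.warns(UserWarning, match="allele"):
            compare_footprints([fp, fp], allele_labels=["A*02", "B*07"])
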