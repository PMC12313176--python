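"""Interface fingerprinting of a binder/peptide-MHC complex.

Quantities computed: buried surface area (BSA) and its partition into
peptide-derived versus MHC-derived contributions, heavy-atom contact
footprints on either side of the interface, and a census of polar bridges
(distance-criterion hydrogen bonds and salt bridges). These are the numbers
a structural immunologist reads off a binder/pMHC crystal structure to judge
how peptide-centric the recognition is.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import chemdata
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, compute_sasa
from .structures import AnnotatedStructure, Residue, StructureError

DEFAULT_CONTACT_CUTOFF = 4.5   # heavy-atom distance, Angstroms
DEFAULT_HB_CUTOFF = 3.5        # donor..acceptor heavy-atom distance
DEFAULT_SB_CUTOFF = 4.0        # basic N .. acidic O distance

ResidueKey = tuple[str, int, str]


class InterfaceError(Exception):
    pass


@dataclasses.dataclass
class HBond:
    donor: tuple[str, str]      # (residue label incl. chain, atom name)
    acceptor: tuple[str, str]
    distance: float
    partners: tuple[str, str]   # chain roles of donor side, acceptor side


@dataclasses.dataclass
class SaltBridge:
    basic_residue: str
    acidic_residue: str
    min_distance: float
    histidine_mediated: bool = False


@dataclasses.dataclass
class BsaResult:
    """Buried surface area between two chain groups.

    ``bsa_total`` uses the per-side-average convention
    (SASA_a + SASA_b - SASA_ab)/2; both one-sided burials are kept because
    the literature is split on which convention a printed number uses.
    """

    bsa_total: float
    buried_side_a: float
    buried_side_b: float
    per_residue_a: dict[ResidueKey, float]
    per_residue_b: dict[ResidueKey, float]
    convention: str = "per-side-average"


@dataclasses.dataclass
class InterfaceFingerprint:
    source_id: str
    bsa_total: float
    bsa_peptide: float
    bsa_mhc: float
    peptide_fraction: float
    binder_contact_residues: set[ResidueKey]
    mhc_contact_residues: set[ResidueKey]
    peptide_contact_positions: set[int]
    hbonds: list[HBond]
    salt_bridges: list[SaltBridge]
    contact_cutoff: float
    buried_side_binder: float = 0.0
    buried_side_target: float = 0.0

    def mhc_contact_numbers(self) -> set[int]:
        """Author residue numbers of the MHC contact set (for cross-structure
        comparison on a shared allele numbering)."""
        return {num for (_, num, _) in self.mhc_contact_residues}

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "bsa_total": self.bsa_total,
            "bsa_convention": "per-side-average",
            "buried_side_binder": self.buried_side_binder,
            "buried_side_target": self.buried_side_target,
            "bsa_peptide": self.bsa_peptide,
            "bsa_mhc": self.bsa_mhc,
            "peptide_fraction": self.peptide_fraction,
            "contact_cutoff": self.contact_cutoff,
            "n_binder_contacts": len(self.binder_contact_residues),
            "n_mhc_contacts": len(self.mhc_contact_residues),
            "peptide_contact_positions": sorted(self.peptide_contact_positions),
            "mhc_contact_numbers": sorted(self.mhc_contact_numbers()),
            "n_hbonds": len(self.hbonds),
            "n_salt_bridges": len(self.salt_bridges),
            "hbonds": [dataclasses.asdict(h) for h in self.hbonds],
            "salt_bridges": [dataclasses.asdict(b) for b in self.salt_bridges],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _chains_for_roles(s: AnnotatedStructure, roles: Iterable[str]) -> list[str]:
    wanted = set(roles)
    out = [cid for cid, r in s.roles.items() if r in wanted]
    return out


def compute_bsa(
    s: AnnotatedStructure,
    side_a: Sequence[str],
    side_b: Sequence[str],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> BsaResult:
    """Buried surface area between two disjoint groups of chain roles.

    side_a / side_b are chain *roles* (e.g. ("binder",) vs
    ("mhc_heavy", "peptide")). Per-residue burial is the residue's SASA in
    its own side alone minus its SASA in the two-side complex; chains not in
    either side are removed entirely, never occluding.
    """
    if set(side_a) & set(side_b):
        raise InterfaceError(f"sides overlap: {set(side_a) & set(side_b)}")
    chains_a = _chains_for_roles(s, side_a)
    chains_b = _chains_for_roles(s, side_b)
    if not chains_a or not chains_b:
        raise InterfaceError(
            f"both sides must be present; got chains {chains_a} vs {chains_b}"
        )
    # one shared canonical frame for all three SASA evaluations: differencing
    # is then exact (separated chains bury exactly zero) and the whole BSA is
    # invariant under rigid motion of the input structure
    from .sasa import canonical_frame

    union_coords, _ = s.heavy_atom_table(chains_a + chains_b)
    R, t = canonical_frame(union_coords)
    s = s.transformed(R, t)
    sasa_a = compute_sasa(s, chains_a, probe=probe, n_points=n_points,
                          canonicalize=False)
    sasa_b = compute_sasa(s, chains_b, probe=probe, n_points=n_points,
                          canonicalize=False)
    sasa_ab = compute_sasa(s, chains_a + chains_b, probe=probe,
                           n_points=n_points, canonicalize=False)

    def buried(iso, keys):
        return {
            key: max(0.0, iso.per_residue[key] - sasa_ab.per_residue[key])
            for key in keys
        }

    per_a = buried(sasa_a, sasa_a.per_residue)
    per_b = buried(sasa_b, sasa_b.per_residue)
    buried_a = sasa_a.total - sum(
        sasa_ab.per_residue[k] for k in sasa_a.per_residue
    )
    buried_b = sasa_b.total - sum(
        sasa_ab.per_residue[k] for k in sasa_b.per_residue
    )
    return BsaResult(
        bsa_total=0.5 * (sasa_a.total + sasa_b.total - sasa_ab.total),
        buried_side_a=buried_a,
        buried_side_b=buried_b,
        per_residue_a=per_a,
        per_residue_b=per_b,
    )


def partition_bsa(
    per_residue_target: dict[ResidueKey, float], s: AnnotatedStructure
) -> tuple[float, float, float]:
    """Split target-side burial into peptide vs MHC contributions.

    Returns (bsa_peptide, bsa_mhc, peptide_fraction) where the fraction is
    bsa_peptide / (bsa_peptide + bsa_mhc) — the "peptide-specific" share of
    the footprint.
    """
    pep_chain = s.chain_for_role("peptide")
    mhc_chains = set(_chains_for_roles(s, ("mhc_heavy", "b2m")))
    bsa_pep = sum(v for (cid, _, _), v in per_residue_target.items() if cid == pep_chain)
    bsa_mhc = sum(v for (cid, _, _), v in per_residue_target.items() if cid in mhc_chains)
    total = bsa_pep + bsa_mhc
    if total <= 0:
        raise InterfaceError("target-side buried area is zero; peptide fraction undefined")
    return bsa_pep, bsa_mhc, bsa_pep / total


def _cross_pairs(
    s: AnnotatedStructure, chains_a: list[str], chains_b: list[str], cutoff: float
) -> list[tuple[Residue, Residue, float, str, str]]:
    """All heavy-atom contacts (res_a, res_b, distance, atom_a, atom_b) within cutoff."""
    coords_a, index_a = s.heavy_atom_table(chains_a)
    coords_b, index_b = s.heavy_atom_table(chains_b)
    out = []
    if len(coords_a) == 0 or len(coords_b) == 0:
        return out
    tree = cKDTree(coords_b)
    for i, hits in enumerate(tree.query_ball_point(coords_a, cutoff)):
        res_a, atom_a = index_a[i]
        for j in hits:
            res_b, atom_b = index_b[j]
            d = float(np.linalg.norm(coords_a[i] - coords_b[j]))
            out.append((res_a, res_b, d, atom_a.name, atom_b.name))
    return out


def contact_footprint(
    s: AnnotatedStructure, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> tuple[set[ResidueKey], set[ResidueKey], set[int]]:
    """Contact residue sets across the binder <-> pMHC interface.

    A residue is a contact iff at least one of its heavy atoms is within
    cutoff of a heavy atom across the interface. Peptide contacts are
    reported as 1-based positions from the N terminus.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    binder = _chains_for_roles(s, ("binder",))
    target = _chains_for_roles(s, ("mhc_heavy", "peptide"))
    if not binder:
        raise StructureError("binder role not assigned")
    pep_chain = s.chain_for_role("peptide") if s.has_role("peptide") else None
    pep_positions = (
        {res.key: i + 1 for i, res in enumerate(s.chains[pep_chain])}
        if pep_chain else {}
    )
    binder_set: set[ResidueKey] = set()
    mhc_set: set[ResidueKey] = set()
    pep_set: set[int] = set()
    for res_a, res_b, _, _, _ in _cross_pairs(s, binder, target, cutoff):
        binder_set.add(res_a.key)
        if res_b.chain_id == pep_chain:
            pep_set.add(pep_positions[res_b.key])
        else:
            mhc_set.add(res_b.key)
    return binder_set, mhc_set, pep_set


def detect_polar_bridges(
    s: AnnotatedStructure,
    hb_cutoff: float = DEFAULT_HB_CUTOFF,
    sb_cutoff: float = DEFAULT_SB_CUTOFF,
    target_roles: Sequence[str] = ("mhc_heavy", "peptide"),
) -> tuple[list[HBond], list[SaltBridge]]:
    """Distance-criterion hydrogen bonds and salt bridges, binder vs target.

    Without deposited hydrogens the criterion is heavy-atom distance only: a
    donor-capable atom on one side within hb_cutoff of an acceptor-capable
    atom on the other. Salt bridges pair side-chain N of Lys/Arg/His with
    side-chain carboxylate O of Asp/Glu within sb_cutoff; His bridges are
    flagged since protonation is unknown. Each bond is listed once.
    """
    binder = _chains_for_roles(s, ("binder",))
    target = _chains_for_roles(s, target_roles)
    if not binder or not target:
        raise StructureError("binder and target roles must be assigned")
    role_of = dict(s.roles)
    pairs = _cross_pairs(s, binder, target, max(hb_cutoff, sb_cutoff))

    hbonds: list[HBond] = []
    seen_hb: set[frozenset] = set()
    sb_best: dict[tuple[str, str], SaltBridge] = {}

    for res_a, res_b, d, atom_a, atom_b in pairs:
        label_a = f"{res_a.chain_id}/{res_a.label}"
        label_b = f"{res_b.chain_id}/{res_b.label}"
        if d <= hb_cutoff:
            don_a = atom_a in chemdata.hb_donor_atoms(res_a.aa3)
            acc_a = atom_a in chemdata.hb_acceptor_atoms(res_a.aa3)
            don_b = atom_b in chemdata.hb_donor_atoms(res_b.aa3)
            acc_b = atom_b in chemdata.hb_acceptor_atoms(res_b.aa3)
            for (dres, datm, dlab), (ares, aatm, alab) in (
                ((res_a, atom_a, label_a), (res_b, atom_b, label_b)),
                ((res_b, atom_b, label_b), (res_a, atom_a, label_a)),
            ):
                is_don = datm in chemdata.hb_donor_atoms(dres.aa3)
                is_acc = aatm in chemdata.hb_acceptor_atoms(ares.aa3)
                if is_don and is_acc:
                    key = frozenset({(dlab, datm), (alab, aatm)})
                    if key not in seen_hb:
                        seen_hb.add(key)
                        hbonds.append(HBond(
                            donor=(dlab, datm), acceptor=(alab, aatm),
                            distance=round(d, 3),
                            partners=(role_of[dres.chain_id], role_of[ares.chain_id]),
                        ))
                    break  # one orientation per atom pair
        if d <= sb_cutoff:
            for (basic, batm, blab), (acidic, aatm2, alab2) in (
                ((res_a, atom_a, label_a), (res_b, atom_b, label_b)),
                ((res_b, atom_b, label_b), (res_a, atom_a, label_a)),
            ):
                if (
                    batm in chemdata.BASIC_SIDECHAIN_N.get(basic.aa3, ())
                    and aatm2 in chemdata.ACIDIC_SIDECHAIN_O.get(acidic.aa3, ())
                ):
                    key2 = (blab, alab2)
                    prev = sb_best.get(key2)
                    if prev is None or d < prev.min_distance:
                        sb_best[key2] = SaltBridge(
                            basic_residue=blab, acidic_residue=alab2,
                            min_distance=round(d, 3),
                            histidine_mediated=basic.aa3 == "HIS",
                        )
    salt_bridges = sorted(
        sb_best.values(), key=lambda b: (b.basic_residue, b.acidic_residue)
    )
    hbonds.sort(key=lambda h: (h.donor, h.acceptor))
    return hbonds, salt_bridges


def fingerprint(
    s: AnnotatedStructure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    hb_cutoff: float = DEFAULT_HB_CUTOFF,
    sb_cutoff: float = DEFAULT_SB_CUTOFF,
) -> InterfaceFingerprint:
    """Full interface fingerprint of one binder/pMHC complex."""
    target_roles = [r for r in ("mhc_heavy", "peptide") if s.has_role(r)]
    bsa = compute_bsa(s, ("binder",), tuple(target_roles), probe=probe, n_points=n_points)
    if s.has_role("peptide"):
        bsa_pep, bsa_mhc, frac = partition_bsa(bsa.per_residue_b, s)
    else:
        bsa_pep, bsa_mhc, frac = 0.0, bsa.buried_side_b, 0.0
    binder_set, mhc_set, pep_set = contact_footprint(s, cutoff)
    hbonds, bridges = detect_polar_bridges(s, hb_cutoff, sb_cutoff)
    return InterfaceFingerprint(
        source_id=s.source_id,
        bsa_total=bsa.bsa_total,
        bsa_peptide=bsa_pep,
        bsa_mhc=bsa_mhc,
        peptide_fraction=frac,
        binder_contact_residues=binder_set,
        mhc_contact_residues=mhc_set,
        peptide_contact_positions=pep_set,
        hbonds=hbonds,
        salt_bridges=bridges,
        contact_cutoff=cutoff,
        buried_side_binder=bsa.buried_side_a,
        buried_side_target=bsa.buried_side_b,
    )


def compare_footprints(
    fps: Sequence[InterfaceFingerprint], allele_labels: Optional[Sequence[str]] = None
) -> tuple[set[int], pd.DataFrame]:
    """Shared/exclusive MHC contact residues across binders of one allele.

    MHC residues are compared by author numbering, which is meaningful when
    all fingerprints come from the same allele (e.g. HLA-A*02). Returns the
    shared residue-number set and a tidy table, one row per (binder,
    residue), with membership flags.
    """
    if len(fps) < 2:
        raise InterfaceError("need at least two fingerprints to compare")
    if allele_labels is not None and len(set(allele_labels)) > 1:
        import warnings as _warnings
        _warnings.warn(
            "fingerprints come from different MHC alleles; residue numbering "
            "may not correspond", stacklevel=2,
        )
    sets = {fp.source_id: fp.mhc_contact_numbers() for fp in fps}
    shared = set.intersection(*sets.values())
    rows = []
    for fp in fps:
        for num in sorted(sets[fp.source_id]):
            rows.append({
                "binder": fp.source_id,
                "mhc_residue": num,
                "shared_by_all": num in shared,
                "exclusive": all(
                    num not in other
                    for sid, other in sets.items() if sid != fp.source_id
                ),
                "peptide_fraction": fp.peptide_fraction,
            })
    return shared, pd.DataFrame(rows)
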