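"""Coordinate data model for binder/peptide-MHC complexes.

Parses PDB/mmCIF files (via gemmi), resolves alternate locations to the
highest-occupancy conformer, drops waters and non-polymer heteroatoms, and
assigns biological roles to chains: the designed binder, the MHC class I
heavy chain, beta-2-microglobulin, the presented peptide (8-13 residues for
class I), and any crystallization chaperone.
"""

from __future__ import annotations

import dataclasses
import urllib.request
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .chemdata import AA3_TO_1, STANDARD_AA3

ROLES = ("binder", "mhc_heavy", "b2m", "peptide", "chaperone", "other")

PEPTIDE_LENGTH_RANGE = (8, 13)   # class I groove accommodates 8-13 mers
MHC_HEAVY_LENGTH_RANGE = (250, 300)
B2M_LENGTH_RANGE = (90, 110)


class StructureError(Exception):
    """Base class for structure parsing/annotation failures."""


class StructureFormatError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class RoleAssignmentError(StructureError):
    pass


@dataclasses.dataclass
class Atom:
    """One heavy (or hydrogen) atom with PDB-style naming."""

    element: str
    name: str
    coords: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclasses.dataclass
class Residue:
    """One residue; author numbering preserved for reporting."""

    chain_id: str
    seq_number: int
    insertion_code: str
    aa3: str
    atoms: list[Atom]
    is_standard: bool = True

    def __post_init__(self) -> None:
        if not any(a.is_heavy for a in self.atoms):
            raise ValueError(
                f"residue {self.aa3}{self.seq_number}{self.insertion_code} "
                f"chain {self.chain_id}: no heavy atoms"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.aa3}{self.seq_number}{self.insertion_code}".strip()

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy])

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.aa3, "X")


@dataclasses.dataclass
class AnnotatedStructure:
    """Chains of residues plus a chain -> biological role mapping."""

    chains: dict[str, list[Residue]]
    roles: dict[str, str] = dataclasses.field(default_factory=dict)
    source_id: str = ""
    role_evidence: dict[str, str] = dataclasses.field(default_factory=dict)
    warnings: list[str] = dataclasses.field(default_factory=list)

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def chain_for_role(self, role: str) -> str:
        for cid, r in self.roles.items():
            if r == role:
                return cid
        raise RoleAssignmentError(f"no chain assigned role {role!r}")

    def has_role(self, role: str) -> bool:
        return role in self.roles.values()

    def residues(self, chain_ids: Optional[Iterable[str]] = None) -> list[Residue]:
        ids = list(chain_ids) if chain_ids is not None else list(self.chains)
        out: list[Residue] = []
        for cid in ids:
            if cid not in self.chains:
                raise StructureError(f"chain {cid!r} not in structure {self.source_id!r}")
            out.extend(self.chains[cid])
        return out

    def heavy_atom_table(
        self, chain_ids: Optional[Iterable[str]] = None
    ) -> tuple[np.ndarray, list[tuple[Residue, Atom]]]:
        """Heavy-atom coordinates plus parallel (residue, atom) index."""
        index: list[tuple[Residue, Atom]] = []
        for res in self.residues(chain_ids):
            for atom in res.atoms:
                if atom.is_heavy:
                    index.append((res, atom))
        coords = np.array([a.coords for _, a in index]) if index else np.empty((0, 3))
        return coords, index

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AnnotatedStructure":
        """Copy with every atom moved by x -> R x + t (rigid motion)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        chains = {
            cid: [
                dataclasses.replace(
                    res,
                    atoms=[
                        dataclasses.replace(a, coords=R @ a.coords + t)
                        for a in res.atoms
                    ],
                )
                for res in residues
            ]
            for cid, residues in self.chains.items()
        }
        return AnnotatedStructure(
            chains=chains, roles=dict(self.roles), source_id=self.source_id,
            role_evidence=dict(self.role_evidence), warnings=list(self.warnings),
        )


def _resolve_altlocs(raw_atoms: list[tuple[str, gemmi.Atom]]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, list[tuple[str, gemmi.Atom]]] = {}
    for altloc, atom in raw_atoms:
        by_name.setdefault(atom.name, []).append((altloc, atom))
    kept = []
    for name, variants in by_name.items():
        variants.sort(key=lambda av: (-av[1].occ, av[0]))
        kept.append(variants[0][1])
    return kept


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    """Amino-acid-like residue: standard, or nonstandard with a CA atom."""
    if res.name in ("HOH", "WAT", "DOD"):
        return False
    if res.name in STANDARD_AA3:
        return True
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    return any(a.name == "CA" and a.element.name != "Ca" for a in res)


def load_structure(path: str | Path, format: str = "auto") -> AnnotatedStructure:
    """Read a PDB or mmCIF file into an AnnotatedStructure (roles unassigned).

    Waters and non-polymer heteroatoms are excluded; alternate locations are
    resolved to the highest-occupancy conformer; hydrogens, if deposited, are
    kept in atom lists but ignored by all heavy-atom analyses downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise ValueError(f"format must be pdb/mmcif/auto, got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path.name}: no models")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if not _is_polymer_residue(res):
                continue
            kept = _resolve_altlocs([(a.altloc, a) for a in res])
            atoms = [
                Atom(
                    element=a.element.name,
                    name=a.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                )
                for a in kept
            ]
            if not any(a.is_heavy for a in atoms):
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    aa3=res.name,
                    atoms=atoms,
                    is_standard=res.name in STANDARD_AA3,
                )
            )
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise EmptyStructureError(f"{path.name}: no polymer residues found")
    return AnnotatedStructure(chains=chains, source_id=path.stem)


def _contact_counts(
    s: AnnotatedStructure, chain_a: str, chain_b: str, cutoff: float = 4.5
) -> int:
    """Number of heavy-atom pairs between two chains within cutoff."""
    ca, _ = s.heavy_atom_table([chain_a])
    cb, _ = s.heavy_atom_table([chain_b])
    if len(ca) == 0 or len(cb) == 0:
        return 0
    tree = cKDTree(cb)
    return int(sum(len(hits) for hits in tree.query_ball_point(ca, cutoff)))


def assign_roles(
    s: AnnotatedStructure, hints: Optional[dict[str, str]] = None
) -> AnnotatedStructure:
    """Assign biological roles to chains by size and contact heuristics.

    peptide: shortest chain of class I length (8-13). mhc_heavy: ~250-300
    residue chain contacting the peptide most. b2m: ~90-110 residue chain
    contacting the heavy chain. binder: remaining chain with the largest
    peptide contact count. Leftover chains contacting the complex become
    chaperone, anything else other. Explicit hints override heuristics (a
    warning is recorded when a hint contradicts the heuristic evidence).
    """
    hints = dict(hints or {})
    roles: dict[str, str] = {}
    evidence: dict[str, str] = {}
    warnings: list[str] = []
    lengths = {cid: len(res) for cid, res in s.chains.items()}

    for cid, role in hints.items():
        if cid not in s.chains:
            raise RoleAssignmentError(f"hint names unknown chain {cid!r}")
        if role not in ROLES:
            raise RoleAssignmentError(f"hint role {role!r} not one of {ROLES}")
        roles[cid] = role
        evidence[cid] = "explicit hint"
        if role == "peptide" and not (
            PEPTIDE_LENGTH_RANGE[0] <= lengths[cid] <= PEPTIDE_LENGTH_RANGE[1]
        ):
            warnings.append(
                f"hint assigns peptide to chain {cid} of length {lengths[cid]}, "
                f"outside the class I range {PEPTIDE_LENGTH_RANGE}"
            )

    def unassigned() -> list[str]:
        return [cid for cid in s.chains if cid not in roles]

    def pick_unique(candidates: list[str], keyfn, role: str) -> Optional[str]:
        if not candidates:
            return None
        scored = sorted(((keyfn(c), c) for c in candidates), reverse=True)
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            tied = [c for score, c in scored if score == scored[0][0]]
            raise RoleAssignmentError(
                f"ambiguous {role} assignment: chains {tied} tie "
                f"(score {scored[0][0]}); pass hints to resolve"
            )
        return scored[0][1]

    # peptide: shortest in-range chain
    if "peptide" not in roles.values():
        pep_candidates = [
            c for c in unassigned()
            if PEPTIDE_LENGTH_RANGE[0] <= lengths[c] <= PEPTIDE_LENGTH_RANGE[1]
        ]
        pep = pick_unique(pep_candidates, lambda c: -lengths[c], "peptide")
        if pep is not None:
            roles[pep] = "peptide"
            evidence[pep] = f"shortest chain of class I length ({lengths[pep]} residues)"

    pep_chain = next((c for c, r in roles.items() if r == "peptide"), None)

    # mhc_heavy: in-range chain contacting the peptide most
    if "mhc_heavy" not in roles.values() and pep_chain is not None:
        mhc_candidates = [
            c for c in unassigned()
            if MHC_HEAVY_LENGTH_RANGE[0] <= lengths[c] <= MHC_HEAVY_LENGTH_RANGE[1]
        ]
        mhc = pick_unique(
            mhc_candidates, lambda c: _contact_counts(s, c, pep_chain), "mhc_heavy"
        )
        if mhc is not None and _contact_counts(s, mhc, pep_chain) > 0:
            roles[mhc] = "mhc_heavy"
            evidence[mhc] = (
                f"{lengths[mhc]} residues, "
                f"{_contact_counts(s, mhc, pep_chain)} atom contacts with peptide"
            )

    mhc_chain = next((c for c, r in roles.items() if r == "mhc_heavy"), None)

    # b2m: ~99-residue chain contacting the heavy chain
    if "b2m" not in roles.values() and mhc_chain is not None:
        b2m_candidates = [
            c for c in unassigned()
            if B2M_LENGTH_RANGE[0] <= lengths[c] <= B2M_LENGTH_RANGE[1]
            and _contact_counts(s, c, mhc_chain) > 0
        ]
        b2m = pick_unique(
            b2m_candidates, lambda c: _contact_counts(s, c, mhc_chain), "b2m"
        )
        if b2m is not None:
            roles[b2m] = "b2m"
            evidence[b2m] = (
                f"{lengths[b2m]} residues, contacts MHC heavy chain"
            )

    # binder: remaining chain with the largest peptide contact count
    if "binder" not in roles.values() and pep_chain is not None:
        cand = [c for c in unassigned() if _contact_counts(s, c, pep_chain) > 0]
        binder = pick_unique(
            cand, lambda c: _contact_counts(s, c, pep_chain), "binder"
        )
        if binder is not None:
            roles[binder] = "binder"
            evidence[binder] = (
                f"{_contact_counts(s, binder, pep_chain)} atom contacts with peptide"
            )

    # leftovers: chaperone if touching the assigned complex, else other
    assigned = [c for c in s.chains if c in roles]
    for cid in unassigned():
        touches = any(_contact_counts(s, cid, a) > 0 for a in assigned)
        roles[cid] = "chaperone" if touches else "other"
        evidence[cid] = (
            "contacts the assigned complex" if touches else "no complex contacts"
        )

    for role in ("binder", "mhc_heavy", "peptide"):
        holders = [c for c, r in roles.items() if r == role]
        if len(holders) > 1:
            raise RoleAssignmentError(f"role {role} assigned to multiple chains {holders}")

    return AnnotatedStructure(
        chains=s.chains, roles=roles, source_id=s.source_id,
        role_evidence=evidence, warnings=list(s.warnings) + warnings,
    )


def peptide_sequence(s: AnnotatedStructure) -> str:
    """One-letter peptide sequence, positions 1-based from the N terminus.

    Position i of the returned string is the i-th residue in chain order
    regardless of author numbering, so e.g. the Met-Trp bulge of the
    NY-ESO-1 9-mer is always at positions 4-5.
    """
    cid = s.chain_for_role("peptide")
    letters = []
    for res in s.chains[cid]:
        if res.aa3 not in AA3_TO_1:
            raise StructureError(
                f"nonstandard residue {res.aa3}{res.seq_number} in peptide chain {cid}"
            )
        letters.append(AA3_TO_1[res.aa3])
    return "".join(letters)


def write_pdb(s: AnnotatedStructure, path: str | Path) -> None:
    """Write ATOM records; used for toy fixtures and round-trip checks."""
    path = Path(path)
    lines = []
    serial = 1
    for cid, residues in s.chains.items():
        for res in residues:
            for atom in res.atoms:
                name = atom.name
                # PDB column rules: 4-char names start at col 13, shorter at 14
                name_field = name if len(name) == 4 else f" {name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{'':1s}{res.aa3:>3s} {cid:1s}"
                    f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1].aa3:>3s} {cid:1s}"
                     f"{residues[-1].seq_number:4d}")
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_mmcif(s: AnnotatedStructure, path: str | Path) -> None:
    """Write the same model as mmCIF (via gemmi), for dialect round trips."""
    import io
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        tmp = Path(fh.name)
    try:
        write_pdb(s, tmp)
        st = gemmi.read_structure(str(tmp), format=gemmi.CoorFormat.Pdb)
        st.setup_entities()
        st.make_mmcif_document().write_file(str(path))
    finally:
        tmp.unlink(missing_ok=True)


RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"


def fetch_structure(pdb_id: str, cache_dir: str | Path, timeout: float = 15.0) -> Path:
    """Download an mmCIF from RCSB into cache_dir (no-op when cached).

    Never called implicitly: analyses take file paths. Raises OSError when
    the archive is unreachable.
    """
    pdb_id = pdb_id.strip().upper()
    if len(pdb_id) != 4:
        raise ValueError(f"PDB accession must be 4 characters, got {pdb_id!r}")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_dir / f"{pdb_id}.cif"
    if target.exists():
        return target
    url = RCSB_URL.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except OSError as exc:
        raise OSError(
            f"could not fetch {pdb_id} from {url}: {exc}. "
            f"Place {pdb_id}.cif in {cache_dir} manually to proceed."
        ) from exc
    target.write_bytes(data)
    return target
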