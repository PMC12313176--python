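"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Three generators: anchor-biased 9-mer ligandomes with planted neighbours at
controlled Hamming distances, toy two/three-chain helical complexes with
constructed interface ground truth, and block-structured predicted-aligned-
error matrices. Every generator is a pure function of (plan, seed): the same
inputs produce byte-identical files, and each output ships with a JSON
manifest recording the planted truth so downstream checks never peek at
generator internals.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemdata import AA_ALPHABET
from .structures import AnnotatedStructure, Atom, Residue, write_pdb


class PlanError(Exception):
    pass


# ---------------------------------------------------------------------------
# Ligandome generator
# ---------------------------------------------------------------------------

# HLA-A*02-like anchor preferences of MS-detected 9-mers: hydrophobic
# anchors at positions 2 and 9. A plausible emulation, not a fit to the
# real atlas.
DEFAULT_ANCHOR_PROFILE: dict[int, dict[str, float]] = {
    2: {"L": 0.5, "M": 0.25, "I": 0.25},
    9: {"V": 0.5, "L": 0.3, "I": 0.2},
}


@dataclasses.dataclass
class PlantedPeptide:
    distance: int
    preserve_motif: bool
    organism: str = "human"


@dataclasses.dataclass
class LigandomePlan:
    n_background: int = 500
    anchor_profile: Optional[dict[int, dict[str, float]]] = None
    planted: Sequence[PlantedPeptide] = ()
    seed: int = 0
    motif_positions: frozenset[int] = frozenset({4, 5})
    background_organism: str = "human"
    min_background_distance: int = 7
    length: int = 9

    def __post_init__(self) -> None:
        if self.anchor_profile is None:
            self.anchor_profile = DEFAULT_ANCHOR_PROFILE
        n_free = self.length - len(self.motif_positions)
        for p in self.planted:
            if not 1 <= p.distance <= self.length:
                raise PlanError(f"planted distance {p.distance} outside 1..{self.length}")
            if p.distance >= self.min_background_distance:
                raise PlanError(
                    f"planted distance {p.distance} >= background floor "
                    f"{self.min_background_distance}; ground truth would be ambiguous"
                )
            if p.preserve_motif and p.distance > n_free:
                raise PlanError(
                    f"cannot plant distance {p.distance} while preserving the "
                    f"motif: only {n_free} free positions"
                )


def _mutate(
    target: str, distance: int, positions: Sequence[int], rng: np.random.Generator
) -> str:
    """Mutate ``target`` at ``distance`` of the given 1-based positions."""
    chosen = rng.choice(len(positions), size=distance, replace=False)
    letters = list(target)
    for ci in sorted(chosen):
        pos = positions[int(ci)] - 1
        alternatives = [a for a in AA_ALPHABET if a != letters[pos]]
        letters[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(letters)


def _plant_peptide(
    target: str, spec: PlantedPeptide, motif: frozenset[int], rng: np.random.Generator
) -> str:
    n = len(target)
    free = [i for i in range(1, n + 1) if i not in motif]
    if spec.preserve_motif:
        if spec.distance > len(free):
            raise PlanError(
                f"cannot plant distance {spec.distance} while preserving the "
                f"motif: only {len(free)} free positions"
            )
        return _mutate(target, spec.distance, free, rng)
    # motif must be broken so the motif pass cannot pick this entry up
    if not motif:
        raise PlanError("preserve_motif=False requires nonempty motif positions")
    motif_hits = int(rng.integers(1, min(spec.distance, len(motif)) + 1))
    pep = _mutate(target, motif_hits, sorted(motif), rng)
    remaining = spec.distance - motif_hits
    if remaining > len(free):
        raise PlanError(f"distance {spec.distance} infeasible for length {n}")
    if remaining:
        pep = _mutate(pep, remaining, free, rng)
    return pep


def _sample_background(
    target: str,
    plan: LigandomePlan,
    taken: set[str],
    rng: np.random.Generator,
) -> str:
    """One anchor-biased background peptide far from the target, motif broken."""
    n = plan.length
    profile = plan.anchor_profile
    for _ in range(10_000):
        letters = []
        for pos in range(1, n + 1):
            weights = profile.get(pos)
            if weights:
                aas = list(weights)
                p = np.array([weights[a] for a in aas], float)
                letters.append(aas[int(rng.choice(len(aas), p=p / p.sum()))])
            else:
                letters.append(AA_ALPHABET[int(rng.integers(20))])
        pep = "".join(letters)
        dist = sum(1 for a, b in zip(pep, target) if a != b)
        motif_intact = all(pep[i - 1] == target[i - 1] for i in plan.motif_positions)
        if pep not in taken and dist >= plan.min_background_distance and not motif_intact:
            return pep
    raise PlanError("background sampling failed; plan constraints too tight")


def generate_ligandome(
    plan: LigandomePlan, target: str, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a ligandome TSV plus a ground-truth manifest JSON.

    Planted entries realize exactly their planned Hamming distance and motif
    status; background entries sit at or beyond the plan's distance floor
    with the motif broken, so the planted panel is recoverable by
    construction. Returns (tsv_path, manifest_path).
    """
    if len(target) != plan.length:
        raise PlanError(f"target length {len(target)} != plan length {plan.length}")
    rng = np.random.default_rng(plan.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    taken: set[str] = {target}
    planted_rows = []
    for k, spec in enumerate(plan.planted):
        for _ in range(1000):
            pep = _plant_peptide(target, spec, plan.motif_positions, rng)
            if pep not in taken:
                break
        else:
            raise PlanError(f"could not realize distinct planted peptide #{k}")
        taken.add(pep)
        planted_rows.append({
            "peptide": pep,
            "source_protein": f"PLANTED_{k:03d}",
            "organism": spec.organism,
            "distance": spec.distance,
            "preserve_motif": spec.preserve_motif,
        })

    background_rows = []
    for k in range(plan.n_background):
        pep = _sample_background(target, plan, taken, rng)
        taken.add(pep)
        background_rows.append({
            "peptide": pep,
            "source_protein": f"BG_{k:05d}",
            "organism": plan.background_organism,
        })

    table = pd.DataFrame(
        [{k: r[k] for k in ("peptide", "source_protein", "organism")}
         for r in planted_rows + background_rows],
        columns=["peptide", "source_protein", "organism"],
    )
    tsv_path = out_dir / "ligandome.tsv"
    table.to_csv(tsv_path, sep="\t", index=False)

    # expected screen outcome, derived from plan-known truth only
    human = [r for r in planted_rows if r["organism"].lower() == "human"]
    if human:
        dmin = min(r["distance"] for r in human)
        min_set = sorted(r["peptide"] for r in human if r["distance"] == dmin)
        motif_set = sorted(
            r["peptide"] for r in human
            if r["preserve_motif"] and r["peptide"] not in min_set
        )
    else:
        dmin, min_set, motif_set = None, [], []
    manifest = {
        "generator": "ligandome",
        "seed": plan.seed,
        "target": target,
        "motif_positions": sorted(plan.motif_positions),
        "n_background": plan.n_background,
        "min_background_distance": plan.min_background_distance,
        "planted": planted_rows,
        "expected_min_distance": dmin,
        "expected_min_distance_set": min_set,
        "expected_motif_set": motif_set,
        "expected_panel": sorted(set(min_set) | set(motif_set)),
    }
    manifest_path = out_dir / "ligandome.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return tsv_path, manifest_path


# ---------------------------------------------------------------------------
# Toy helical complex generator
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5        # A per residue along the axis
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # CA radius, A

_ELEMENT_BY_INITIAL = {"C": "C", "N": "N", "O": "O", "S": "S", "H": "H"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_BY_INITIAL.get(atom_name[0].upper(), "C")


@dataclasses.dataclass
class ContactSpec:
    """One designed cross-chain atom pair realized at an exact distance."""

    binder_res: int              # 1-based index into the binder chain
    binder_atom: str
    partner_chain: str           # "peptide" or "mhc"
    partner_res: int             # 1-based index into the partner chain
    partner_atom: str
    distance: float
    binder_aa3: str = "ALA"
    partner_aa3: str = "ALA"


@dataclasses.dataclass
class ToyComplexPlan:
    peptide_length: int = 9
    peptide_sequence: Optional[str] = None       # one-letter; default poly-A
    binder_helix_count: int = 2
    binder_helix_length: int = 14
    binder_height: float = 9.0                   # z offset above the groove
    helix_spacing: float = 10.0                  # lateral offset between helices
    designed_angle: float = 0.0                  # degrees vs the peptide axis
    include_mhc: bool = False
    mhc_helix_length: int = 14
    designed_contacts: Sequence[ContactSpec] = ()
    rigid_motion: Optional[tuple[np.ndarray, np.ndarray]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peptide_sequence is not None:
            if len(self.peptide_sequence) != self.peptide_length:
                raise PlanError("peptide_sequence length != peptide_length")
        if not 0.0 <= self.designed_angle <= 90.0:
            raise PlanError("designed_angle must lie in [0, 90] degrees")
        if self.binder_helix_count < 1:
            raise PlanError("need at least one binder helix")


def _strand_residues(
    chain_id: str, sequence: str, origin: np.ndarray, direction: np.ndarray
) -> list[Residue]:
    """Extended chain: CA every 3.8 A along direction, backbone interpolated."""
    from .chemdata import AA1_TO_3

    direction = direction / np.linalg.norm(direction)
    n = len(sequence)
    cas = [origin + direction * (3.8 * (i - (n - 1) / 2.0)) for i in range(n)]
    residues = []
    for i, aa in enumerate(sequence):
        ca = cas[i]
        atoms = [
            Atom("N", "N", ca - direction * 1.2 + np.array([0, 0.35, 0.0])),
            Atom("C", "CA", ca),
            Atom("C", "C", ca + direction * 1.2 + np.array([0, 0.35, 0.0])),
            Atom("O", "O", ca + direction * 1.2 + np.array([0, 1.35, 0.3])),
        ]
        if aa != "G":
            atoms.append(Atom("C", "CB", ca + np.array([0, -0.9, 1.2])))
        residues.append(Residue(chain_id, i + 1, "", AA1_TO_3[aa], atoms))
    return residues


def _helix_residues(
    chain_id: str,
    n_res: int,
    origin: np.ndarray,
    direction: np.ndarray,
    start_num: int = 1,
    phase_deg: float = 0.0,
) -> list[Residue]:
    """Ideal alpha-helix CA trace (rise 1.5 A, 100 deg/residue, radius 2.3 A)
    with interpolated N/C and radially displaced O/CB."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    # orthonormal frame around the axis
    seed_vec = np.array([0.0, 0.0, 1.0])
    if abs(direction @ seed_vec) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, seed_vec)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)

    cas, radial = [], []
    for i in range(n_res):
        theta = np.radians(HELIX_TWIST * i + phase_deg)
        r_vec = np.cos(theta) * u + np.sin(theta) * v
        cas.append(origin + direction * (HELIX_RISE * i) + HELIX_RADIUS * r_vec)
        radial.append(r_vec)
    residues = []
    for i in range(n_res):
        ca = cas[i]
        prev_dir = cas[i - 1] - ca if i > 0 else ca - cas[i + 1]
        next_dir = cas[i + 1] - ca if i < n_res - 1 else ca - cas[i - 1]
        atoms = [
            Atom("N", "N", ca + 0.35 * prev_dir),
            Atom("C", "CA", ca),
            Atom("C", "C", ca + 0.35 * next_dir),
            Atom("O", "O", ca + 0.35 * next_dir + 1.1 * radial[i]),
            Atom("C", "CB", ca + 1.3 * radial[i]),
        ]
        residues.append(Residue(chain_id, start_num + i, "", "ALA", atoms))
    return residues


def _apply_contacts(
    chains: dict[str, list[Residue]],
    contacts: Sequence[ContactSpec],
    partner_chain_ids: dict[str, str],
) -> list[dict]:
    """Realize each designed cross-chain atom pair at its exact distance."""
    realized = []
    for spec in contacts:
        binder_res = chains["B"][spec.binder_res - 1]
        pcid = partner_chain_ids.get(spec.partner_chain)
        if pcid is None or pcid not in chains:
            raise PlanError(f"designed contact names absent chain {spec.partner_chain!r}")
        partner_res = chains[pcid][spec.partner_res - 1]
        ca_b = binder_res.atom("CA").coords
        ca_p = partner_res.atom("CA").coords
        gap = float(np.linalg.norm(ca_p - ca_b))
        offset = (gap - spec.distance) / 2.0
        if offset < 0.5 or offset > 5.5:
            raise PlanError(
                f"contact {spec.binder_atom}-{spec.partner_atom}: CA gap {gap:.1f} A "
                f"needs side-chain reach {offset:.1f} A (allowed 0.5-5.5)"
            )
        u = (ca_p - ca_b) / gap
        pos_b = ca_b + u * offset
        pos_p = ca_p - u * offset
        binder_res.aa3 = spec.binder_aa3
        partner_res.aa3 = spec.partner_aa3

        def _place(res: Residue, name: str, pos: np.ndarray) -> None:
            # moving an existing atom (e.g. backbone O) keeps names unique,
            # which PDB round-tripping requires
            res.atoms = [a for a in res.atoms if a.name != name]
            res.atoms.append(Atom(_element_of(name), name, pos))

        _place(binder_res, spec.binder_atom, pos_b)
        _place(partner_res, spec.partner_atom, pos_p)
        realized.append({
            "binder_residue": f"B/{binder_res.aa3}{binder_res.seq_number}",
            "binder_atom": spec.binder_atom,
            "partner_residue": f"{pcid}/{partner_res.aa3}{partner_res.seq_number}",
            "partner_atom": spec.partner_atom,
            "distance": round(float(np.linalg.norm(pos_p - pos_b)), 4),
            "planned_distance": spec.distance,
        })
    return realized


def _cross_chain_contacts(
    s: AnnotatedStructure, chain_a: str, chain_b: str, cutoff: float
) -> list[tuple[int, int]]:
    """Brute-force residue-index contact pairs (1-based) between two chains."""
    pairs = set()
    for i, res_a in enumerate(s.chains[chain_a]):
        for j, res_b in enumerate(s.chains[chain_b]):
            da = res_a.heavy_coords()
            db = res_b.heavy_coords()
            d2 = ((da[:, None, :] - db[None, :, :]) ** 2).sum(axis=2)
            if (d2 < cutoff * cutoff).any():
                pairs.add((i + 1, j + 1))
    return sorted(pairs)


def _min_cross_chain_distance(s: AnnotatedStructure) -> float:
    from scipy.spatial import cKDTree

    ids = list(s.chains)
    best = np.inf
    for i, a in enumerate(ids):
        ca, _ = s.heavy_atom_table([a])
        for b in ids[i + 1:]:
            cb, _ = s.heavy_atom_table([b])
            d, _ = cKDTree(cb).query(ca, k=1)
            best = min(best, float(d.min()))
    return best


def generate_toy_complex(
    plan: ToyComplexPlan, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a toy complex PDB plus a ground-truth manifest.

    Geometry: peptide as an extended strand along x at the origin; binder
    helices above it (z = binder_height) running at ``designed_angle`` to
    the peptide axis in the xy plane; optionally two MHC-like groove helices
    flanking the peptide in y. Designed contacts are realized within
    0.05 A. Returns (pdb_path, manifest_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pep_seq = plan.peptide_sequence or "A" * plan.peptide_length

    chains: dict[str, list[Residue]] = {}
    chains["P"] = _strand_residues(
        "P", pep_seq, np.zeros(3), np.array([1.0, 0.0, 0.0])
    )

    theta = np.radians(plan.designed_angle)
    helix_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
    lateral = np.array([-np.sin(theta), np.cos(theta), 0.0])
    binder: list[Residue] = []
    half_len = HELIX_RISE * (plan.binder_helix_length - 1) / 2.0
    for h in range(plan.binder_helix_count):
        side = (h - (plan.binder_helix_count - 1) / 2.0) * plan.helix_spacing
        origin = (
            -helix_dir * half_len
            + lateral * side
            + np.array([0.0, 0.0, plan.binder_height])
        )
        # alternate phases by 180 deg so the pooled CA wobble of a helix
        # pair cancels and the bundle's principal axis is exactly helix_dir
        binder.extend(
            _helix_residues(
                "B", plan.binder_helix_length, origin, helix_dir,
                start_num=1 + h * plan.binder_helix_length,
                phase_deg=180.0 * (h % 2),
            )
        )
    chains["B"] = binder

    if plan.include_mhc:
        mhc: list[Residue] = []
        for k, y in enumerate((-8.0, 8.0)):
            origin = np.array([-half_len, y, 0.0])
            mhc.extend(
                _helix_residues(
                    "M", plan.mhc_helix_length, origin, np.array([1.0, 0.0, 0.0]),
                    start_num=1 + k * plan.mhc_helix_length,
                )
            )
        chains["M"] = mhc

    partner_ids = {"peptide": "P", "mhc": "M" if plan.include_mhc else None}
    realized = _apply_contacts(chains, plan.designed_contacts, partner_ids)

    roles = {"P": "peptide", "B": "binder"}
    if plan.include_mhc:
        roles["M"] = "mhc_heavy"
    s = AnnotatedStructure(chains=chains, roles=roles, source_id="toy")

    sheet_normal = np.array([0.0, 0.0, 1.0])
    if plan.rigid_motion is not None:
        R, t = plan.rigid_motion
        R = np.asarray(R, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise PlanError("rigid_motion rotation must be proper orthonormal")
        s = s.transformed(R, np.asarray(t, float))
        sheet_normal = R @ sheet_normal

    min_gap = _min_cross_chain_distance(s)
    designed_min = min((c.distance for c in plan.designed_contacts), default=np.inf)
    if min_gap < 2.0 and min_gap < designed_min - 1e-6:
        raise PlanError(f"steric clash: cross-chain atoms at {min_gap:.2f} A")

    pdb_path = out_dir / "toy_complex.pdb"
    write_pdb(s, pdb_path)

    contact_truth = {
        f"B:{other}": _cross_chain_contacts(s, "B", other, 4.5)
        for other in chains if other != "B"
    }
    from .chemdata import AA3_TO_1

    realized_pep_seq = "".join(AA3_TO_1.get(r.aa3, "X") for r in chains["P"])
    manifest = {
        "generator": "toy_complex",
        "seed": plan.seed,
        "chains": {cid: len(res) for cid, res in chains.items()},
        "roles": roles,
        "peptide_sequence": realized_pep_seq,
        "designed_angle": plan.designed_angle,
        "sheet_normal": [round(float(x), 6) for x in sheet_normal],
        "designed_contacts": realized,
        "contact_pairs_4p5": contact_truth,
        "rigid_motion_applied": plan.rigid_motion is not None,
    }
    manifest_path = out_dir / "toy_complex.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return pdb_path, manifest_path


# ---------------------------------------------------------------------------
# PAE matrix generator
# ---------------------------------------------------------------------------

def generate_pae(
    chain_lengths: dict[str, int],
    block_means: dict[tuple[str, str], float],
    noise_sd: float,
    seed: int,
    out_path: str | Path,
) -> tuple[Path, Path]:
    """Write an AlphaFold-dialect PAE JSON with block-structured means.

    ``block_means`` maps unordered chain pairs (and (c, c) diagonals) to the
    planned mean error of that block. Gaussian noise of sd ``noise_sd`` is
    added then clipped at zero; the manifest records the exact realized
    symmetrized inter-chain mean for every chain pair, which is what
    interface-PAE recomputes. Returns (pae_path, manifest_path).
    """
    if noise_sd < 0:
        raise PlanError("noise_sd must be nonnegative")
    if not chain_lengths:
        raise PlanError("chain_lengths must be nonempty")
    rng = np.random.default_rng(seed)
    chains = list(chain_lengths)
    spans: dict[str, tuple[int, int]] = {}
    start = 0
    for c in chains:
        spans[c] = (start, start + int(chain_lengths[c]))
        start += int(chain_lengths[c])
    n = start

    def mean_for(a: str, b: str) -> float:
        for key in ((a, b), (b, a)):
            if key in block_means:
                return float(block_means[key])
        raise PlanError(f"no block mean given for chain pair ({a}, {b})")

    values = np.zeros((n, n))
    for a in chains:
        a0, a1 = spans[a]
        for b in chains:
            b0, b1 = spans[b]
            mu = mean_for(a, b)
            if mu < 0:
                raise PlanError("block means must be nonnegative")
            block = np.full((a1 - a0, b1 - b0), mu)
            if noise_sd > 0:
                block = block + rng.normal(0.0, noise_sd, block.shape)
            values[a0:a1, b0:b1] = block
    np.fill_diagonal(values, 0.0)
    values = np.clip(values, 0.0, None)

    sym = 0.5 * (values + values.T)
    realized = {}
    for i, a in enumerate(chains):
        a0, a1 = spans[a]
        for b in chains[i + 1:]:
            b0, b1 = spans[b]
            realized[f"{a}:{b}"] = float(sym[a0:a1, b0:b1].mean())

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "predicted_aligned_error": [[round(float(v), 6) for v in row] for row in values],
        "chain_lengths": {c: int(chain_lengths[c]) for c in chains},
        "max_predicted_aligned_error": round(float(values.max()), 6),
    }
    out_path.write_text(json.dumps(doc, sort_keys=True) + "\n")
    sidecar = out_path.with_name(out_path.name + ".chains.json")
    sidecar.write_text(
        json.dumps({"chain_lengths": {c: int(chain_lengths[c]) for c in chains}},
                   sort_keys=True) + "\n"
    )
    manifest = {
        "generator": "pae",
        "seed": seed,
        "noise_sd": noise_sd,
        "chain_lengths": {c: int(chain_lengths[c]) for c in chains},
        "planned_block_means": {f"{a}:{b}": mean_for(a, b)
                                for i, a in enumerate(chains)
                                for b in chains[i:]},
        "realized_interchain_means": {k: round(v, 10) for k, v in realized.items()},
    }
    manifest_path = out_path.with_name(out_path.stem + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_path, manifest_path
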