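"""Docking geometry over the peptide-MHC groove, and rigid superposition.

The docking angle follows the TCR-literature convention of an in-plane
crossing angle: the peptide axis (first principal component of peptide
C-alpha atoms, oriented N to C) and the binder's interface-helix axis are
both projected onto the plane of the MHC platform, and the unsigned angle
between them is reported in [0, 90] degrees.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .interface import InterfaceFingerprint, contact_footprint
from .structures import AnnotatedStructure, StructureError

CONVENTION_ID = "pep-ca-pca/contact-helix-pca/platform-plane/v1"


class GeometryError(Exception):
    pass


@dataclasses.dataclass
class DockingGeometry:
    groove_axis: np.ndarray
    binder_axis: np.ndarray
    sheet_normal: np.ndarray
    docking_angle: float          # degrees, [0, 90]
    convention_id: str = CONVENTION_ID
    binder_axis_fallback: bool = False


@dataclasses.dataclass
class SuperpositionReport:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    pairing_rule: str


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length vector")
    return v / n


def principal_axis(coords: np.ndarray, orient: Optional[np.ndarray] = None) -> np.ndarray:
    """First principal component of a coordinate cloud, optionally oriented
    so its dot product with ``orient`` is nonnegative."""
    coords = np.asarray(coords, float)
    if len(coords) < 3:
        raise GeometryError(f"need at least 3 points, got {len(coords)}")
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = _unit(vt[0])
    if orient is not None and float(axis @ orient) < 0:
        axis = -axis
    return axis


def _ca_coords(s: AnnotatedStructure, chain_id: str, keys=None) -> np.ndarray:
    out = []
    for res in s.chains[chain_id]:
        if keys is not None and res.key not in keys:
            continue
        ca = res.atom("CA")
        if ca is not None:
            out.append(ca.coords)
    return np.array(out)


def groove_axis(s: AnnotatedStructure) -> np.ndarray:
    """Long axis of the peptide in the groove: PCA of peptide CA, N->C."""
    cid = s.chain_for_role("peptide")
    cas = _ca_coords(s, cid)
    if len(cas) < 3:
        raise GeometryError("peptide has fewer than 3 CA atoms")
    return principal_axis(cas, orient=cas[-1] - cas[0])


def mhc_sheet_normal(s: AnnotatedStructure, cutoff: float = 4.5) -> np.ndarray:
    """Normal of the least-squares plane through the CA atoms of MHC
    residues in contact with the peptide (the groove platform)."""
    mhc = s.chain_for_role("mhc_heavy")
    pep = s.chain_for_role("peptide")
    pep_coords, _ = s.heavy_atom_table([pep])
    from scipy.spatial import cKDTree

    tree = cKDTree(pep_coords)
    platform_keys = set()
    for res in s.chains[mhc]:
        coords = res.heavy_coords()
        if len(tree.query_ball_point(coords, cutoff, return_length=True).nonzero()[0]):
            platform_keys.add(res.key)
    cas = _ca_coords(s, mhc, platform_keys)
    if len(cas) < 3:
        raise GeometryError("fewer than 3 MHC platform residues near the peptide")
    centred = cas - cas.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return _unit(vt[2])   # smallest-variance direction = plane normal


def _contiguous_segments(indices: Sequence[int], max_gap: int = 1) -> list[list[int]]:
    """Split sorted residue indices into runs, tolerating gaps of max_gap."""
    segments: list[list[int]] = []
    for i in sorted(indices):
        if segments and i - segments[-1][-1] <= max_gap + 1:
            segments[-1].append(i)
        else:
            segments.append([i])
    return segments


def binder_axis(
    s: AnnotatedStructure,
    fp: Optional[InterfaceFingerprint] = None,
    sheet_normal: Optional[np.ndarray] = None,
    cutoff: float = 4.5,
) -> tuple[np.ndarray, bool]:
    """Axis of the binder's interface helices, projected into the platform.

    Takes the two longest contiguous runs of binder contact residues (the
    interface-dominant helices), fits their CA principal axis, and projects
    it onto the plane orthogonal to the MHC-sheet normal. Falls back to all
    interface CA atoms (flagged) when fewer than two runs exist.
    """
    binder = s.chain_for_role("binder")
    if fp is not None:
        contact_keys = fp.binder_contact_residues
    else:
        contact_keys, _, _ = contact_footprint(s, cutoff)
    if not contact_keys:
        raise GeometryError("binder has no interface contact residues")
    key_to_idx = {res.key: i for i, res in enumerate(s.chains[binder])}
    indices = sorted(key_to_idx[k] for k in contact_keys if k in key_to_idx)
    segments = _contiguous_segments(indices)
    fallback = len(segments) < 2
    if fallback:
        chosen = indices
    else:
        segments.sort(key=len, reverse=True)
        chosen = sorted(segments[0] + segments[1])
    keys = {s.chains[binder][i].key for i in chosen}
    cas = _ca_coords(s, binder, keys)
    if len(cas) < 4:
        # interface too sparse to trace the helices (e.g. a few designed
        # contacts): the whole chain is a better-conditioned estimate than
        # a scatter of isolated contact residues
        cas = _ca_coords(s, binder)
        fallback = True
    axis = principal_axis(cas)
    if sheet_normal is not None:
        axis = axis - (axis @ sheet_normal) * _unit(np.asarray(sheet_normal, float))
        axis = _unit(axis)
    return axis, fallback


def docking_angle(
    groove: np.ndarray, binder: np.ndarray, sheet_normal: np.ndarray
) -> float:
    """In-plane crossing angle between groove and binder axes, degrees.

    Both axes are projected onto the plane orthogonal to the sheet normal;
    the unsigned angle arccos(|g.b|) lies in [0, 90] and is invariant to
    sign flips of either axis.
    """
    n = _unit(np.asarray(sheet_normal, float))
    proj = []
    for v in (groove, binder):
        v = np.asarray(v, float)
        p = v - (v @ n) * n
        if np.linalg.norm(p) < 1e-8:
            raise GeometryError("axis parallel to the sheet normal; angle undefined")
        proj.append(_unit(p))
    cosang = abs(float(proj[0] @ proj[1]))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def docking_report(
    s: AnnotatedStructure,
    fp: Optional[InterfaceFingerprint] = None,
    sheet_normal: Optional[np.ndarray] = None,
    cutoff: float = 4.5,
) -> DockingGeometry:
    """Groove axis, binder axis, platform normal and crossing angle."""
    g = groove_axis(s)
    n = (
        np.asarray(sheet_normal, float)
        if sheet_normal is not None
        else mhc_sheet_normal(s, cutoff)
    )
    b, fallback = binder_axis(s, fp=fp, sheet_normal=n, cutoff=cutoff)
    return DockingGeometry(
        groove_axis=g,
        binder_axis=b,
        sheet_normal=_unit(n),
        docking_angle=docking_angle(g, b, n),
        binder_axis_fallback=fallback,
    )


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    pairing: Optional[Sequence[tuple[int, int]]] = None,
    pairing_rule: str = "index-identical",
) -> SuperpositionReport:
    """Least-squares rigid superposition (Kabsch, reflection-corrected).

    Finds the proper rotation R and translation t minimizing
    sum_i |R m_i + t - r_i|^2 over the paired atoms and reports the RMSD at
    the optimum.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if pairing is not None:
        mi = [i for i, _ in pairing]
        ri = [j for _, j in pairing]
        mobile, reference = mobile[mi], reference[ri]
    if mobile.shape != reference.shape:
        raise GeometryError(
            f"paired coordinate sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    n = len(mobile)
    if n < 3:
        raise GeometryError("need at least 3 atom pairs")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    rank = np.sum(S > 1e-10 * S.max()) if S.max() > 0 else 0
    if rank < 2:
        raise GeometryError("coordinates are collinear; rotation underdetermined")
    t = rc - R @ mc
    diff = (mobile @ R.T + t) - reference
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionReport(
        rotation=R, translation=t, rmsd=rmsd, n_atoms=n, pairing_rule=pairing_rule
    )
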