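"""Solvent-accessible surface area by Shrake-Rupley sphere sampling.

Each heavy atom is inflated by the probe radius and sampled with a
deterministic Fibonacci spiral of test points; a point is accessible when it
lies outside every neighbouring inflated sphere. Determinism (fixed point
rule, fixed radii set) is the design goal: the same structure always yields
the same area to the last bit.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .chemdata import RADII_SET_NAME, vdw_radius
from .structures import AnnotatedStructure, StructureError

DEFAULT_PROBE = 1.4       # water probe, Angstroms
DEFAULT_N_POINTS = 960


@dataclasses.dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible areas in square Angstroms."""

    per_atom: dict[tuple[str, int, str, str], float]
    per_residue: dict[tuple[str, int, str], float]
    total: float
    probe: float
    n_points: int
    radii_set: str = RADII_SET_NAME


def fibonacci_sphere(n: int) -> np.ndarray:
    """n nearly-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA for a bare coordinate/radius array."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    sphere = fibonacci_sphere(n_points)
    inflated = radii + probe
    tree = cKDTree(coords)
    max_reach = inflated.max()
    areas = np.empty(n)
    for i in range(n):
        ri = inflated[i]
        pts = coords[i] + ri * sphere
        neighbours = [
            j for j in tree.query_ball_point(coords[i], ri + max_reach) if j != i
        ]
        if neighbours:
            nb = np.asarray(neighbours)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (inflated[nb] ** 2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = n_points
        areas[i] = 4.0 * np.pi * ri * ri * exposed / n_points
    return areas


def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) mapping a cloud into its principal-axis frame.

    The frame is intrinsic (centroid at the origin, axes by descending
    covariance eigenvalue, signs fixed by the third moment), so any rigid
    motion of the input yields the same canonical coordinates x -> R x + t.
    """
    coords = np.asarray(coords, float)
    mean = coords.mean(axis=0)
    centred = coords - mean
    if len(coords) < 3:
        return np.eye(3), -mean
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    V = vecs[:, ::-1].copy()
    X = centred @ V
    for k in range(3):
        skew = float((X[:, k] ** 3).sum())
        if abs(skew) < 1e-9:
            idx = int(np.argmax(np.abs(X[:, k])))
            skew = float(X[idx, k])
        if skew < 0:
            V[:, k] = -V[:, k]
    R = V.T
    return R, -R @ mean


def canonical_coords(coords: np.ndarray) -> np.ndarray:
    """Coordinates in the intrinsic principal-axis frame (see
    :func:`canonical_frame`). Running the sphere quadrature in this frame
    makes SASA exactly invariant under rigid motion of the structure."""
    coords = np.asarray(coords, float)
    R, t = canonical_frame(coords)
    return coords @ R.T + t


def compute_sasa(
    s: AnnotatedStructure,
    chain_subset: Optional[Iterable[str]] = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    canonicalize: bool = True,
) -> SasaResult:
    """SASA of the heavy atoms of chain_subset, other chains removed.

    Chains outside the subset do not occlude: computing a chain "alone" and
    in complex and differencing gives buried surface area. With
    ``canonicalize`` (default) coordinates are first moved into their
    principal-axis frame, making the result independent of how the
    structure happens to be oriented in the file.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 92:
        raise ValueError("n_points must be at least 92 for a usable quadrature")
    subset = list(chain_subset) if chain_subset is not None else list(s.chains)
    if not subset:
        raise ValueError("chain_subset must be nonempty")
    for cid in subset:
        if cid not in s.chains:
            raise StructureError(f"chain {cid!r} not in structure")

    coords, index = s.heavy_atom_table(subset)
    radii = np.array([vdw_radius(atom.element) for _, atom in index])
    if canonicalize and len(coords) >= 3:
        coords = canonical_coords(coords)
    areas = shrake_rupley_areas(coords, radii, probe=probe, n_points=n_points)

    per_atom: dict[tuple[str, int, str, str], float] = {}
    per_residue: dict[tuple[str, int, str], float] = {}
    for (res, atom), area in zip(index, areas):
        per_atom[res.key + (atom.name,)] = float(area)
        per_residue[res.key] = per_residue.get(res.key, 0.0) + float(area)
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=float(areas.sum()),
        probe=probe,
        n_points=n_points,
    )
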