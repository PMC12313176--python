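"""Reference chemistry tables used across the package.

Van der Waals radii, per-residue hydrogen-bond donor/acceptor atom names,
salt-bridge atom names, and amino-acid code conversions. These are plain
module-level constants so every analysis is auditable and deterministic.
"""

from __future__ import annotations

import functools

import numpy as np

# Bondi (1964) van der Waals radii by element, in Angstroms. The generic
# fallback covers rare elements (Se in MSE etc.) without failing.
VDW_RADII_BONDI64: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
VDW_DEFAULT_RADIUS = 1.80
RADII_SET_NAME = "bondi64"


def vdw_radius(element: str) -> float:
    return VDW_RADII_BONDI64.get(element.upper(), VDW_DEFAULT_RADIUS)


STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Heavy-atom hydrogen-bond capability tables. Donor = heavy atom bearing a
# polar hydrogen; acceptor = heavy atom with a lone pair. Backbone N is a
# donor (except proline), backbone O an acceptor, for every residue.
SIDECHAIN_HB_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
SIDECHAIN_HB_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
    "CYS": {"SG"},
}

# Salt bridges: side-chain nitrogens of basic residues vs side-chain
# carboxylate oxygens. His is included as potentially protonated and every
# His-mediated bridge is flagged in the report.
BASIC_SIDECHAIN_N: dict[str, set[str]] = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
ACIDIC_SIDECHAIN_O: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


def hb_donor_atoms(aa3: str) -> set[str]:
    """Heavy donor atom names for one residue type (backbone N included)."""
    donors = set(SIDECHAIN_HB_DONORS.get(aa3, set()))
    if aa3 != "PRO":
        donors.add("N")
    return donors


def hb_acceptor_atoms(aa3: str) -> set[str]:
    """Heavy acceptor atom names for one residue type (backbone O included)."""
    acceptors = set(SIDECHAIN_HB_ACCEPTORS.get(aa3, set()))
    acceptors.update({"O", "OXT"})
    return acceptors


@functools.cache
def blosum62_dissimilarity() -> dict[tuple[str, str], float]:
    """Substitution dissimilarity d(a,b) = s(a,a) - s(a,b) from BLOSUM62.

    Nonnegative with zero diagonal; symmetrized because BLOSUM self-scores
    differ between the two letters: d(a,b) = (s(a,a)+s(b,b))/2 - s(a,b).
    """
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in AA_ALPHABET:
        for b in AA_ALPHABET:
            d = 0.5 * (mat[a, a] + mat[b, b]) - mat[a, b]
            table[(a, b)] = float(d)
    return table


def dissimilarity_matrix() -> np.ndarray:
    """20x20 dissimilarity array indexed by AA_ALPHABET order."""
    table = blosum62_dissimilarity()
    n = len(AA_ALPHABET)
    out = np.zeros((n, n))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = table[(a, b)]
    return out
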