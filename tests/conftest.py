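"""Shared fixtures: toy complexes, ligandomes and screen configurations."""

from __future__ import annotations

import json

import pytest

from pmhclens import assign_roles, load_structure
from pmhclens.synthetic import (
    ContactSpec,
    LigandomePlan,
    PlantedPeptide,
    ToyComplexPlan,
    generate_ligandome,
    generate_toy_complex,
)

# NY-ESO-1 157-165 (C9V): the study's target peptide, Met4-Trp5 bulge
TARGET = "SLLMWITQV"


@pytest.fixture(scope="session")
def bridge_plan() -> ToyComplexPlan:
    """Toy with one constructed H-bond and one constructed salt bridge."""
    return ToyComplexPlan(
        designed_angle=0.0,
        designed_contacts=[
            ContactSpec(5, "OG", "peptide", 5, "O", 2.8, "SER", "ALA"),
            ContactSpec(23, "NZ", "peptide", 7, "OE1", 3.5, "LYS", "GLU"),
        ],
    )


@pytest.fixture(scope="session")
def bridge_complex(tmp_path_factory, bridge_plan):
    """(annotated structure, manifest) for the polar-bridge toy."""
    out = tmp_path_factory.mktemp("bridge_toy")
    pdb, manifest = generate_toy_complex(bridge_plan, out)
    s = assign_roles(load_structure(pdb))
    return s, json.loads(manifest.read_text()), pdb


@pytest.fixture(scope="session")
def mhc_complex(tmp_path_factory):
    """Toy with binder, peptide and an MHC-like flanking chain."""
    plan = ToyComplexPlan(
        designed_angle=40.0,
        include_mhc=True,
        designed_contacts=[
            ContactSpec(9, "OG", "peptide", 6, "O", 2.8, "SER", "ALA"),
            ContactSpec(25, "NZ", "mhc", 21, "OE1", 3.4, "LYS", "GLU"),
        ],
    )
    out = tmp_path_factory.mktemp("mhc_toy")
    pdb, manifest = generate_toy_complex(plan, out)
    # the toy groove is far shorter than a real class I heavy chain, so the
    # size heuristic cannot find it; a hint stands in for the real-size signal
    s = assign_roles(load_structure(pdb), hints={"M": "mhc_heavy"})
    return s, json.loads(manifest.read_text()), pdb


@pytest.fixture(scope="session")
def paper_shaped_ligandome(tmp_path_factory):
    """Ligandome emulating the study conditions: five distance-4 human
    neighbours plus motif-preserving entries at distances 5 and 6."""
    plan = LigandomePlan(
        n_background=500,
        planted=[PlantedPeptide(4, False) for _ in range(5)]
        + [PlantedPeptide(5, True), PlantedPeptide(6, True)],
        seed=11,
    )
    out = tmp_path_factory.mktemp("ligandome")
    tsv, manifest = generate_ligandome(plan, TARGET, out)
    return tsv, json.loads(manifest.read_text())
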