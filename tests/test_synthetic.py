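"""Generators: planted ground truth, determinism, feasibility checks."""

import json

import numpy as np
import pytest

from pmhclens import assign_roles, load_structure
from pmhclens.screen import Ligandome, ScreenConfig, ScreenError, run_screen
from pmhclens.synthetic import (
    ContactSpec,
    LigandomePlan,
    PlanError,
    PlantedPeptide,
    ToyComplexPlan,
    generate_ligandome,
    generate_pae,
    generate_toy_complex,
)

TARGET = "SLLMWITQV"


def _hamming(a, b):
    return sum(1 for x, y in zip(a, b) if x != y)


class TestLigandomeGenerator:
    def test_planted_distances_and_motif_status_exact(self, paper_shaped_ligandome):
        tsv, manifest = paper_shaped_ligandome
        for row in manifest["planted"]:
            assert _hamming(row["peptide"], manifest["target"]) == row["distance"]
            motif_ok = all(
                row["peptide"][p - 1] == manifest["target"][p - 1]
                for p in manifest["motif_positions"]
            )
            assert motif_ok == row["preserve_motif"]

    def test_background_obeys_distance_floor_and_breaks_motif(
        self, paper_shaped_ligandome
    ):
        tsv, manifest = paper_shaped_ligandome
        planted = {r["peptide"] for r in manifest["planted"]}
        lig = Ligandome.from_tsv(tsv)
        for pep in lig.entries["peptide"]:
            if pep in planted:
                continue
            assert _hamming(pep, manifest["target"]) >= manifest[
                "min_background_distance"
            ]
            assert any(
                pep[p - 1] != manifest["target"][p - 1]
                for p in manifest["motif_positions"]
            )

    def test_same_seed_is_byte_identical(self, tmp_path):
        plan = LigandomePlan(
            n_background=50, planted=[PlantedPeptide(4, False)], seed=3
        )
        t1, m1 = generate_ligandome(plan, TARGET, tmp_path / "a")
        t2, m2 = generate_ligandome(plan, TARGET, tmp_path / "b")
        assert t1.read_bytes() == t2.read_bytes()
        assert m1.read_bytes() == m2.read_bytes()

    def test_different_seed_changes_output(self, tmp_path):
        p1 = LigandomePlan(n_background=50, seed=1)
        p2 = LigandomePlan(n_background=50, seed=2)
        t1, _ = generate_ligandome(p1, TARGET, tmp_path / "a")
        t2, _ = generate_ligandome(p2, TARGET, tmp_path / "b")
        assert t1.read_bytes() != t2.read_bytes()

    def test_empty_plan_yields_unscreenable_ligandome(self, tmp_path):
        plan = LigandomePlan(n_background=0, planted=[], seed=0)
        tsv, _ = generate_ligandome(plan, TARGET, tmp_path)
        with pytest.raises(ScreenError, match="empty"):
            Ligandome.from_tsv(tsv)

    def test_infeasible_motif_preserving_distance_rejected(self):
        with pytest.raises(PlanError):
            LigandomePlan(
                planted=[PlantedPeptide(8, True)], min_background_distance=9
            )

    def test_planted_distance_at_background_floor_rejected(self):
        with pytest.raises(PlanError, match="floor"):
            LigandomePlan(planted=[PlantedPeptide(7, False)])

    def test_anchor_profile_shapes_background(self, tmp_path):
        plan = LigandomePlan(n_background=300, seed=5)
        tsv, _ = generate_ligandome(plan, TARGET, tmp_path)
        lig = Ligandome.from_tsv(tsv)
        p2 = lig.entries["peptide"].str[1]
        # position 2 anchors concentrate on Leu/Met/Ile
        assert p2.isin(list("LMI")).mean() > 0.9

    def test_screen_recovers_planted_panel_across_seeds(self, tmp_path):
        cfg = ScreenConfig(TARGET)
        for seed in range(30):
            plan = LigandomePlan(
                n_background=120,
                planted=[PlantedPeptide(4, False) for _ in range(5)]
                + [PlantedPeptide(5, True), PlantedPeptide(6, True)],
                seed=seed,
            )
            tsv, manifest_path = generate_ligandome(plan, TARGET, tmp_path / str(seed))
            manifest = json.loads(manifest_path.read_text())
            result = run_screen(Ligandome.from_tsv(tsv), cfg)
            assert sorted(h.peptide for h in result["panel"]) == manifest[
                "expected_panel"
            ]


class TestToyComplexGenerator:
    def test_designed_contacts_realized_within_tolerance(self, bridge_complex):
        _, manifest, _ = bridge_complex
        for c in manifest["designed_contacts"]:
            assert abs(c["distance"] - c["planned_distance"]) <= 0.05

    def test_manifest_contacts_match_recomputation(self, bridge_complex):
        s, manifest, _ = bridge_complex
        from pmhclens import contact_footprint

        _, _, pep_positions = contact_footprint(s, 4.5)
        truth = {pair[1] for pair in manifest["contact_pairs_4p5"]["B:P"]}
        assert pep_positions == truth

    def test_designed_bridge_detected(self, mhc_complex):
        s, manifest, _ = mhc_complex
        from pmhclens import detect_polar_bridges

        _, bridges = detect_polar_bridges(s)
        assert len(bridges) == 1
        assert bridges[0].min_distance == pytest.approx(3.4, abs=0.05)

    def test_same_seed_byte_identical(self, tmp_path, bridge_plan):
        p1, m1 = generate_toy_complex(bridge_plan, tmp_path / "a")
        p2, m2 = generate_toy_complex(bridge_plan, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
        assert m1.read_bytes() == m2.read_bytes()

    def test_infeasible_contact_geometry_rejected(self, tmp_path):
        plan = ToyComplexPlan(
            binder_height=40.0,
            designed_contacts=[
                ContactSpec(5, "OG", "peptide", 5, "O", 2.8, "SER", "ALA"),
            ],
        )
        with pytest.raises(PlanError, match="reach"):
            generate_toy_complex(plan, tmp_path)

    def test_bad_rigid_motion_rejected(self, tmp_path):
        plan = ToyComplexPlan(
            rigid_motion=(np.diag([1.0, 1.0, 2.0]), np.zeros(3))
        )
        with pytest.raises(PlanError, match="orthonormal"):
            generate_toy_complex(plan, tmp_path)

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(PlanError, match="angle"):
            ToyComplexPlan(designed_angle=120.0)


class TestPaeGenerator:
    def test_zero_noise_gives_exact_block_means(self, tmp_path):
        pae_path, manifest_path = generate_pae(
            {"B": 5, "T": 8},
            {("B", "B"): 2.0, ("T", "T"): 4.0, ("B", "T"): 7.25},
            noise_sd=0.0, seed=0, out_path=tmp_path / "p.json",
        )
        from pmhclens import interface_pae, load_pae

        p = load_pae(pae_path)
        assert interface_pae(p, "B", ["T"]) == pytest.approx(7.25, abs=1e-12)

    def test_noisy_manifest_matches_recomputation(self, tmp_path):
        pae_path, manifest_path = generate_pae(
            {"B": 10, "T": 12},
            {("B", "B"): 2.0, ("T", "T"): 4.0, ("B", "T"): 8.0},
            noise_sd=1.5, seed=9, out_path=tmp_path / "p.json",
        )
        manifest = json.loads(manifest_path.read_text())
        from pmhclens import interface_pae, load_pae

        p = load_pae(pae_path)
        assert interface_pae(p, "B", ["T"]) == pytest.approx(
            manifest["realized_interchain_means"]["B:T"], abs=1e-5
        )

    def test_single_chain_has_no_interface(self, tmp_path):
        pae_path, _ = generate_pae(
            {"B": 6}, {("B", "B"): 3.0}, noise_sd=0.0, seed=0,
            out_path=tmp_path / "p.json",
        )
        from pmhclens import interface_pae, load_pae
        from pmhclens.triage import TriageError

        p = load_pae(pae_path)
        with pytest.raises(TriageError):
            interface_pae(p, "B", [])

    def test_negative_noise_rejected(self, tmp_path):
        with pytest.raises(PlanError):
            generate_pae({"B": 2}, {("B", "B"): 1.0}, noise_sd=-1.0, seed=0,
                         out_path=tmp_path / "p.json")

    def test_missing_block_mean_rejected(self, tmp_path):
        with pytest.raises(PlanError, match="block mean"):
            generate_pae({"B": 2, "T": 2}, {("B", "B"): 1.0, ("T", "T"): 1.0},
                         noise_sd=0.0, seed=0, out_path=tmp_path / "p.json")
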