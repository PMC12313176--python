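"""Hamming-distance ligandome screen against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pmhclens.chemdata import AA_ALPHABET
from pmhclens.screen import (
    HammingHit,
    Ligandome,
    ScreenConfig,
    ScreenError,
    assemble_panel,
    hamming_distance,
    motif_search,
    rank_ligandome,
    run_screen,
    select_min_distance,
)

TARGET = "SLLMWITQV"


def _lig(rows) -> Ligandome:
    return Ligandome(entries=pd.DataFrame(
        rows, columns=["peptide", "source_protein", "organism"]
    ))


def brute_force_screen(rows, cfg):
    """Independent exhaustive selection, written without the package logic."""
    scored = []
    for pep, prot, org in rows:
        d = sum(1 for a, b in zip(pep, cfg.target_peptide) if a != b)
        scored.append((pep, prot, org, d))
    human = [r for r in scored if r[2].lower() == cfg.organism_filter.lower() and r[3] > 0]
    minset = set()
    if human:
        dmin = min(r[3] for r in human)
        minset = {r[0] for r in human if r[3] == dmin}
    motifset = {
        r[0] for r in human
        if r[0] not in minset
        and all(r[0][p - 1] == cfg.target_peptide[p - 1] for p in cfg.motif_positions)
    }
    return minset, motifset


class TestHammingDistance:
    @pytest.mark.parametrize("a,b,d", [
        ("AAAAAAAAA", "AAAAAAAAA", 0),
        ("AAAAAAAAA", "AAAWAAAAV", 2),
        (TARGET, "SLLMWITQV", 0),
        (TARGET, "ALLMWITQA", 2),
    ])
    def test_known_pairs(self, a, b, d):
        assert hamming_distance(a, b) == d

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ScreenError, match="length"):
            hamming_distance("AAAA", "AAA")

    def test_metric_properties_on_seeded_triples(self):
        rng = np.random.default_rng(17)
        letters = np.array(list(AA_ALPHABET))
        for _ in range(1000):
            a, b, c = (
                "".join(letters[rng.integers(0, 20, 9)]) for _ in range(3)
            )
            dab, dba = hamming_distance(a, b), hamming_distance(b, a)
            assert dab == dba
            assert 0 <= dab <= 9
            assert hamming_distance(a, c) <= dab + hamming_distance(b, c)


class TestHammingHypothesis:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    peptide9 = st.text(alphabet=AA_ALPHABET, min_size=9, max_size=9)

    @settings(derandomize=True, max_examples=200)
    @given(peptide9, peptide9, peptide9)
    def test_metric_axioms(self, a, b, c):
        dab = hamming_distance(a, b)
        assert dab == hamming_distance(b, a)
        assert (dab == 0) == (a == b)
        assert hamming_distance(a, c) <= dab + hamming_distance(b, c)


class TestRanking:
    def test_target_itself_ranks_first_at_zero(self):
        lig = _lig([(TARGET, "self", "human"), ("AAAAAAAAA", "x", "human")])
        hits = rank_ligandome(lig, ScreenConfig(TARGET))
        assert hits[0].peptide == TARGET and hits[0].distance == 0

    def test_planted_neighbours_head_the_ranking_in_order(self):
        near2 = "SALMWITQA"   # distance 2
        near3a = "ALLMWITAA"  # distance 3
        near3b = "TLLMWITAA"  # distance 3, lexicographically after A...
        rows = [(near3b, "c", "human"), (near2, "a", "human"),
                (near3a, "b", "human"), ("KQWESNPRT", "bg", "human")]
        hits = rank_ligandome(_lig(rows), ScreenConfig(TARGET))
        assert [h.peptide for h in hits[:3]] == [near2, near3a, near3b]
        assert [h.distance for h in hits[:3]] == [2, 3, 3]

    def test_ranking_is_complete_and_loses_nothing(self, paper_shaped_ligandome):
        tsv, manifest = paper_shaped_ligandome
        lig = Ligandome.from_tsv(tsv)
        hits = rank_ligandome(lig, ScreenConfig(manifest["target"]))
        assert len(hits) == len(lig)
        assert sorted(h.peptide for h in hits) == sorted(lig.entries["peptide"])

    def test_length_mismatch_rejected(self):
        lig = _lig([("AAAAAAAAA", "x", "human")])
        cfg = ScreenConfig("AAAA", motif_positions=frozenset({1, 2}))
        with pytest.raises(ScreenError, match="length"):
            rank_ligandome(lig, cfg)

    def test_motif_positions_outside_target_rejected(self):
        with pytest.raises(ScreenError, match="motif"):
            ScreenConfig("AAAA")   # default motif {4,5} exceeds length 4


class TestSelection:
    def test_minimum_distance_subset(self):
        hits = [
            HammingHit("AALMWITQV", "p1", "human", 4),
            HammingHit("SAAMWITQA", "p2", "human", 4),
            HammingHit("AAAMWITAA", "p3", "human", 5),
        ]
        chosen = select_min_distance(hits, ScreenConfig(TARGET))
        assert {h.peptide for h in chosen} == {"AALMWITQV", "SAAMWITQA"}
        assert all(h.selected_by == "min_distance" for h in chosen)

    def test_nonhuman_minimum_does_not_mask_human_candidates(self):
        hits = [
            HammingHit("SLLMWITAA", "viral", "vaccinia virus", 2),
            HammingHit("AALMWITQA", "h1", "human", 4),
        ]
        chosen = select_min_distance(hits, ScreenConfig(TARGET))
        assert [h.peptide for h in chosen] == ["AALMWITQA"]

    def test_identical_target_excluded_from_candidates(self):
        hits = [
            HammingHit(TARGET, "self", "human", 0),
            HammingHit("AALMWITQA", "h1", "human", 3),
        ]
        chosen = select_min_distance(hits, ScreenConfig(TARGET))
        assert [h.peptide for h in chosen] == ["AALMWITQA"]

    def test_empty_after_organism_filter_warns(self):
        hits = [HammingHit("AALMWITQA", "x", "mouse", 3)]
        with pytest.warns(UserWarning, match="organism"):
            assert select_min_distance(hits, ScreenConfig(TARGET)) == []


class TestMotifSearch:
    def test_motif_preserving_distant_hit_selected(self):
        hit = HammingHit("AAAMWAAAA", "x", "human", 6)   # Met4-Trp5 intact
        out = motif_search([hit], ScreenConfig(TARGET))
        assert [h.peptide for h in out] == ["AAAMWAAAA"]
        assert out[0].selected_by == "motif_match"

    def test_partial_motif_not_selected(self):
        hit = HammingHit("AAAAWITQV", "x", "human", 4)   # Trp5 but not Met4
        assert motif_search([hit], ScreenConfig(TARGET)) == []

    def test_already_selected_hits_are_excluded(self):
        hit = HammingHit("SLAMWITAA", "x", "human", 3)
        out = motif_search([hit], ScreenConfig(TARGET), already_selected=[hit])
        assert out == []


class TestPanelAssembly:
    def test_disjoint_five_plus_two_gives_seven(self, paper_shaped_ligandome):
        tsv, manifest = paper_shaped_ligandome
        lig = Ligandome.from_tsv(tsv)
        result = run_screen(lig, ScreenConfig(manifest["target"]))
        assert len(result["min_distance_set"]) == 5
        assert len(result["motif_set"]) == 2
        assert len(result["panel"]) == 7
        assert sorted(h.peptide for h in result["panel"]) == manifest["expected_panel"]

    def test_overlap_marked_both(self):
        a = HammingHit("SLAMWITQA", "x", "human", 2, "min_distance")
        b = HammingHit("SLAMWITQA", "x", "human", 2, "motif_match")
        panel = assemble_panel([a], [b], ScreenConfig(TARGET))
        assert len(panel) == 1 and panel[0].selected_by == "both"

    def test_empty_motif_set_leaves_minset(self):
        a = HammingHit("AALMWITQA", "x", "human", 3, "min_distance")
        panel = assemble_panel([a], [], ScreenConfig(TARGET))
        assert [h.peptide for h in panel] == ["AALMWITQA"]

    def test_panel_order_is_distance_then_lexicographic(self):
        hits = [
            HammingHit("ZLLMWITQA", "x", "human", 5, "motif_match"),
            HammingHit("ALLMWITQA", "x", "human", 5, "motif_match"),
            HammingHit("AALMWITQV", "x", "human", 4, "min_distance"),
        ]
        panel = assemble_panel([hits[2]], hits[:2], ScreenConfig(TARGET))
        assert [h.peptide for h in panel] == [
            "AALMWITQV", "ALLMWITQA", "ZLLMWITQA"
        ]


class TestBruteForceEquivalence:
    def test_matches_exhaustive_filter_on_seeded_ligandomes(self):
        rng = np.random.default_rng(23)
        letters = np.array(list(AA_ALPHABET))
        cfg = ScreenConfig(TARGET)
        for trial in range(20):
            n = int(rng.integers(50, 500))
            peptides = set()
            while len(peptides) < n:
                peptides.add("".join(letters[rng.integers(0, 20, 9)]))
            rows = [
                (p, f"P{i}", "human" if rng.random() < 0.8 else "mouse")
                for i, p in enumerate(sorted(peptides))
            ]
            result = run_screen(_lig(rows), cfg)
            min_oracle, motif_oracle = brute_force_screen(rows, cfg)
            assert {h.peptide for h in result["min_distance_set"]} == min_oracle
            assert {h.peptide for h in result["motif_set"]} == motif_oracle


class TestLigandomeValidation:
    def test_mixed_lengths_rejected(self):
        with pytest.raises(ScreenError, match="length"):
            _lig([("AAAA", "x", "human"), ("AAAAAAAAA", "y", "human")])

    def test_duplicates_rejected(self):
        with pytest.raises(ScreenError, match="duplicate"):
            _lig([("AAAAAAAAA", "x", "human"), ("AAAAAAAAA", "y", "human")])

    def test_invalid_letters_rejected(self):
        with pytest.raises(ScreenError, match="letter"):
            _lig([("AAAAAAAAX", "x", "human")])

    def test_tsv_round_trip(self, tmp_path, paper_shaped_ligandome):
        tsv, _ = paper_shaped_ligandome
        lig = Ligandome.from_tsv(tsv)
        out = tmp_path / "copy.tsv"
        lig.to_tsv(out)
        again = Ligandome.from_tsv(out)
        assert again.entries.equals(lig.entries)

    def test_fasta_input_warns_about_missing_organism(self, tmp_path):
        fasta = tmp_path / "peps.fasta"
        fasta.write_text(">p1\nSLLMWITQV\n>p2\nAAAAAAAAA\n")
        with pytest.warns(UserWarning, match="organism"):
            lig = Ligandome.from_fasta(fasta)
        assert len(lig) == 2
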