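"""Hamming-distance off-target screen over an MHC ligandome.

Given a target peptide (here typically the NY-ESO-1 157-165 C9V 9-mer,
SLLMWITQV) and a table of equal-length MHC-presented peptides, rank every
peptide by Hamming distance to the target, keep the human-origin peptides at
the minimum observed distance, add a second motif-restricted pass that keeps
any human peptide preserving the critical hotspot motif (positions 4-5, the
Met-Trp bulge) regardless of overall distance, and assemble the union as the
off-target candidate panel.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemdata import AA_ALPHABET

DEFAULT_MOTIF_POSITIONS = frozenset({4, 5})
DEFAULT_HOTSPOT_POSITIONS = frozenset({1, 4, 5})


class ScreenError(Exception):
    pass


@dataclasses.dataclass
class Ligandome:
    """Equal-length MHC-presented peptides with source annotations."""

    entries: pd.DataFrame      # columns: peptide, source_protein, organism
    allele: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        df = self.entries
        required = {"peptide", "source_protein", "organism"}
        missing = required - set(df.columns)
        if missing:
            raise ScreenError(f"ligandome table missing columns {sorted(missing)}")
        if len(df) == 0:
            raise ScreenError("ligandome is empty")
        peptides = df["peptide"].astype(str)
        lengths = peptides.str.len().unique()
        if len(lengths) != 1:
            raise ScreenError(f"mixed peptide lengths {sorted(lengths)}")
        self.length = int(lengths[0])
        bad = peptides[~peptides.str.fullmatch(f"[{AA_ALPHABET}]+")]
        if len(bad):
            raise ScreenError(f"non-standard peptide letters, e.g. {bad.iloc[0]!r}")
        if peptides.duplicated().any():
            dup = peptides[peptides.duplicated()].iloc[0]
            raise ScreenError(f"duplicate peptide entries, e.g. {dup!r}")
        self.entries = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path, allele: str = "") -> "Ligandome":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] == 1 and "," in df.columns[0]:
            df = pd.read_csv(path, sep=",")
        missing = {"peptide", "source_protein", "organism"} - set(df.columns)
        if missing:
            raise ScreenError(f"ligandome table missing columns {sorted(missing)}")
        return cls(entries=df[["peptide", "source_protein", "organism"]], allele=allele)

    @classmethod
    def from_fasta(cls, path: str | Path, allele: str = "") -> "Ligandome":
        """Peptide-only input; organism filtering is disabled downstream."""
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        warnings.warn(
            "FASTA ligandome has no organism annotations; the organism filter "
            "will match nothing unless disabled", stacklevel=2,
        )
        df = pd.DataFrame({
            "peptide": [str(r.seq).upper() for r in records],
            "source_protein": [r.id for r in records],
            "organism": ["" for _ in records],
        })
        return cls(entries=df, allele=allele)

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class ScreenConfig:
    target_peptide: str
    motif_positions: frozenset[int] = DEFAULT_MOTIF_POSITIONS
    hotspot_positions: frozenset[int] = DEFAULT_HOTSPOT_POSITIONS
    distance_rule: str = "minimum_observed"      # or fixed_threshold
    fixed_threshold: Optional[int] = None
    organism_filter: str = "human"

    def __post_init__(self) -> None:
        self.target_peptide = self.target_peptide.upper()
        n = len(self.target_peptide)
        if any(c not in AA_ALPHABET for c in self.target_peptide):
            raise ScreenError(f"target peptide {self.target_peptide!r} has invalid letters")
        if any(not 1 <= p <= n for p in self.motif_positions):
            raise ScreenError(f"motif positions must lie in 1..{n}")
        if self.distance_rule not in ("minimum_observed", "fixed_threshold"):
            raise ScreenError(f"unknown distance rule {self.distance_rule!r}")
        if self.distance_rule == "fixed_threshold" and self.fixed_threshold is None:
            raise ScreenError("fixed_threshold rule requires a threshold")


@dataclasses.dataclass
class HammingHit:
    peptide: str
    source_protein: str
    organism: str
    distance: int
    selected_by: str = "none"    # min_distance | motif_match | both | none

    @property
    def motif_match(self) -> bool:  # set by the screen, derived field
        return self.selected_by in ("motif_match", "both")


def hamming_distance(a: str, b: str) -> int:
    """Number of differing positions between two equal-length peptides."""
    if len(a) != len(b):
        raise ScreenError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y)


def _distance_vector(peptides: Sequence[str], target: str) -> np.ndarray:
    arr = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(peptides), len(target))
    tgt = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    return (arr != tgt).sum(axis=1).astype(int)


def rank_ligandome(lig: Ligandome, cfg: ScreenConfig) -> list[HammingHit]:
    """Every ligandome entry as a HammingHit, sorted by (distance, peptide)."""
    if lig.length != len(cfg.target_peptide):
        raise ScreenError(
            f"target length {len(cfg.target_peptide)} != ligandome length {lig.length}"
        )
    peptides = lig.entries["peptide"].tolist()
    distances = _distance_vector(peptides, cfg.target_peptide)
    hits = [
        HammingHit(
            peptide=p,
            source_protein=str(sp),
            organism=str(org),
            distance=int(d),
        )
        for p, sp, org, d in zip(
            peptides, lig.entries["source_protein"], lig.entries["organism"], distances
        )
    ]
    hits.sort(key=lambda h: (h.distance, h.peptide))
    return hits


def _organism_ok(hit: HammingHit, cfg: ScreenConfig) -> bool:
    return hit.organism.strip().lower() == cfg.organism_filter.strip().lower()


def select_min_distance(hits: Sequence[HammingHit], cfg: ScreenConfig) -> list[HammingHit]:
    """Organism-matching hits at the minimum observed (nonzero) distance.

    The minimum is computed over the organism-matching, non-identical subset,
    so a closer non-human peptide does not mask the human candidates. Under
    the fixed_threshold rule all organism-matching hits with
    0 < distance <= threshold are kept.
    """
    eligible = [h for h in hits if _organism_ok(h, cfg) and h.distance > 0]
    if not eligible:
        warnings.warn(
            f"no peptides match organism {cfg.organism_filter!r}; empty selection",
            stacklevel=2,
        )
        return []
    if cfg.distance_rule == "fixed_threshold":
        chosen = [h for h in eligible if h.distance <= cfg.fixed_threshold]
    else:
        dmin = min(h.distance for h in eligible)
        chosen = [h for h in eligible if h.distance == dmin]
    return [dataclasses.replace(h, selected_by="min_distance") for h in chosen]


def _matches_motif(peptide: str, cfg: ScreenConfig) -> bool:
    return all(peptide[p - 1] == cfg.target_peptide[p - 1] for p in cfg.motif_positions)


def motif_search(
    hits: Sequence[HammingHit],
    cfg: ScreenConfig,
    already_selected: Sequence[HammingHit] = (),
) -> list[HammingHit]:
    """Second pass: organism-matching hits preserving the hotspot motif.

    Keeps every non-identical hit exactly matching the target at all motif
    positions (default 4 and 5, the Met-Trp bulge), excluding hits already in
    the minimum-distance set.
    """
    taken = {h.peptide for h in already_selected}
    out = [
        dataclasses.replace(h, selected_by="motif_match")
        for h in hits
        if _organism_ok(h, cfg)
        and h.distance > 0
        and h.peptide not in taken
        and _matches_motif(h.peptide, cfg)
    ]
    return out


def assemble_panel(
    minset: Sequence[HammingHit], motifset: Sequence[HammingHit], cfg: ScreenConfig
) -> list[HammingHit]:
    """Union of the two selections with provenance, ordered (distance, peptide)."""
    by_peptide: dict[str, HammingHit] = {}
    for h in minset:
        by_peptide[h.peptide] = dataclasses.replace(h, selected_by="min_distance")
    for h in motifset:
        if h.peptide in by_peptide:
            by_peptide[h.peptide] = dataclasses.replace(
                by_peptide[h.peptide], selected_by="both"
            )
        else:
            by_peptide[h.peptide] = dataclasses.replace(h, selected_by="motif_match")
    panel = sorted(by_peptide.values(), key=lambda h: (h.distance, h.peptide))
    return panel


def run_screen(lig: Ligandome, cfg: ScreenConfig) -> dict:
    """Full screen: ranking, both selections, and the assembled panel."""
    hits = rank_ligandome(lig, cfg)
    minset = select_min_distance(hits, cfg)
    motifset = motif_search(hits, cfg, already_selected=minset)
    panel = assemble_panel(minset, motifset, cfg)
    return {
        "ranking": hits,
        "min_distance_set": minset,
        "motif_set": motifset,
        "panel": panel,
    }


def hits_to_frame(hits: Sequence[HammingHit]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(h) for h in hits])
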