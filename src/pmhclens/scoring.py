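"""Off-target scoring: context likelihood differences between peptides.

A likelihood engine assigns each peptide a per-position cost (negative-log-
likelihood-like, lower = better fit to the fixed structural context of the
binder/MHC complex). The off-target score of a candidate is

    delta = cost(candidate) - cost(reference)

so delta(reference) = 0 and more negative deltas mean the candidate fits the
binding-constrained context at least as well as the reference — the
candidates most likely to be real off-targets.

Two engines are provided: a deterministic structure-weighted baseline
(per-position weights times a BLOSUM62-derived substitution dissimilarity to
the reference) and an adapter for external per-position log-probability
tables produced by an inverse-folding network.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .chemdata import AA_ALPHABET, blosum62_dissimilarity


class ScoringError(Exception):
    pass


class LikelihoodEngine(Protocol):
    """Deterministic per-position peptide cost under a fixed context."""

    name: str

    def score(self, peptide: str) -> tuple[np.ndarray, float]:
        """Return (per-position cost vector, total cost = its sum)."""
        ...


@dataclasses.dataclass
class OffTargetScore:
    peptide: str
    reference: str
    delta: float
    per_position_delta: np.ndarray
    engine_name: str


@dataclasses.dataclass
class BaselineEngineConfig:
    """Configuration for the structure-weighted baseline engine.

    position_weights: nonnegative, sum 1; by default proportional to the
    per-position peptide buried surface area of the interface fingerprint,
    so positions the binder actually engages dominate the score. A hotspot
    alternative concentrates all weight on the critical motif positions.
    """

    reference: str
    position_weights: np.ndarray
    dissimilarity: Optional[dict[tuple[str, str], float]] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.position_weights, float)
        if w.ndim != 1 or len(w) != len(self.reference):
            raise ScoringError("weights must match peptide length")
        if (w < 0).any():
            raise ScoringError("weights must be nonnegative")
        if not np.isclose(w.sum(), 1.0):
            if w.sum() <= 0:
                raise ScoringError("weights must have positive sum")
            w = w / w.sum()
        self.position_weights = w
        if self.dissimilarity is None:
            self.dissimilarity = blosum62_dissimilarity()
        for a in AA_ALPHABET:
            if abs(self.dissimilarity.get((a, a), 0.0)) > 1e-12:
                raise ScoringError(f"dissimilarity diagonal must be zero (d[{a},{a}])")


class BaselineEngine:
    """cost(p)[i] = w[i] * d(reference[i], p[i]); total = sum over positions."""

    def __init__(self, cfg: BaselineEngineConfig):
        self.cfg = cfg
        self.name = "baseline-bsa-weighted-blosum62"

    def score(self, peptide: str) -> tuple[np.ndarray, float]:
        ref = self.cfg.reference
        if len(peptide) != len(ref):
            raise ScoringError(f"peptide length {len(peptide)} != reference {len(ref)}")
        for c in peptide:
            if c not in AA_ALPHABET:
                raise ScoringError(f"invalid amino-acid letter {c!r}")
        costs = np.array([
            self.cfg.position_weights[i] * self.cfg.dissimilarity[(ref[i], peptide[i])]
            for i in range(len(ref))
        ])
        return costs, float(costs.sum())


def baseline_engine(cfg: BaselineEngineConfig) -> BaselineEngine:
    return BaselineEngine(cfg)


class ExternalTableEngine:
    """Adapter for an external inverse-folding engine's output.

    Consumes a TSV of per-position log-probabilities (rows = peptide
    positions 1..L, columns = the 20 amino acids); the cost of a peptide is
    the sum over positions of -log p(aa at position). The network itself is
    never run here — only its exported table is read.
    """

    def __init__(self, table_path: str | Path, name: str = "external-logprob-table"):
        df = pd.read_csv(table_path, sep="\t")
        missing = [a for a in AA_ALPHABET if a not in df.columns]
        if missing:
            raise ScoringError(f"log-probability table missing columns {missing}")
        self.logprobs = df[list(AA_ALPHABET)].to_numpy(float)
        self.name = name

    def score(self, peptide: str) -> tuple[np.ndarray, float]:
        if len(peptide) != len(self.logprobs):
            raise ScoringError(
                f"peptide length {len(peptide)} != table rows {len(self.logprobs)}"
            )
        idx = [AA_ALPHABET.index(c) for c in peptide]
        costs = -self.logprobs[np.arange(len(peptide)), idx]
        return costs, float(costs.sum())


def weights_from_bsa(per_position_bsa: dict[int, float], length: int) -> np.ndarray:
    """Position weights proportional to per-position peptide burial."""
    w = np.array([per_position_bsa.get(i + 1, 0.0) for i in range(length)], float)
    if w.sum() <= 0:
        raise ScoringError("peptide has no buried surface; cannot derive weights")
    return w / w.sum()


def hotspot_weights(positions: Sequence[int], length: int) -> np.ndarray:
    """Binary weights on the critical motif positions (e.g. {4, 5})."""
    w = np.zeros(length)
    for p in positions:
        w[p - 1] = 1.0
    return w / w.sum()


def score_candidate(
    candidate: str, reference: str, engine: LikelihoodEngine
) -> OffTargetScore:
    """delta = engine cost(candidate) - engine cost(reference)."""
    if len(candidate) != len(reference):
        raise ScoringError("candidate and reference must have equal length")
    try:
        cand_pos, cand_total = engine.score(candidate)
        ref_pos, ref_total = engine.score(reference)
    except ScoringError:
        raise
    except Exception as exc:   # engine contract: propagate with engine name
        raise ScoringError(f"engine {engine.name!r} failed: {exc}") from exc
    return OffTargetScore(
        peptide=candidate,
        reference=reference,
        delta=cand_total - ref_total,
        per_position_delta=cand_pos - ref_pos,
        engine_name=engine.name,
    )


def rank_panel(
    panel: Sequence[str], reference: str, engine: LikelihoodEngine
) -> pd.DataFrame:
    """Score every candidate and sort ascending by delta (ties: peptide).

    The head of the table holds the candidates most compatible with the
    structural context — the predicted true off-targets.
    """
    if not panel:
        raise ScoringError("panel is empty")
    scores = [score_candidate(p, reference, engine) for p in panel]
    df = pd.DataFrame({
        "peptide": [s.peptide for s in scores],
        "delta": [s.delta for s in scores],
        "engine": [s.engine_name for s in scores],
    })
    df["rank"] = df["delta"].rank(method="min").astype(int)
    return df.sort_values(["delta", "peptide"], kind="stable").reset_index(drop=True)
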