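"""Design triage by interface predicted aligned error (iPAE).

iPAE summarizes a structure predictor's confidence in the relative placement
of residues across a binder/target interface: the mean of the symmetrized
predicted-aligned-error matrix over inter-chain residue pairs, in Angstroms.
Designs below a confidence threshold (10.0 A by convention, strict less-than)
pass; a scaffold is a "hit" when at least one of its designs passes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_IPAE_THRESHOLD = 10.0


class TriageError(Exception):
    pass


@dataclasses.dataclass
class PaeMatrix:
    values: np.ndarray                      # n x n expected position errors, A
    chain_spans: dict[str, tuple[int, int]]  # half-open 0-based index ranges

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise TriageError(f"PAE matrix must be square, got {v.shape}")
        if (v < 0).any():
            raise TriageError("PAE values must be nonnegative")
        self.values = v
        n = v.shape[0]
        covered = sorted(self.chain_spans.values())
        flat = [i for start, stop in covered for i in range(start, stop)]
        if flat != list(range(n)):
            raise TriageError(
                f"chain spans {self.chain_spans} do not partition 0..{n}"
            )


@dataclasses.dataclass
class DesignRecord:
    design_id: str
    scaffold_id: str
    ipae: float
    passes: bool = False


def load_pae(
    path: str | Path, chain_lengths: Optional[dict[str, int]] = None
) -> PaeMatrix:
    """Read an AlphaFold-dialect PAE JSON plus chain spans.

    Accepts ``{"predicted_aligned_error": [[...]]}`` or the list-wrapped
    variant. Chain spans come from ``chain_lengths`` (ordered mapping
    chain -> length) or from a ``<path>.chains.json`` sidecar with the same
    mapping; without either the call fails asking for spans.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        doc = doc[0]
    key = next(
        (k for k in ("predicted_aligned_error", "pae") if k in doc), None
    )
    if key is None:
        raise TriageError(f"{path.name}: no predicted_aligned_error array")
    values = np.asarray(doc[key], float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise TriageError(f"{path.name}: PAE array is not square ({values.shape})")
    if chain_lengths is None:
        sidecar = path.with_name(path.name + ".chains.json")
        if sidecar.exists():
            with open(sidecar) as fh:
                chain_lengths = json.load(fh)["chain_lengths"]
        elif "chain_lengths" in doc:
            chain_lengths = doc["chain_lengths"]
        else:
            raise TriageError(
                f"{path.name}: chain spans unknown; provide chain_lengths or a "
                f"{sidecar.name} sidecar"
            )
    spans: dict[str, tuple[int, int]] = {}
    start = 0
    for chain, length in chain_lengths.items():
        spans[chain] = (start, start + int(length))
        start += int(length)
    return PaeMatrix(values=values, chain_spans=spans)


def interface_pae(
    p: PaeMatrix,
    binder_chain: str,
    target_chains: Sequence[str],
    pair_selector: str = "all_interchain",
    contacts: Optional[Sequence[tuple[int, int]]] = None,
) -> float:
    """Mean symmetrized PAE over binder <-> target residue pairs.

    Each unordered inter-chain pair (i, j) contributes
    (v[i,j] + v[j,i]) / 2 once, so the result is invariant to swapping the
    binder and target labels. ``contact_pairs`` restricts the average to an
    explicit pair list (e.g. from an interface footprint).
    """
    for chain in [binder_chain, *target_chains]:
        if chain not in p.chain_spans:
            raise TriageError(f"chain {chain!r} not in PAE spans {list(p.chain_spans)}")
    if pair_selector not in ("all_interchain", "contact_pairs"):
        raise TriageError(f"unknown pair selector {pair_selector!r}")
    sym = 0.5 * (p.values + p.values.T)
    if pair_selector == "contact_pairs":
        if not contacts:
            raise TriageError("contact_pairs selector requires a nonempty pair list")
        vals = [sym[i, j] for i, j in contacts]
        return float(np.mean(vals))
    b0, b1 = p.chain_spans[binder_chain]
    blocks = []
    for tc in target_chains:
        t0, t1 = p.chain_spans[tc]
        blocks.append(sym[b0:b1, t0:t1].ravel())
    if not blocks or sum(len(b) for b in blocks) == 0:
        raise TriageError("no inter-chain pairs selected")
    return float(np.concatenate(blocks).mean())


def triage(
    records: Sequence[dict | DesignRecord],
    threshold: float = DEFAULT_IPAE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank designs by iPAE and summarize scaffolds.

    A design passes iff ipae < threshold (strict: "under" the threshold);
    a scaffold is a hit iff at least one of its designs passes. Returns
    (ranked designs, scaffold summary) tables.
    """
    if threshold <= 0:
        raise TriageError("threshold must be positive")
    rows = []
    for r in records:
        if isinstance(r, DesignRecord):
            r = {"design_id": r.design_id, "scaffold_id": r.scaffold_id, "ipae": r.ipae}
        rows.append({
            "design_id": str(r["design_id"]),
            "scaffold_id": str(r["scaffold_id"]),
            "ipae": float(r["ipae"]),
        })
    designs = pd.DataFrame(rows)
    designs["passes"] = designs["ipae"] < threshold
    designs = designs.sort_values(
        ["ipae", "design_id"], kind="stable"
    ).reset_index(drop=True)
    summary = (
        designs.groupby("scaffold_id", sort=True)
        .agg(n_designs=("design_id", "size"), n_pass=("passes", "sum"))
        .reset_index()
    )
    summary["pass_rate"] = summary["n_pass"] / summary["n_designs"]
    summary["hit"] = summary["n_pass"] >= 1
    return designs, summary
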