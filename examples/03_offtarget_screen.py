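"""Run the Hamming-distance off-target screen and score the panel.

Generates a synthetic HLA-A*02-like 9-mer ligandome around the NY-ESO-1
157-165 (C9V) target peptide SLLMWITQV with planted neighbours: five human
peptides at Hamming distance 4, plus motif-preserving peptides at distances
5 and 6 that keep the critical Met4-Trp5 bulge. The screen recovers the
7-candidate panel and the baseline engine ranks it by structural-context
compatibility.
"""

import tempfile
from pathlib import Path

from pmhclens.screen import Ligandome, ScreenConfig, run_screen
from pmhclens.scoring import (
    BaselineEngineConfig, baseline_engine, hotspot_weights, rank_panel,
)
from pmhclens.synthetic import LigandomePlan, PlantedPeptide, generate_ligandome

TARGET = "SLLMWITQV"

plan = LigandomePlan(
    n_background=500,
    planted=[PlantedPeptide(4, False) for _ in range(5)]
    + [PlantedPeptide(5, True), PlantedPeptide(6, True)],
    seed=1,
)

with tempfile.TemporaryDirectory() as tmp:
    tsv, _ = generate_ligandome(plan, TARGET, Path(tmp))
    lig = Ligandome.from_tsv(tsv)
    result = run_screen(lig, ScreenConfig(TARGET))

print(f"ligandome size: {len(lig)}")
print(f"minimum human Hamming distance: "
      f"{min(h.distance for h in result['min_distance_set'])}")
print(f"candidates at the minimum: {len(result['min_distance_set'])}")
print(f"motif-restricted additions: {len(result['motif_set'])}")
print(f"panel size: {len(result['panel'])}")

engine = baseline_engine(BaselineEngineConfig(
    reference=TARGET, position_weights=hotspot_weights([4, 5], 9),
))
ranked = rank_panel([h.peptide for h in result["panel"]], TARGET, engine)
print("\npanel ranked by off-target score (most negative = most compatible):")
print(ranked.to_string(index=False))

# Candidates preserving the Met4-Trp5 hotspot motif score 0 under hotspot
# weights (indistinguishable from the target at the positions the binder
# grips) and head the ranking: those are the predicted real off-targets.
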