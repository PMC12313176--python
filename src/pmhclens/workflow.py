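"""End-to-end pipelines with reproducible plain-text reports.

Two entry points mirror the study's two computational arms:
``run_interface_report`` fingerprints one or more binder/pMHC structures
(BSA partition, contacts, polar bridges, docking geometry, cross-binder
footprint comparison) and ``run_offtarget_screen`` runs the ligandome
Hamming screen plus context-likelihood scoring of the candidate panel.
All outputs are TSV/JSON and embed the fully resolved configuration, so a
re-run with the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .geometry import GeometryError, docking_report
from .interface import (
    DEFAULT_CONTACT_CUTOFF,
    DEFAULT_HB_CUTOFF,
    DEFAULT_SB_CUTOFF,
    compare_footprints,
    fingerprint,
)
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE
from .scoring import (
    BaselineEngineConfig,
    ExternalTableEngine,
    baseline_engine,
    hotspot_weights,
    rank_panel,
)
from .screen import Ligandome, ScreenConfig, hits_to_frame, run_screen
from .structures import StructureError, assign_roles, load_structure


class WorkflowError(Exception):
    pass


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters for one pipeline run; embedded in every report."""

    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    probe: float = DEFAULT_PROBE
    n_points: int = DEFAULT_N_POINTS
    hb_cutoff: float = DEFAULT_HB_CUTOFF
    sb_cutoff: float = DEFAULT_SB_CUTOFF
    motif_positions: tuple[int, ...] = (4, 5)
    hotspot_positions: tuple[int, ...] = (1, 4, 5)
    organism_filter: str = "human"
    engine: str = "baseline"          # baseline | external
    engine_table: Optional[str] = None
    ipae_threshold: float = 10.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return d


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, WorkflowError):
                raise WorkflowError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


def run_interface_report(
    structure_paths: Sequence[str | Path],
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
    hints: Optional[dict[str, dict[str, str]]] = None,
) -> dict:
    """Fingerprint + docking geometry for each structure; comparison when >=2.

    ``hints`` optionally maps structure stem -> chain-role hints. Writes
    ``<stem>.fingerprint.json`` per structure, ``comparison.tsv`` when at
    least two structures are given, and ``interface_report.json`` with the
    resolved configuration. Returns the report dict.
    """
    cfg = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hints = hints or {}

    fingerprints = []
    geometries = {}
    for path in structure_paths:
        path = Path(path)
        with _stage(f"load+annotate {path.name}"):
            s = assign_roles(load_structure(path), hints.get(path.stem))
        with _stage(f"fingerprint {path.name}"):
            fp = fingerprint(
                s,
                cutoff=cfg.contact_cutoff,
                probe=cfg.probe,
                n_points=cfg.n_points,
                hb_cutoff=cfg.hb_cutoff,
                sb_cutoff=cfg.sb_cutoff,
            )
            fp.to_json(out_dir / f"{path.stem}.fingerprint.json")
            fingerprints.append(fp)
        try:
            geom = docking_report(s, fp=fp, cutoff=cfg.contact_cutoff)
            geometries[path.stem] = {
                "docking_angle": round(geom.docking_angle, 3),
                "convention_id": geom.convention_id,
                "groove_axis": [round(float(x), 6) for x in geom.groove_axis],
                "binder_axis": [round(float(x), 6) for x in geom.binder_axis],
                "binder_axis_fallback": geom.binder_axis_fallback,
            }
        except (GeometryError, StructureError) as exc:
            # e.g. a complex without an MHC chain has no platform plane;
            # the report still carries the fingerprint
            geometries[path.stem] = {"error": str(exc)}

    report: dict = {
        "config": cfg.to_dict(),
        "structures": [fp.source_id for fp in fingerprints],
        "fingerprints": {fp.source_id: fp.to_dict() for fp in fingerprints},
        "docking_geometry": geometries,
    }
    if len(fingerprints) >= 2:
        with _stage("compare footprints"):
            shared, table = compare_footprints(fingerprints)
            table.to_csv(out_dir / "comparison.tsv", sep="\t", index=False)
            report["shared_mhc_residues"] = sorted(shared)
            report["n_shared_mhc_residues"] = len(shared)
    (out_dir / "interface_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def run_offtarget_screen(
    ligandome_path: str | Path,
    target: str,
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
    position_weights=None,
) -> dict:
    """Rank the ligandome, select the candidate panel, score it.

    Writes ``ranking.tsv``, ``panel.tsv``, ``scores.tsv`` and
    ``screen_summary.json``. The scoring engine is the structure-weighted
    baseline unless the config names an external log-probability table.
    Position weights default to hotspot weights on the motif positions when
    no per-position burial vector is supplied.
    """
    cfg = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("load ligandome"):
        lig = Ligandome.from_tsv(ligandome_path)
    with _stage("screen"):
        scfg = ScreenConfig(
            target_peptide=target,
            motif_positions=frozenset(cfg.motif_positions),
            hotspot_positions=frozenset(cfg.hotspot_positions),
            organism_filter=cfg.organism_filter,
        )
        result = run_screen(lig, scfg)
    hits_to_frame(result["ranking"]).to_csv(out_dir / "ranking.tsv", sep="\t", index=False)
    panel = result["panel"]
    hits_to_frame(panel).to_csv(out_dir / "panel.tsv", sep="\t", index=False) \
        if panel else (out_dir / "panel.tsv").write_text(
            "peptide\tsource_protein\torganism\tdistance\tselected_by\n"
        )

    scores_table = None
    if panel:
        with _stage("score panel"):
            if cfg.engine == "external":
                if not cfg.engine_table:
                    raise WorkflowError("external engine requires engine_table")
                engine = ExternalTableEngine(cfg.engine_table)
            else:
                weights = (
                    position_weights
                    if position_weights is not None
                    else hotspot_weights(cfg.motif_positions, len(target))
                )
                engine = baseline_engine(
                    BaselineEngineConfig(reference=target, position_weights=weights)
                )
            scores_table = rank_panel([h.peptide for h in panel], target, engine)
            scores_table.to_csv(out_dir / "scores.tsv", sep="\t", index=False)

    summary = {
        "config": cfg.to_dict(),
        "target": target,
        "ligandome_size": len(lig),
        "counts": {
            "min_distance": len(result["min_distance_set"]),
            "motif_match": len(result["motif_set"]),
            "panel": len(panel),
        },
        "min_distance": (
            min(h.distance for h in result["min_distance_set"])
            if result["min_distance_set"] else None
        ),
        "panel": [dataclasses.asdict(h) for h in panel],
        "top_scored": (
            scores_table.iloc[0]["peptide"] if scores_table is not None else None
        ),
    }
    (out_dir / "screen_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
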