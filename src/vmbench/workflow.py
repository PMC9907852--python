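"""End-to-end benchmark orchestration.

One call runs the whole loop for a grid of cells: generate the ecology,
synthesize the reference universe, simulate amplicon and WGS runs at the
requested depths, classify each run against every scenario database
(complete, rank-incomplete DB1/DB2/DB3, and abundance-representation
subsets), score each cell, and compare the two sequencing modes. All
randomness flows from one master seed through deterministically spawned
child seeds, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from vmbench._errors import VmbenchError
from vmbench.classify import (
    RANKS,
    ClassificationResult,
    build_kmer_index,
    classify_readset,
    import_abundance_table,
)
from vmbench.ecology import EcologyParams, VirtualMicrobiome, generate_ecology
from vmbench.evaluate import (
    EvaluationReport,
    evaluation_report,
    method_overlap,
    _truth_taxa,
)
from vmbench.readsim import ReadSimConfig, simulate_reads
from vmbench.refdb import (
    ReferenceDatabase,
    ScenarioSpec,
    build_representation_scenario,
    make_incomplete_db,
)
from vmbench.universe import UniverseSpec, bind_ecology_to_universe, generate_universe

logger = logging.getLogger("vmbench")

__all__ = ["BenchmarkConfig", "run_benchmark", "audit"]


@dataclass
class BenchmarkConfig:
    """Everything one benchmark run needs.

    ``scenarios`` may contain "complete", "DB1" (half the families
    removed), "DB2" (half the genera), "DB3" (half the species), "repr50"
    and "repr25" (family subsets retaining ~50% / ~25% of community
    abundance). ``depths`` maps mode to the read-pair counts to simulate.
    """

    ecology: EcologyParams = field(default_factory=EcologyParams)
    universe: UniverseSpec | None = None
    scenarios: list[str] = field(
        default_factory=lambda: ["complete", "DB1", "DB2", "DB3"])
    depths: dict[str, list[int]] = field(
        default_factory=lambda: {"amplicon": [100_000, 50_000],
                                 "wgs": [60_000, 20_000]})
    ranks: tuple[str, ...] = RANKS
    community_index: int = 0
    kmer_k: int = 31
    min_hits: int = 10
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_json_dict(self) -> dict:
        d = asdict(self)
        if self.universe is not None:
            d["universe"]["primers"] = {
                "forward": self.universe.primers.forward,
                "reverse": self.universe.primers.reverse,
            }
        return d


def _scenario_databases(
    name: str, vm: VirtualMicrobiome, db: ReferenceDatabase,
    rng: np.random.Generator,
) -> list[tuple[str, ReferenceDatabase, ScenarioSpec]]:
    """Expand a scenario name into concrete (label, database, manifest)."""
    if name == "complete":
        spec = ScenarioSpec(1.0, "complete", "none", [])
        return [("complete", db, spec)]
    if name in ("DB1", "DB2", "DB3"):
        level = {"DB1": "family", "DB2": "genus", "DB3": "species"}[name]
        reduced, spec = make_incomplete_db(db, level, 0.5, rng)
        return [(name, reduced, spec)]
    if name in ("repr50", "repr25"):
        target = 0.5 if name == "repr50" else 0.25
        out = []
        for reduced, spec in build_representation_scenario(vm, db, target):
            out.append((f"{name}{spec.variant}", reduced, spec))
        return out
    raise VmbenchError(f"unknown scenario {name!r}")


def run_benchmark(config: BenchmarkConfig,
                  outdir: str | Path) -> dict[str, EvaluationReport]:
    """Run the full grid and write per-cell reports plus summaries.

    Returns the evaluation reports keyed by "scenario/mode/depth". Cells
    that fail are logged and skipped; the rest of the grid continues.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seed_ecology, seed_universe, seed_scenarios, seed_reads = master.spawn(4)

    logger.info("generating ecology (%d species, %d communities)",
                config.ecology.n_species, config.ecology.n_communities)
    vm = generate_ecology(config.ecology,
                          np.random.default_rng(seed_ecology))
    uspec = config.universe or UniverseSpec.matching(vm)
    logger.info("generating reference universe (%d families)", uspec.n_families)
    db_16s, db_gen, taxonomy = generate_universe(
        uspec, np.random.default_rng(seed_universe))
    vm = bind_ecology_to_universe(vm, taxonomy)
    vm.write(outdir / "microbiome")

    mode_db = {"amplicon": db_16s, "wgs": db_gen}
    scenario_rng = np.random.default_rng(seed_scenarios)
    # same removal choices applied to both markers: spawn one rng per name
    scenario_cells: dict[str, dict[str, tuple[ReferenceDatabase, ScenarioSpec]]] = {}
    for name in config.scenarios:
        state = scenario_rng.bit_generator.state
        for mode, db in mode_db.items():
            scenario_rng.bit_generator.state = state  # same draws per marker
            for label, reduced, spec in _scenario_databases(
                    name, vm, db, scenario_rng):
                scenario_cells.setdefault(label, {})[mode] = (reduced, spec)

    reads_rng = np.random.default_rng(seed_reads)
    reports: dict[str, EvaluationReport] = {}
    results_by_cell: dict[tuple[str, int], dict[str, ClassificationResult]] = {}
    overlap_rows: list[dict] = []

    for mode, depths in config.depths.items():
        db = mode_db[mode]
        for depth_idx, depth in enumerate(depths):
            if mode == "amplicon":
                sim = ReadSimConfig.amplicon(total_reads=depth)
            else:
                sim = ReadSimConfig.wgs(total_reads=depth)
            logger.info("simulating %s reads, depth %d", mode, depth)
            rs = simulate_reads(vm, config.community_index, db, sim,
                                rng=reads_rng)
            for label, per_mode in scenario_cells.items():
                if mode not in per_mode:
                    continue
                reduced, spec = per_mode[mode]
                cell = f"{label}/{mode}/{depth}"
                try:
                    index = build_kmer_index(reduced, k=config.kmer_k)
                    result = classify_readset(rs, index,
                                              min_hits=config.min_hits)
                    report = evaluation_report(
                        vm, rs, result, scenario=label,
                        ranks=config.ranks,
                        community_index=config.community_index)
                    report.metadata.update({
                        "config_hash": config.config_hash(),
                        "seed": config.seed,
                        "scenario_manifest": asdict(spec),
                    })
                except VmbenchError as exc:
                    logger.error("cell %s failed: %s", cell, exc)
                    continue
                stem = f"{label}_{mode}_{depth}"
                report.write(outdir / "reports", stem)
                reports[cell] = report
                results_by_cell.setdefault((label, depth_idx), {})[mode] = result

    for (label, depth_idx), per_mode in sorted(results_by_cell.items()):
        if len(per_mode) < 2:
            continue
        for rank in config.ranks:
            truth = _truth_taxa(vm, config.community_index, rank)
            ov = method_overlap(per_mode["amplicon"], per_mode["wgs"],
                                truth, rank)
            overlap_rows.append({
                "scenario": label, "depth_index": depth_idx, "rank": rank,
                "overlap_pct": ov.overlap_pct,
                "fp_in_overlap_pct": ov.fp_in_overlap_pct,
                "exclusive_tp_16s": ov.exclusive_tp_a,
                "exclusive_tp_wgs": ov.exclusive_tp_b,
            })

    if overlap_rows:
        pd.DataFrame(overlap_rows).to_csv(
            outdir / "overlap.tsv", sep="\t", index=False,
            float_format="%.6g")
    if reports:
        summary = pd.concat([r.to_long_frame() for r in reports.values()],
                            ignore_index=True)
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
    (outdir / "run.json").write_text(json.dumps({
        "config": config.to_json_dict(),
        "config_hash": config.config_hash(),
        "cells": sorted(reports),
    }, indent=2, sort_keys=True))
    return reports


def audit(path_a: str | Path, path_b: str | Path,
          ranks: tuple[str, ...] = ("genus",),
          dialect: str = "generic_tsv",
          truth_taxa: dict[str, set[str]] | None = None) -> pd.DataFrame:
    """Compare two externally produced abundance tables.

    Computes the per-rank overlap statistics between the two tables'
    detected taxa; when truth taxa are supplied (per rank), the false
    share of the overlap and exclusive true positives are filled in too.
    """
    res_a = import_abundance_table(path_a, dialect=dialect)
    res_b = import_abundance_table(path_b, dialect=dialect)
    rows = []
    for rank in ranks:
        if rank not in res_a.profiles or rank not in res_b.profiles:
            raise VmbenchError(f"rank {rank!r} absent from an imported table")
        truth = (truth_taxa or {}).get(rank, set())
        ov = method_overlap(res_a, res_b, truth, rank)
        rows.append({
            "rank": rank,
            "overlap_pct": ov.overlap_pct,
            "fp_in_overlap_pct": ov.fp_in_overlap_pct if truth else None,
            "exclusive_tp_a": ov.exclusive_tp_a if truth else None,
            "exclusive_tp_b": ov.exclusive_tp_b if truth else None,
            "n_a": ov.n_a,
            "n_b": ov.n_b,
        })
    return pd.DataFrame(rows)
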