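"""Scoring of classification output against virtual-microbiome ground truth.

All metrics keep their denominators distinct on purpose:

* **unsampled** -- % of truth taxa that received zero reads (a property of
  sampling depth and community evenness, before any database enters);
* **unidentified** -- % of sampled truth taxa none of whose reads matched
  anything in the database;
* **false positives** -- % of *detected* taxa absent from the truth;
* **true positives** -- % of *truth* taxa that were detected;
* **D** -- signed mean relative abundance error (1/N) * sum((a~ - a)/a)
  over taxa both detected and truly present;
* **trend detection** -- % of true abundance changes recovered, and % of
  reported changes that are spurious;
* **overlap** -- Jaccard-style agreement between two methods' detected
  sets, and how much of the agreement is false.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from vmbench._errors import InvalidParameterError, VmbenchError
from vmbench.classify import RANKS, ClassificationResult
from vmbench.ecology import VirtualMicrobiome, aggregate_abundance
from vmbench.readsim import ReadSet

__all__ = [
    "DetectionSets",
    "EvaluationReport",
    "TrendComparison",
    "OverlapReport",
    "detection_sets",
    "unsampled_fraction",
    "unidentified_fraction",
    "confusion_rates",
    "abundance_error_D",
    "trend_analysis",
    "method_overlap",
    "evaluation_report",
]


def _truth_taxa(vm: VirtualMicrobiome, community_index: int,
                rank: str) -> set[str]:
    matrix = aggregate_abundance(vm, rank)
    row = matrix.values[community_index]
    return {t for t, a in zip(matrix.taxon_ids, row) if a > 0}


def _ancestors_at(vm: VirtualMicrobiome, species: set[str],
                  rank: str) -> set[str]:
    if rank == "species":
        return set(species)
    if rank == "genus":
        return {vm.taxonomy.species_to_genus[sp] for sp in species}
    if rank == "family":
        return {vm.taxonomy.family_of_species(sp) for sp in species}
    raise InvalidParameterError(f"unknown rank {rank!r}")


@dataclass
class DetectionSets:
    """The four taxon sets every set-based metric is built from."""

    rank: str
    truth_taxa: set[str]
    detected_taxa: set[str]
    sampled_taxa: set[str]
    identified_taxa: set[str]

    def validate(self) -> None:
        if not self.identified_taxa <= self.sampled_taxa <= self.truth_taxa:
            raise InvalidParameterError(
                "expected identified <= sampled <= truth taxon sets"
            )


def detection_sets(vm: VirtualMicrobiome, community_index: int, rs: ReadSet,
                   result: ClassificationResult, rank: str) -> DetectionSets:
    """Assemble truth/detected/sampled/identified sets at one rank."""
    truth = _truth_taxa(vm, community_index, rank)
    sampled_species = rs.sampled_species()
    sampled = _ancestors_at(vm, sampled_species, rank) & truth
    if result.assignments is not None:
        identified_species = {
            p.species for p in rs.pairs
            if result.assignments.get(p.pair_id) is not None
            and result.assignments[p.pair_id].rank != "unclassified"
        }
        identified = _ancestors_at(vm, identified_species, rank) & sampled
    else:
        identified = set(sampled)
    detected = result.detected_taxa(rank)
    return DetectionSets(rank, truth, detected, sampled, identified)


def unsampled_fraction(vm: VirtualMicrobiome, allocated_counts: np.ndarray,
                       rank: str = "species", min_reads: int = 1) -> float:
    """% of truth taxa whose allocated read count falls below ``min_reads``.

    ``allocated_counts`` is the per-species allocation (post-redistribution
    for amplicon runs), aligned with ``vm.species_ids``. At genus or family
    rank a taxon counts as sampled if any member species was.
    """
    counts = np.asarray(allocated_counts)
    if counts.shape != (len(vm.species_ids),):
        raise InvalidParameterError(
            f"expected one count per species ({len(vm.species_ids)}), "
            f"got shape {counts.shape}"
        )
    sampled_species = {sp for sp, c in zip(vm.species_ids, counts)
                       if c >= min_reads}
    truth = _ancestors_at(vm, set(vm.species_ids), rank)
    sampled = _ancestors_at(vm, sampled_species, rank)
    return 100.0 * len(truth - sampled) / len(truth)


def unidentified_fraction(rs: ReadSet, result: ClassificationResult,
                          vm: VirtualMicrobiome,
                          rank: str = "species") -> float | None:
    """% of sampled truth taxa none of whose reads got any assignment.

    Needs per-read assignments; imported profiles return None
    (not computable) rather than raising.
    """
    if result.assignments is None:
        return None
    sampled_species = rs.sampled_species()
    identified_species = {
        p.species for p in rs.pairs
        if result.assignments[p.pair_id].rank != "unclassified"
    }
    sampled = _ancestors_at(vm, sampled_species, rank)
    identified = _ancestors_at(vm, identified_species, rank)
    if not sampled:
        return None
    return 100.0 * len(sampled - identified) / len(sampled)


def confusion_rates(ds: DetectionSets) -> tuple[float | None, float]:
    """(false-positive %, true-positive %).

    FP is the share of *detected* taxa not in the truth (None when nothing
    was detected); TP is the share of *truth* taxa detected.
    """
    if not ds.truth_taxa:
        raise InvalidParameterError("empty truth set")
    tp = 100.0 * len(ds.detected_taxa & ds.truth_taxa) / len(ds.truth_taxa)
    if not ds.detected_taxa:
        return None, tp
    fp = 100.0 * len(ds.detected_taxa - ds.truth_taxa) / len(ds.detected_taxa)
    return fp, tp


def abundance_error_D(truth_ab: dict[str, float],
                      est_ab: dict[str, float]) -> float | None:
    """Signed mean relative abundance error over detected truth taxa.

    D = (1/N) * sum over i of (a~_i - a_i) / a_i, where the sum runs over
    the N taxa that are both detected (a~ > 0) and truly present (a > 0);
    false positives have a = 0 and are excluded, which is the only reading
    under which the formula is defined. Returns None when N = 0.
    """
    evaluated = [t for t, est in est_ab.items()
                 if est > 0 and truth_ab.get(t, 0.0) > 0]
    if not evaluated:
        return None
    terms = [(est_ab[t] - truth_ab[t]) / truth_ab[t] for t in evaluated]
    return float(np.mean(terms))


@dataclass
class TrendComparison:
    """Per-taxon abundance-change signs in truth vs estimate."""

    actual_trends: dict[str, str]
    detected_trends: dict[str, str]
    detected_pct: float | None  # % of true changes recovered with right sign
    spurious_pct: float | None  # % of reported changes that are not real


def _sign_of_change(before: float, after: float, min_fold: float) -> str:
    if before == 0 and after == 0:
        return "unchanged"
    if before == 0:
        return "up"
    if after == 0:
        return "down"
    ratio = after / before
    if ratio > min_fold:
        return "up"
    if ratio < 1.0 / min_fold:
        return "down"
    return "unchanged"


def trend_analysis(truth_pair: tuple[dict[str, float], dict[str, float]],
                   est_pair: tuple[dict[str, float], dict[str, float]],
                   min_fold: float = 1.0) -> TrendComparison:
    """Compare abundance-change directions between truth and estimate.

    A taxon trends up/down when its after/before ratio exceeds ``min_fold``
    (default 1.0: any nonzero change counts, magnitude ignored). Taxon
    universes are aligned on the union; absence means abundance 0.
    ``detected_pct`` is the share of truly changed taxa whose estimated
    trend matches in sign; ``spurious_pct`` the share of estimated changes
    with no matching true change. Either is None when its denominator is
    empty.
    """
    if min_fold < 1.0:
        raise InvalidParameterError("min_fold must be >= 1")
    t_before, t_after = truth_pair
    e_before, e_after = est_pair
    taxa = (set(t_before) | set(t_after) | set(e_before) | set(e_after))
    actual = {t: _sign_of_change(t_before.get(t, 0.0), t_after.get(t, 0.0),
                                 min_fold) for t in taxa}
    detected = {t: _sign_of_change(e_before.get(t, 0.0), e_after.get(t, 0.0),
                                   min_fold) for t in taxa}
    true_changes = [t for t in taxa if actual[t] != "unchanged"]
    est_changes = [t for t in taxa if detected[t] != "unchanged"]
    detected_pct = (
        100.0 * sum(detected[t] == actual[t] for t in true_changes)
        / len(true_changes) if true_changes else None
    )
    spurious_pct = (
        100.0 * sum(actual[t] != detected[t] for t in est_changes)
        / len(est_changes) if est_changes else None
    )
    return TrendComparison(actual, detected, detected_pct, spurious_pct)


@dataclass
class OverlapReport:
    """Agreement between two methods' detected taxon sets at one rank."""

    rank: str
    overlap_pct: float | None  # |A & B| / |A | B| * 100
    fp_in_overlap_pct: float | None  # % of A & B absent from truth
    exclusive_tp_a: int
    exclusive_tp_b: int
    n_a: int = 0
    n_b: int = 0


def method_overlap(result_a: ClassificationResult,
                   result_b: ClassificationResult,
                   truth_taxa: set[str], rank: str,
                   denominator: str = "union") -> OverlapReport:
    """Two-method agreement: how much of either's detections both share.

    ``overlap_pct`` uses the union of detected sets as denominator (the
    default reading; ``denominator="a"`` or ``"b"`` rescales to one
    method's set for sensitivity analysis). ``fp_in_overlap_pct`` is the
    share of jointly detected taxa that are not in the truth -- agreement
    between methods does not imply presence in the community. Exclusive
    true positives count truth taxa found by one method only.
    """
    a = result_a.detected_taxa(rank)
    b = result_b.detected_taxa(rank)
    both = a & b
    if denominator == "union":
        denom = a | b
    elif denominator == "a":
        denom = a
    elif denominator == "b":
        denom = b
    else:
        raise InvalidParameterError(f"unknown denominator {denominator!r}")
    overlap = 100.0 * len(both) / len(denom) if denom else None
    fp_in_overlap = (100.0 * len(both - truth_taxa) / len(both)
                     if both else None)
    return OverlapReport(
        rank=rank,
        overlap_pct=overlap,
        fp_in_overlap_pct=fp_in_overlap,
        exclusive_tp_a=len((a - b) & truth_taxa),
        exclusive_tp_b=len((b - a) & truth_taxa),
        n_a=len(a),
        n_b=len(b),
    )


@dataclass
class EvaluationReport:
    """The full metric bundle for one (scenario, mode, depth) cell."""

    scenario: str
    mode: str
    depth: int
    community: int
    per_rank: dict[str, dict[str, float | None]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            (self.scenario, self.mode, self.depth, self.community,
             rank, metric, value)
            for rank, metrics in sorted(self.per_rank.items())
            for metric, value in sorted(metrics.items())
        ]
        return pd.DataFrame(rows, columns=[
            "scenario", "mode", "depth", "community", "rank", "metric", "value",
        ])

    def write(self, directory: str | Path, stem: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / f"{stem}.json").write_text(self.to_json())
        self.to_long_frame().to_csv(directory / f"{stem}.tsv", sep="\t",
                                    index=False, float_format="%.6g")


def evaluation_report(vm: VirtualMicrobiome, rs: ReadSet,
                      result: ClassificationResult, scenario: str,
                      ranks: tuple[str, ...] = RANKS,
                      community_index: int = 0) -> EvaluationReport:
    """Aggregate every metric for one classification run."""
    species_counts = Counter(p.species for p in rs.pairs)
    allocated = np.array([species_counts.get(sp, 0) for sp in vm.species_ids])
    config = rs.config
    report = EvaluationReport(
        scenario=scenario,
        mode=config.mode if config else "unknown",
        depth=len(rs),
        community=community_index,
        metadata={"method": result.method_tag},
    )
    for rank in ranks:
        ds = detection_sets(vm, community_index, rs, result, rank)
        ds.validate()
        fp, tp = confusion_rates(ds)
        truth_matrix = aggregate_abundance(vm, rank)
        truth_ab = dict(zip(truth_matrix.taxon_ids,
                            truth_matrix.values[community_index]))
        d = abundance_error_D(truth_ab, result.profiles.get(rank, {}))
        report.per_rank[rank] = {
            "unsampled_pct": unsampled_fraction(vm, allocated, rank),
            "unidentified_pct": unidentified_fraction(rs, result, vm, rank),
            "fp_pct": fp,
            "tp_pct": tp,
            "abundance_error_D": d,
            "n_truth": len(ds.truth_taxa),
            "n_detected": len(ds.detected_taxa),
        }
    return report
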