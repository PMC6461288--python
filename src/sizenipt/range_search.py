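"""Two-stage traversal search for the optimal fragment-size window.

The search scans candidate window boundaries on coarse grids — lower bound
30..130 bp in 10 bp steps with the upper bound provisionally fixed at
150 bp, then upper bound 150..170 bp in 5 bp steps at the selected lower
bound — evaluating the size-filtered ratio classifier at each candidate
window and recording per-trisomy sensitivity and specificity. Per trisomy,
the *optimal set* is the plateau of candidates maximizing
sensitivity + specificity (a Youden-style criterion); the three sets are
intersected ("AND"), and the boundary is chosen from the intersection,
breaking ties toward the wider window (more retained fragments, lower
counting noise). An optional fine pass rescans the lower bound at 1 bp
resolution (75..85 bp by default) at the selected upper bound.

One training partition, drawn once from the classifier's seed, is shared
by every candidate so that candidate comparisons are not confounded by
partition noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .caller import ProtocolConfig, run_protocol, select_training
from .core_stats import SizeRange
from .errors import DegenerateSampleError, SearchError
from .sizedist_io import SizeDistributionTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Grids and classifier for the two-stage boundary search."""

    lower_candidates: tuple[int, ...] = tuple(range(30, 131, 10))
    upper_candidates: tuple[int, ...] = tuple(range(150, 171, 5))
    provisional_upper: int = 150
    classifier: ProtocolConfig = field(
        default_factory=lambda: ProtocolConfig.size_filtered()
    )
    #: 1 bp refinement grid for the lower bound; None disables the fine pass
    fine_lower_candidates: tuple[int, ...] | None = tuple(range(75, 86))
    #: window returned when the data carry no signal at all (degenerate scan)
    fallback_window: SizeRange = SizeRange(80, 155)

    def __post_init__(self) -> None:
        for name, cands in (
            ("lower_candidates", self.lower_candidates),
            ("upper_candidates", self.upper_candidates),
        ):
            if not cands:
                raise SearchError(f"{name} must be non-empty")
            if list(cands) != sorted(set(cands)):
                raise SearchError(f"{name} must be strictly increasing")
        if max(self.lower_candidates) >= min(self.upper_candidates):
            raise SearchError(
                "max(lower_candidates) must be < min(upper_candidates)"
            )


@dataclass(frozen=True)
class BoundaryGridResult:
    """Per-candidate metrics for one scan stage, with the selection audit."""

    stage: str  # "lower" | "upper"
    fixed_boundary: int
    candidates: tuple[int, ...]
    #: candidate -> target -> (sensitivity, specificity)
    metrics: dict[int, dict[str, tuple[float, float]]]
    #: candidate -> reason, for candidates that could not be evaluated
    invalid: dict[int, str]
    optimal_sets: dict[str, frozenset[int]]
    intersection: frozenset[int]
    selected: int
    degenerate: bool = False


def _window(stage: str, candidate: int, fixed: int) -> SizeRange:
    if stage == "lower":
        return SizeRange(candidate, fixed)
    if stage == "upper":
        return SizeRange(fixed, candidate)
    raise SearchError(f"unknown stage {stage!r}")


def optimal_set(
    grid: dict[int, tuple[float, float]]
) -> frozenset[int]:
    """Candidates attaining the maximum sensitivity + specificity."""
    if not grid:
        raise SearchError("no valid candidates in grid")
    best = max(sens + spec for sens, spec in grid.values())
    return frozenset(
        cand for cand, (sens, spec) in grid.items() if sens + spec == best
    )


def intersect_and_select(
    sets: dict[str, frozenset[int]],
    metrics: dict[int, dict[str, tuple[float, float]]],
    stage: str,
) -> tuple[frozenset[int], int]:
    """Intersect per-trisomy optimal sets and pick the boundary.

    Within the intersection the candidate maximizing summed
    sensitivity + specificity across the three trisomies wins; ties go to
    the wider window (smaller lower bound / larger upper bound). An empty
    intersection falls back to the summed-Youden argmax over all valid
    candidates, with a warning.
    """
    if not sets or any(not s for s in sets.values()):
        raise SearchError("empty per-trisomy optimal set")
    intersection = frozenset.intersection(*sets.values())
    pool = intersection
    if not pool:
        logger.warning(
            "%s-stage optimal sets have empty intersection; falling back to "
            "summed sensitivity+specificity argmax over all candidates",
            stage,
        )
        pool = frozenset(metrics)

    def summed_youden(cand: int) -> float:
        return sum(sens + spec for sens, spec in metrics[cand].values())

    # Tie-break toward the wider window: smaller candidate for the lower
    # bound, larger for the upper bound.
    wider = (lambda c: c) if stage == "lower" else (lambda c: -c)
    selected = min(pool, key=lambda c: (-summed_youden(c), wider(c)))
    return intersection, selected


def scan_boundary(
    table: SizeDistributionTable,
    config: SearchConfig,
    stage: str,
    fixed_boundary: int | None = None,
    candidates: tuple[int, ...] | None = None,
    training_ids: tuple[str, ...] | None = None,
) -> BoundaryGridResult:
    """Evaluate the classifier at every candidate boundary of one stage."""
    if stage not in ("lower", "upper"):
        raise SearchError(f"unknown stage {stage!r}")
    if candidates is None:
        candidates = (
            config.lower_candidates if stage == "lower" else config.upper_candidates
        )
    if fixed_boundary is None:
        if stage != "lower":
            raise SearchError("upper stage requires an explicit fixed_boundary")
        fixed_boundary = config.provisional_upper
    if training_ids is None:
        training_ids, _ = select_training(table, config.classifier)

    targets = config.classifier.targets
    metrics: dict[int, dict[str, tuple[float, float]]] = {}
    invalid: dict[int, str] = {}
    for cand in candidates:
        window = _window(stage, cand, fixed_boundary)
        classifier = replace(config.classifier, size_range=window)
        try:
            result = run_protocol(table, classifier, training_ids=training_ids)
        except DegenerateSampleError as exc:
            invalid[cand] = str(exc)
            logger.warning("candidate %d excluded: %s", cand, exc)
            continue
        metrics[cand] = {
            t: (result.summaries[t].sensitivity, result.summaries[t].specificity)
            for t in targets
        }
    if not metrics:
        raise SearchError(f"{stage} stage: no candidate could be evaluated")

    optimal_sets = {
        t: optimal_set({c: m[t] for c, m in metrics.items()}) for t in targets
    }

    # A scan is degenerate when the data rank no candidate above any other:
    # either every candidate ties exactly, or no candidate detects anything.
    youden = {
        c: sum(sens + spec for sens, spec in m.values())
        for c, m in metrics.items()
    }
    all_tie = len(youden) > 1 and max(youden.values()) == min(youden.values())
    no_signal = all(
        m[t][0] == 0.0 for m in metrics.values() for t in targets
    )
    degenerate = all_tie or no_signal

    intersection, selected = intersect_and_select(optimal_sets, metrics, stage)
    return BoundaryGridResult(
        stage=stage,
        fixed_boundary=fixed_boundary,
        candidates=tuple(candidates),
        metrics=metrics,
        invalid=invalid,
        optimal_sets=optimal_sets,
        intersection=intersection,
        selected=selected,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class SearchResult:
    window: SizeRange
    lower_grid: BoundaryGridResult
    upper_grid: BoundaryGridResult
    fine_grid: BoundaryGridResult | None = None
    degenerate: bool = False


def two_stage_search(
    table: SizeDistributionTable, config: SearchConfig | None = None
) -> SearchResult:
    """Lower scan at the provisional upper bound, upper scan at the chosen
    lower bound, optional 1 bp refinement of the lower bound.

    If both coarse scans are degenerate (uninformative data), the
    configured fallback window is returned with a warning.
    """
    config = config or SearchConfig()
    training_ids, _ = select_training(table, config.classifier)

    lower_grid = scan_boundary(
        table,
        config,
        "lower",
        fixed_boundary=config.provisional_upper,
        training_ids=training_ids,
    )
    lower = lower_grid.selected

    upper_grid = scan_boundary(
        table,
        config,
        "upper",
        fixed_boundary=lower,
        training_ids=training_ids,
    )
    upper = upper_grid.selected

    if lower_grid.degenerate and upper_grid.degenerate:
        logger.warning(
            "search degenerate (no candidate ranked above any other); "
            "returning fallback window %s",
            config.fallback_window,
        )
        return SearchResult(
            window=config.fallback_window,
            lower_grid=lower_grid,
            upper_grid=upper_grid,
            degenerate=True,
        )

    fine_grid = None
    if config.fine_lower_candidates:
        fine_grid = scan_boundary(
            table,
            config,
            "lower",
            fixed_boundary=upper,
            candidates=tuple(config.fine_lower_candidates),
            training_ids=training_ids,
        )
        lower = fine_grid.selected

    return SearchResult(
        window=SizeRange(lower, upper),
        lower_grid=lower_grid,
        upper_grid=upper_grid,
        fine_grid=fine_grid,
    )


def grid_to_rows(grid: BoundaryGridResult) -> list[dict]:
    """Flatten a grid result to long rows for CSV export."""
    rows = []
    for cand in grid.candidates:
        if cand in grid.invalid:
            continue
        for target, (sens, spec) in grid.metrics[cand].items():
            rows.append(
                {
                    "stage": grid.stage,
                    "candidate": cand,
                    "target": target,
                    "sensitivity": sens,
                    "specificity": spec,
                    "in_optimal_set": cand in grid.optimal_sets[target],
                }
            )
    return rows
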