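"""Chromosome representation statistics for size-restricted cfDNA counts.

Two statistics drive trisomy detection:

* the **proportion** ``P_chrN = Sum_chrN / Sum_all`` of fragments mapping to
  a target chromosome among a denominator chromosome set (22 autosomes by
  default), optionally restricted to a fragment-length window; and
* the **ratio** ``R_chrN = P(w)_chrN / P(w)_chrother`` of the windowed
  target-chromosome proportion to the windowed proportion of the 19
  autosomes other than chr13/18/21. The shared denominator cancels, so R is
  the plain quotient of in-window counts — exactly scale-invariant.

Both are standardized against a euploid training panel as
``z = (x - mean_training) / sd_training`` (sample SD, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromosomes import AUTOSOMES, OTHER_AUTOSOMES, TARGET_CHROMS
from .errors import (
    ConfigurationError,
    DegenerateSampleError,
    DegenerateTrainingError,
)
from .sizedist_io import SampleRecord, SizeDistributionTable

STATISTIC_KINDS = ("proportion", "ratio")


@dataclass(frozen=True, order=True)
class SizeRange:
    """Inclusive fragment-length window [lower_bp, upper_bp]."""

    lower_bp: int
    upper_bp: int

    def __post_init__(self) -> None:
        if not (1 <= self.lower_bp <= self.upper_bp):
            raise ValueError(
                f"invalid SizeRange [{self.lower_bp}, {self.upper_bp}]"
            )

    def contains(self, length: int) -> bool:
        return self.lower_bp <= length <= self.upper_bp

    def __str__(self) -> str:  # used in logs and reports
        return f"[{self.lower_bp},{self.upper_bp}]"


#: The fragment-size window selected by the boundary search on the original
#: cohort; the default window of the size-filtered protocol.
SELECTED_RANGE = SizeRange(80, 155)


@dataclass(frozen=True)
class ChromProportionProfile:
    sample_id: str
    size_range: SizeRange
    included_chroms: tuple[str, ...]
    P: dict[str, float]


@dataclass(frozen=True)
class RatioProfile:
    sample_id: str
    size_range: SizeRange
    R: dict[str, float]


@dataclass(frozen=True)
class TrainingStats:
    """Per-target mean/SD of a statistic over a euploid training panel."""

    statistic_kind: str
    size_range: SizeRange
    n_training: int
    mean: dict[str, float]
    sd: dict[str, float]
    training_ids: tuple[str, ...]
    #: targets whose training SD collapsed to zero (z-scores against them error)
    degenerate_targets: frozenset[str] = field(default_factory=frozenset)


def restrict_range(record: SampleRecord, size_range: SizeRange) -> SampleRecord:
    """Keep only counts whose fragment length lies inside the window."""
    counts = {
        key: n for key, n in record.counts.items() if size_range.contains(key[1])
    }
    if sum(counts.values()) == 0:
        raise DegenerateSampleError(
            f"sample {record.sample_id!r}: no fragments in {size_range}"
        )
    return SampleRecord(record.sample_id, record.label, counts)


def chrom_proportions(
    record: SampleRecord,
    included_chroms: tuple[str, ...] = AUTOSOMES,
    size_range: SizeRange | None = None,
) -> ChromProportionProfile:
    """Per-chromosome fragment proportions over ``included_chroms``.

    Both numerator and denominator are restricted to ``size_range`` (the
    whole observed domain when None).
    """
    if size_range is None:
        lo, hi = record.length_bounds()
        size_range = SizeRange(lo, hi)
    counts = record.in_range_counts(
        size_range.lower_bp, size_range.upper_bp, tuple(included_chroms)
    )
    total = sum(counts.values())
    if total == 0:
        raise DegenerateSampleError(
            f"sample {record.sample_id!r}: zero denominator over "
            f"{len(included_chroms)} chromosomes in {size_range}"
        )
    return ChromProportionProfile(
        sample_id=record.sample_id,
        size_range=size_range,
        included_chroms=tuple(included_chroms),
        P={c: counts[c] / total for c in included_chroms},
    )


def ratio_statistic(
    record: SampleRecord, target: str, size_range: SizeRange
) -> float:
    """R = in-window count of ``target`` / in-window count of the 19
    non-screened autosomes."""
    if target not in TARGET_CHROMS:
        raise ConfigurationError(f"target must be one of {TARGET_CHROMS}")
    num = record.in_range_count(target, size_range.lower_bp, size_range.upper_bp)
    den = sum(
        record.in_range_count(c, size_range.lower_bp, size_range.upper_bp)
        for c in OTHER_AUTOSOMES
    )
    if den == 0:
        raise DegenerateSampleError(
            f"sample {record.sample_id!r}: zero reference-autosome count "
            f"in {size_range}"
        )
    return num / den


def compute_statistic(
    record: SampleRecord,
    statistic_kind: str,
    size_range: SizeRange,
    target: str,
    included_chroms: tuple[str, ...] = AUTOSOMES,
) -> float:
    """Dispatch to the proportion or ratio statistic for one target."""
    if statistic_kind == "proportion":
        profile = chrom_proportions(record, included_chroms, size_range)
        return profile.P[target]
    if statistic_kind == "ratio":
        return ratio_statistic(record, target, size_range)
    raise ConfigurationError(f"unknown statistic_kind {statistic_kind!r}")


def fit_training_stats(
    table: SizeDistributionTable,
    training_ids,
    statistic_kind: str,
    size_range: SizeRange,
    targets: tuple[str, ...] = TARGET_CHROMS,
    included_chroms: tuple[str, ...] = AUTOSOMES,
) -> TrainingStats:
    """Mean/SD of the chosen statistic over a euploid training panel.

    SD uses the n-1 (sample) convention. A zero SD is flagged rather than
    raised here; z-scores against a flagged target raise.
    """
    training_ids = tuple(training_ids)
    if len(training_ids) < 2:
        raise ConfigurationError("need at least 2 training samples")
    records = []
    for sid in training_ids:
        try:
            rec = table.get(sid)
        except KeyError as exc:
            raise ConfigurationError(str(exc)) from exc
        if rec.label != "euploid":
            raise ConfigurationError(
                f"training sample {sid!r} has label {rec.label!r}, "
                "expected 'euploid'"
            )
        records.append(rec)

    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    degenerate: set[str] = set()
    for target in targets:
        values = np.array(
            [
                compute_statistic(
                    rec, statistic_kind, size_range, target, included_chroms
                )
                for rec in records
            ]
        )
        mean[target] = float(values.mean())
        sd[target] = float(values.std(ddof=1))
        if sd[target] == 0.0:
            degenerate.add(target)

    return TrainingStats(
        statistic_kind=statistic_kind,
        size_range=size_range,
        n_training=len(training_ids),
        mean=mean,
        sd=sd,
        training_ids=training_ids,
        degenerate_targets=frozenset(degenerate),
    )


def zscore(value: float, stats: TrainingStats, target: str) -> float:
    """(value - training mean) / training SD for one target chromosome."""
    if target in stats.degenerate_targets or stats.sd[target] == 0.0:
        raise DegenerateTrainingError(
            f"training SD for {target} is zero; z-score undefined"
        )
    return (value - stats.mean[target]) / stats.sd[target]
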