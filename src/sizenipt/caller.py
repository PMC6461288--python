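"""Trisomy calling protocols and their evaluation.

Two z-score protocols are provided:

* **full-range proportion** — the chromosome proportion over the whole
  observed fragment-length domain, standardized against 30 random euploid
  training samples, positive when z > 3.5;
* **size-filtered ratio** — the ratio R of target-chromosome to
  reference-autosome counts within a fragment-size window (80-155 bp by
  default), standardized the same way, positive when z > 2.5.

Both cutoffs are strict: a z exactly at the cutoff is a negative call.
Performance is scored one-vs-rest per target chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromosomes import AUTOSOMES, LABEL_TO_CHROM, TARGET_CHROMS
from .core_stats import (
    SELECTED_RANGE,
    SizeRange,
    TrainingStats,
    compute_statistic,
    fit_training_stats,
    zscore,
)
from .errors import ConfigurationError, EvaluationError
from .sizedist_io import SampleRecord, SizeDistributionTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProtocolConfig:
    """Parameterization of one calling protocol.

    ``size_range=None`` means the table's full observed length domain
    (resolved at run time). Training samples are either drawn without
    replacement from the euploid samples by a seeded generator
    (``training_selection='seeded_random'``) or given verbatim
    (``'explicit_ids'``).
    """

    statistic_kind: str = "ratio"
    size_range: SizeRange | None = SELECTED_RANGE
    cutoff: float = 2.5
    targets: tuple[str, ...] = TARGET_CHROMS
    n_training: int = 30
    training_selection: str = "seeded_random"
    seed: int = 0
    training_ids: tuple[str, ...] | None = None
    #: 'off' or 'replace_with_training_mean' (see run_protocol)
    outlier_policy: str = "off"
    outlier_z: float = 6.0
    included_chroms: tuple[str, ...] = AUTOSOMES

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be > 0")
        if self.n_training < 2:
            raise ConfigurationError("n_training must be >= 2")
        if self.statistic_kind not in ("proportion", "ratio"):
            raise ConfigurationError(
                f"unknown statistic_kind {self.statistic_kind!r}"
            )
        if not set(self.targets) <= set(TARGET_CHROMS):
            raise ConfigurationError(f"targets must be within {TARGET_CHROMS}")
        if self.training_selection not in ("seeded_random", "explicit_ids"):
            raise ConfigurationError(
                f"unknown training_selection {self.training_selection!r}"
            )
        if self.training_selection == "explicit_ids" and not self.training_ids:
            raise ConfigurationError("explicit_ids requires training_ids")
        if self.outlier_policy not in ("off", "replace_with_training_mean"):
            raise ConfigurationError(
                f"unknown outlier_policy {self.outlier_policy!r}"
            )

    @classmethod
    def full_range(cls, **kwargs) -> "ProtocolConfig":
        """The full-length-domain proportion protocol (cutoff 3.5)."""
        kwargs.setdefault("statistic_kind", "proportion")
        kwargs.setdefault("size_range", None)
        kwargs.setdefault("cutoff", 3.5)
        return cls(**kwargs)

    @classmethod
    def size_filtered(cls, **kwargs) -> "ProtocolConfig":
        """The 80-155 bp ratio protocol (cutoff 2.5)."""
        kwargs.setdefault("statistic_kind", "ratio")
        kwargs.setdefault("size_range", SELECTED_RANGE)
        kwargs.setdefault("cutoff", 2.5)
        return cls(**kwargs)


@dataclass(frozen=True)
class AneuploidyCall:
    sample_id: str
    z: dict[str, float]
    positive: dict[str, bool]
    cutoff: float


@dataclass(frozen=True)
class ConfusionSummary:
    target: str
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else float("nan")

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP) if (self.TN + self.FP) else float("nan")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class ProtocolResult:
    protocol: ProtocolConfig
    resolved_range: SizeRange
    training_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    stats: TrainingStats
    calls: tuple[AneuploidyCall, ...]
    summaries: dict[str, ConfusionSummary]
    outlier_log: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)


def select_training(
    table: SizeDistributionTable, protocol: ProtocolConfig
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Partition the table into (training euploids, everything else).

    Seeded-random selection draws ``n_training`` euploid sample ids without
    replacement; explicit ids are checked to exist and be euploid. The
    returned id tuples partition the table's samples.
    """
    euploid_ids = [s.sample_id for s in table if s.label == "euploid"]
    if protocol.training_selection == "explicit_ids":
        training = tuple(protocol.training_ids)
        for sid in training:
            rec = table.get(sid)  # KeyError -> caller sees missing id
            if rec.label != "euploid":
                raise ConfigurationError(
                    f"training sample {sid!r} has label {rec.label!r}, "
                    "expected 'euploid'"
                )
    else:
        if len(euploid_ids) < protocol.n_training:
            raise ConfigurationError(
                f"need {protocol.n_training} euploid samples for training, "
                f"table has {len(euploid_ids)}"
            )
        rng = np.random.default_rng(protocol.seed)
        training = tuple(
            str(sid)
            for sid in rng.choice(
                euploid_ids, size=protocol.n_training, replace=False
            )
        )
    training_set = set(training)
    test = tuple(sid for sid in table.sample_ids if sid not in training_set)
    return training, test


def call_sample(
    record: SampleRecord,
    stats: TrainingStats,
    protocol: ProtocolConfig,
    statistic_override: dict[str, float] | None = None,
) -> AneuploidyCall:
    """z-score one sample against the training panel and apply the cutoff.

    ``statistic_override`` substitutes a precomputed statistic for selected
    targets (used by the outlier policy).
    """
    z: dict[str, float] = {}
    positive: dict[str, bool] = {}
    for target in protocol.targets:
        if statistic_override and target in statistic_override:
            value = statistic_override[target]
        else:
            value = compute_statistic(
                record,
                stats.statistic_kind,
                stats.size_range,
                target,
                protocol.included_chroms,
            )
        z[target] = zscore(value, stats, target)
        positive[target] = z[target] > protocol.cutoff  # strict
    return AneuploidyCall(record.sample_id, z, positive, protocol.cutoff)


def evaluate_calls(
    calls, labels: dict[str, str], target: str
) -> ConfusionSummary:
    """One-vs-rest confusion summary for one target chromosome."""
    positive_label = next(
        lab for lab, chrom in LABEL_TO_CHROM.items() if chrom == target
    )
    unknown = [
        c.sample_id
        for c in calls
        if labels.get(c.sample_id, "unknown") == "unknown"
    ]
    if unknown:
        raise EvaluationError(
            f"cannot evaluate samples with unknown labels: {', '.join(unknown)}"
        )
    tp = fp = tn = fn = 0
    for call in calls:
        truth = labels[call.sample_id] == positive_label
        called = call.positive[target]
        if truth and called:
            tp += 1
        elif truth:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(target, tp, fp, tn, fn)


def run_protocol(
    table: SizeDistributionTable,
    protocol: ProtocolConfig,
    training_ids: tuple[str, ...] | None = None,
) -> ProtocolResult:
    """End-to-end: select training, fit stats, call every test sample,
    evaluate per target.

    ``training_ids`` overrides partition selection (used by the boundary
    search to share one partition across candidate windows).

    With ``outlier_policy='replace_with_training_mean'`` a test statistic
    whose |z| exceeds ``outlier_z`` on a chromosome other than the sample's
    own trisomy is replaced by the training mean before calling; each
    replacement is logged and recorded in ``outlier_log``.
    """
    if training_ids is not None:
        protocol_for_partition = replace(
            protocol,
            training_selection="explicit_ids",
            training_ids=tuple(training_ids),
        )
    else:
        protocol_for_partition = protocol
    train, test = select_training(table, protocol_for_partition)

    size_range = protocol.size_range
    if size_range is None:
        lo, hi = table.length_domain
        size_range = SizeRange(lo, hi)

    stats = fit_training_stats(
        table,
        train,
        protocol.statistic_kind,
        size_range,
        protocol.targets,
        protocol.included_chroms,
    )

    labels = table.labels()
    calls = []
    outlier_log: list[tuple[str, str, float]] = []
    for sid in test:
        record = table.get(sid)
        override: dict[str, float] = {}
        if protocol.outlier_policy == "replace_with_training_mean":
            own_chrom = LABEL_TO_CHROM.get(labels.get(sid, "unknown"))
            for target in protocol.targets:
                if target == own_chrom:
                    continue
                value = compute_statistic(
                    record,
                    protocol.statistic_kind,
                    size_range,
                    target,
                    protocol.included_chroms,
                )
                z = zscore(value, stats, target)
                if abs(z) > protocol.outlier_z:
                    override[target] = stats.mean[target]
                    outlier_log.append((sid, target, z))
                    logger.warning(
                        "outlier policy: sample %s %s z=%.2f replaced by "
                        "training mean",
                        sid,
                        target,
                        z,
                    )
        calls.append(call_sample(record, stats, protocol, override or None))

    summaries = {
        target: evaluate_calls(calls, labels, target)
        for target in protocol.targets
    }
    return ProtocolResult(
        protocol=protocol,
        resolved_range=size_range,
        training_ids=tuple(train),
        test_ids=tuple(test),
        stats=stats,
        calls=tuple(calls),
        summaries=summaries,
        outlier_log=tuple(outlier_log),
    )


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------


def calls_to_frame(calls) -> pd.DataFrame:
    rows = [
        (c.sample_id, target, c.z[target], c.positive[target])
        for c in calls
        for target in sorted(c.z)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "target", "z", "positive"])


def summaries_to_frame(summaries: dict[str, ConfusionSummary]) -> pd.DataFrame:
    rows = [
        (
            s.target, s.TP, s.FP, s.TN, s.FN,
            s.sensitivity, s.specificity,
        )
        for s in summaries.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["target", "TP", "FP", "TN", "FN", "sensitivity", "specificity"],
    )
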