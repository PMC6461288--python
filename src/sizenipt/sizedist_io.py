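"""Fragment-size count tables: containers, readers/writers, SAM/BAM extraction.

The unit of data is a per-sample histogram of cfDNA fragment counts indexed
by (chromosome, fragment length in bp). Tables are exchanged as long-format
CSV/TSV with the header ``sample_id,label,chromosome,length_bp,count``; an
XLSX dialect with the same column roles is supported for supplementary
datasets distributed as spreadsheets. Fragment-size histograms can also be
derived directly from coordinate-sorted paired-end SAM/BAM via pysam.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .chromosomes import (
    CHROMOSOMES,
    VALID_LABELS,
    chrom_sort_key,
    normalize_chrom,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["sample_id", "label", "chromosome", "length_bp", "count"]


@dataclass
class SampleRecord:
    """One plasma sample's fragment-size histogram.

    Parameters
    ----------
    sample_id:
        Unique sample name.
    label:
        Ground-truth class: one of ``T13``, ``T18``, ``T21``, ``euploid``,
        ``unknown``.
    counts:
        Mapping ``(chromosome, fragment_length_bp) -> count``.
    """

    sample_id: str
    label: str
    counts: dict[tuple[str, int], int]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def validate(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValidationError(
                f"sample {self.sample_id!r}: invalid label {self.label!r}"
            )
        total = 0
        for (chrom, length), count in self.counts.items():
            if chrom not in CHROMOSOMES:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown chromosome {chrom!r}"
                )
            if length < 1:
                raise ValidationError(
                    f"sample {self.sample_id!r}: fragment length {length} < 1"
                )
            if count < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative count at "
                    f"({chrom}, {length})"
                )
            total += count
        if total == 0:
            raise ValidationError(f"sample {self.sample_id!r}: total count is 0")

    def total(self) -> int:
        return int(sum(self.counts.values()))

    def length_bounds(self) -> tuple[int, int]:
        lengths = [length for (_, length) in self.counts]
        return (min(lengths), max(lengths))

    def _chrom_cumsum(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted lengths and cumulative counts for one chromosome (cached)."""
        cached = self._cache.get(chrom)
        if cached is None:
            pairs = sorted(
                (length, count)
                for (c, length), count in self.counts.items()
                if c == chrom
            )
            if pairs:
                lengths = np.array([p[0] for p in pairs], dtype=np.int64)
                cum = np.cumsum([p[1] for p in pairs], dtype=np.int64)
            else:
                lengths = np.empty(0, dtype=np.int64)
                cum = np.empty(0, dtype=np.int64)
            cached = (lengths, cum)
            self._cache[chrom] = cached
        return cached

    def in_range_count(self, chrom: str, lower_bp: int, upper_bp: int) -> int:
        """Fragments of ``chrom`` with length in [lower_bp, upper_bp]."""
        lengths, cum = self._chrom_cumsum(chrom)
        if lengths.size == 0:
            return 0
        lo = np.searchsorted(lengths, lower_bp, side="left")
        hi = np.searchsorted(lengths, upper_bp, side="right")
        if hi == lo:
            return 0
        return int(cum[hi - 1] - (cum[lo - 1] if lo > 0 else 0))

    def in_range_counts(
        self, lower_bp: int, upper_bp: int, chroms: tuple[str, ...]
    ) -> dict[str, int]:
        return {c: self.in_range_count(c, lower_bp, upper_bp) for c in chroms}


@dataclass
class SizeDistributionTable:
    """An ordered collection of SampleRecords with a shared length domain."""

    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        self._index = {s.sample_id: s for s in self.samples}

    def validate(self) -> None:
        if not self.samples:
            raise ValidationError("no samples")
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            s.validate()

    @property
    def length_domain(self) -> tuple[int, int]:
        """Inclusive (min, max) fragment length observed in the table."""
        bounds = [s.length_bounds() for s in self.samples if s.counts]
        if not bounds:
            raise ValidationError("no samples")
        return (min(b[0] for b in bounds), max(b[1] for b in bounds))

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def get(self, sample_id: str) -> SampleRecord:
        try:
            return self._index[sample_id]
        except KeyError:
            raise KeyError(f"no sample {sample_id!r} in table") from None

    def labels(self) -> dict[str, str]:
        return {s.sample_id: s.label for s in self.samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)


@dataclass(frozen=True)
class AlignmentFilterConfig:
    """Filters applied when deriving fragment sizes from paired-end alignments.

    Defaults are conservative: MAPQ >= 30, proper pairs only, duplicates
    dropped, fragment lengths restricted to [30, 600] bp (spanning every
    window the boundary search ever scans). Templates outside the length
    window are dropped, not clipped.
    """

    min_mapq: int = 30
    min_len_bp: int = 30
    max_len_bp: int = 600
    require_proper_pair: bool = True
    drop_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.min_len_bp < 1:
            raise ValidationError("min_len_bp must be >= 1")
        if self.min_len_bp > self.max_len_bp:
            raise ValidationError("min_len_bp must be <= max_len_bp")
        if self.min_mapq < 0:
            raise ValidationError("min_mapq must be >= 0")


# ---------------------------------------------------------------------------
# long CSV/TSV and XLSX readers
# ---------------------------------------------------------------------------


def _table_from_long_frame(df: pd.DataFrame, source: str) -> SizeDistributionTable:
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{source}: missing required column(s): {', '.join(missing)}"
        )
    if df.empty:
        raise ValidationError(f"{source}: no samples")

    df = df.loc[:, LONG_COLUMNS].copy()
    # Row numbers reported in errors are 1-based data rows (header = row 0).
    df["_row"] = np.arange(1, len(df) + 1)

    for col in ("length_bp", "count"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{source}: column {col!r} is not integer") from exc

    bad = df.loc[df["count"] < 0]
    if len(bad):
        row = int(bad["_row"].iloc[0])
        raise ValidationError(f"{source}: negative count at data row {row}")
    bad = df.loc[df["length_bp"] < 1]
    if len(bad):
        row = int(bad["_row"].iloc[0])
        raise ValidationError(f"{source}: length_bp < 1 at data row {row}")

    try:
        df["chromosome"] = df["chromosome"].map(normalize_chrom)
    except ValueError as exc:
        raise ValidationError(f"{source}: {exc}") from exc

    records: list[SampleRecord] = []
    # groupby(sort=False) preserves first-appearance order of samples.
    for (sample_id, label), group in df.groupby(
        ["sample_id", "label"], sort=False
    ):
        summed = group.groupby(["chromosome", "length_bp"], sort=False)[
            "count"
        ].sum()
        counts = {
            (chrom, int(length)): int(count)
            for (chrom, length), count in summed.items()
        }
        records.append(SampleRecord(str(sample_id), str(label), counts))

    table = SizeDistributionTable(records)
    table.validate()
    return table


def default_s1_layout() -> dict:
    """Column-role mapping for the supplementary-XLSX dialect.

    Shipped as a small editable YAML declaration because spreadsheet
    supplements drift in layout; adjust the packaged file (or pass
    ``layout=`` to :func:`read_size_table`) to match a concrete file.
    """
    ref = importlib.resources.files("sizenipt").joinpath("s1_layout.yaml")
    return yaml.safe_load(ref.read_text())


def read_size_table(
    path, format_spec: str = "long_csv", layout: dict | None = None
) -> SizeDistributionTable:
    """Read a fragment-size count table.

    Parameters
    ----------
    path:
        Input file.
    format_spec:
        ``long_csv``, ``long_tsv`` or ``s1_xlsx``.
    layout:
        For ``s1_xlsx`` only: overrides the packaged sheet/column mapping.

    Rows sharing a (sample, chromosome, length) key are summed. Chromosome
    names are normalized ('21' and 'chr21' are both accepted).
    """
    if format_spec in ("long_csv", "long_tsv"):
        sep = "," if format_spec == "long_csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        return _table_from_long_frame(df, str(path))
    if format_spec == "s1_xlsx":
        spec = layout or default_s1_layout()
        df = pd.read_excel(path, sheet_name=spec["sheet"], engine="openpyxl")
        df = df.rename(
            columns={v: k for k, v in spec["columns"].items()}
        )
        if "label" not in df.columns and spec.get("default_label"):
            df["label"] = spec["default_label"]
        return _table_from_long_frame(df, str(path))
    raise ValueError(f"unknown format_spec {format_spec!r}")


def write_size_table(
    table: SizeDistributionTable, path, format_spec: str = "long_csv"
) -> None:
    """Write a table in long format; inverse of :func:`read_size_table`.

    An empty table is written as a header-only file.
    """
    if format_spec not in ("long_csv", "long_tsv"):
        raise ValueError(f"unknown format_spec {format_spec!r}")
    sep = "," if format_spec == "long_csv" else "\t"
    rows = []
    for s in table.samples:
        for (chrom, length) in sorted(
            s.counts, key=lambda k: (chrom_sort_key(k[0]), k[1])
        ):
            rows.append((s.sample_id, s.label, chrom, length, s.counts[(chrom, length)]))
    df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# SAM/BAM fragment-size extraction
# ---------------------------------------------------------------------------


def extract_fragment_sizes(
    alignment_path,
    sample_id: str,
    filters: AlignmentFilterConfig | None = None,
) -> SampleRecord:
    """Tally fragment sizes from a paired-end SAM/BAM file.

    Each template is counted exactly once, from the mate with strictly
    positive template length (TLEN); the fragment length is |TLEN|.
    Records failing MAPQ / proper-pair / duplicate filters, falling outside
    the configured length window, or mapped to non-canonical contigs are
    skipped (a summary is logged). The returned record carries label
    ``unknown``; it may have zero total counts if nothing passed, in which
    case a warning is emitted.
    """
    import pysam

    filters = filters or AlignmentFilterConfig()
    counts: dict[tuple[str, int], int] = {}
    n_skipped = 0
    with pysam.AlignmentFile(str(alignment_path), require_index=False) as af:
        for read in af.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_paired
                or read.template_length <= 0
            ):
                n_skipped += 1
                continue
            if read.mapping_quality < filters.min_mapq:
                n_skipped += 1
                continue
            if filters.require_proper_pair and not read.is_proper_pair:
                n_skipped += 1
                continue
            if filters.drop_duplicates and read.is_duplicate:
                n_skipped += 1
                continue
            length = abs(read.template_length)
            if not (filters.min_len_bp <= length <= filters.max_len_bp):
                n_skipped += 1
                continue
            try:
                chrom = normalize_chrom(read.reference_name)
            except ValueError:
                n_skipped += 1
                continue
            key = (chrom, length)
            counts[key] = counts.get(key, 0) + 1

    record = SampleRecord(sample_id, "unknown", counts)
    if not counts:
        logger.warning(
            "extract_fragment_sizes(%s): no templates passed filters "
            "(%d records skipped)",
            sample_id,
            n_skipped,
        )
    else:
        logger.info(
            "extract_fragment_sizes(%s): %d fragments tallied, %d records skipped",
            sample_id,
            record.total(),
            n_skipped,
        )
    return record
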