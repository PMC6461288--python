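"""Chromosome naming and the denominator sets used throughout.

Maternal-plasma cfDNA statistics here are computed over the 22 autosomes by
default: fetal sex is usually unknown, so chrX/chrY counts vary strongly
between pregnancies and would inflate the variance of any proportion that
includes them. Sex chromosomes are retained on I/O and excluded at
computation time.
"""

from __future__ import annotations

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMS: tuple[str, ...] = ("chrX", "chrY")
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + SEX_CHROMS

#: Chromosomes whose trisomies are clinically screened (13: Patau,
#: 18: Edwards, 21: Down).
TARGET_CHROMS: tuple[str, ...] = ("chr13", "chr18", "chr21")

#: The 19 autosomes that serve as the reference ("other") set in the
#: ratio statistic's denominator.
OTHER_AUTOSOMES: tuple[str, ...] = tuple(
    c for c in AUTOSOMES if c not in TARGET_CHROMS
)

VALID_LABELS: tuple[str, ...] = ("T13", "T18", "T21", "euploid", "unknown")

#: Trisomy label -> affected chromosome.
LABEL_TO_CHROM: dict[str, str] = {"T13": "chr13", "T18": "chr18", "T21": "chr21"}

_CHROM_INDEX = {c: i for i, c in enumerate(CHROMOSOMES)}


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to its 'chr'-prefixed form.

    Accepts '21', 'chr21', 'Chr21', 'x', 'chrX' etc.

    Raises
    ------
    ValueError
        If the name does not denote one of chr1..chr22, chrX, chrY.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    candidate = f"chr{s}"
    if candidate not in _CHROM_INDEX:
        raise ValueError(f"unknown chromosome name: {name!r}")
    return candidate


def chrom_sort_key(chrom: str) -> int:
    """Genomic ordering chr1..chr22, chrX, chrY."""
    return _CHROM_INDEX[chrom]
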