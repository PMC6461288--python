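"""Synthetic maternal-plasma cfDNA cohorts with known ground truth.

The generative model mirrors the biology the size-based method exploits.
Plasma cfDNA of a pregnant woman is a two-origin mixture: a maternal
component (fetal fraction ``1 - f``) whose fragment lengths peak at the
mononucleosomal mode near 166 bp, and a placental/fetal component
(fraction ``f``, typically 5-20%) that is systematically shorter (mode
near 143 bp here). Chromosome of origin and fragment length are drawn
independently within each origin component. For a trisomic fetus the
affected chromosome receives a 1.5x dosage (three copies against two) in
the fetal component only, after which fetal chromosome weights are
renormalized.

Counts are one multinomial draw of the configured depth over
(chromosome x origin x length) cells, so each sample's histogram is exactly
normalized; an independent per-cell Poisson alternative is available.
Baseline autosome proportions follow genome length blended toward uniform
(0.7/0.3), which places every autosome in the ~2-9% band observed in
mapped sequencing data. Sex chromosomes are simulated at a small weight
with a random fetal sex, exercising the downstream autosomes-only policy;
maternal and fetal sex-chromosome weights are equal in total, so the
autosome-conditional mixture has exactly the closed form used by
:func:`expected_statistic`.

Deliberately not modelled: the 10-bp nucleosomal periodicity of real
cfDNA length spectra, GC/mappability bias, and duplicate structure — the
method consumes window sums only, for which these features are irrelevant;
an optional per-chromosome lognormal overdispersion (default off) can
emulate uncorrected technical variation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .chromosomes import AUTOSOMES, LABEL_TO_CHROM, OTHER_AUTOSOMES
from .errors import ConfigurationError
from .sizedist_io import SampleRecord, SizeDistributionTable

# GRCh38 autosome lengths (bp), used only to shape baseline proportions.
_AUTOSOME_LENGTHS = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468,
}


def default_baseline_props() -> dict[str, float]:
    """Autosome baseline proportions: 0.7 genome-length + 0.3 uniform blend."""
    total = sum(_AUTOSOME_LENGTHS.values())
    return {
        c: 0.7 * _AUTOSOME_LENGTHS[c] / total + 0.3 / len(AUTOSOMES)
        for c in AUTOSOMES
    }


@dataclass(frozen=True)
class LengthDistribution:
    """A discretized fragment-length distribution on integer bp."""

    lengths: tuple[int, ...]
    pmf: tuple[float, ...]

    @classmethod
    def discretized_normal(
        cls, mode: float, scale: float, support: tuple[int, int] = (60, 400)
    ) -> "LengthDistribution":
        lengths = np.arange(support[0], support[1] + 1)
        p = sps.norm.pdf(lengths, loc=mode, scale=scale)
        p = p / p.sum()
        return cls(tuple(int(x) for x in lengths), tuple(p))

    @classmethod
    def uniform(cls, lower: int, upper: int) -> "LengthDistribution":
        lengths = np.arange(lower, upper + 1)
        p = np.full(lengths.size, 1.0 / lengths.size)
        return cls(tuple(int(x) for x in lengths), tuple(p))

    @classmethod
    def mixture(
        cls, components: list[tuple[float, "LengthDistribution"]]
    ) -> "LengthDistribution":
        weights = np.array([w for w, _ in components], dtype=float)
        if not np.isclose(weights.sum(), 1.0):
            raise ConfigurationError("mixture weights must sum to 1")
        lo = min(min(d.lengths) for _, d in components)
        hi = max(max(d.lengths) for _, d in components)
        pmf = np.zeros(hi - lo + 1)
        for w, d in components:
            idx = np.asarray(d.lengths) - lo
            pmf[idx] += w * np.asarray(d.pmf)
        return cls(tuple(range(lo, hi + 1)), tuple(pmf))

    def on_support(self, support: tuple[int, int]) -> np.ndarray:
        """Dense pmf array over an enclosing support (zeros outside)."""
        out = np.zeros(support[1] - support[0] + 1)
        idx = np.asarray(self.lengths) - support[0]
        out[idx] = self.pmf
        return out

    def mass(self, lower_bp: int, upper_bp: int) -> float:
        """Probability mass on the inclusive window [lower_bp, upper_bp]."""
        lengths = np.asarray(self.lengths)
        sel = (lengths >= lower_bp) & (lengths <= upper_bp)
        return float(np.asarray(self.pmf)[sel].sum())


@dataclass(frozen=True)
class FetalFraction:
    """Fixed or uniform fetal-fraction distribution on (0, 1)."""

    kind: str  # "fixed" | "uniform"
    value: float | None = None
    low: float | None = None
    high: float | None = None

    @classmethod
    def fixed(cls, f: float) -> "FetalFraction":
        # f = 0 is allowed as the zero-signal limit used in null studies.
        if not 0.0 <= f < 1.0:
            raise ConfigurationError("fetal fraction must be in [0, 1)")
        return cls("fixed", value=f)

    @classmethod
    def uniform(cls, low: float, high: float) -> "FetalFraction":
        if not (0.0 < low <= high < 1.0):
            raise ConfigurationError("need 0 < low <= high < 1")
        return cls("uniform", low=low, high=high)

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return float(self.value)
        return float(rng.uniform(self.low, self.high))


def _default_n_per_class() -> dict[str, int]:
    # Composition of the original 144-sample cohort.
    return {"T13": 21, "T18": 27, "T21": 36, "euploid": 60}


@dataclass(frozen=True)
class CohortSimConfig:
    """Full parameterization of the synthetic cohort generator.

    Defaults are the study conditions used throughout the test suite:
    the original cohort's class composition, 5x10^5 expected fragments per
    sample, fetal fraction uniform on [0.08, 0.15], length modes 166/143 bp
    with scale 9, and a 1.5x trisomy dosage.
    """

    n_per_class: dict[str, int] = field(default_factory=_default_n_per_class)
    depth: int = 500_000
    baseline_props: dict[str, float] | None = None
    fetal_fraction: FetalFraction = FetalFraction.uniform(0.08, 0.15)
    maternal_length_dist: LengthDistribution = (
        LengthDistribution.discretized_normal(166.0, 9.0)
    )
    fetal_length_dist: LengthDistribution = (
        LengthDistribution.discretized_normal(143.0, 9.0)
    )
    trisomy_dosage: float = 1.5
    #: total sex-chromosome weight per origin, relative to autosomal weight 1
    sex_chrom_weight: float = 0.05
    #: SD of per-sample per-chromosome lognormal weight jitter (0 = pure
    #: multinomial counting noise)
    overdispersion_sigma: float = 0.0
    counting: str = "multinomial"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigurationError("depth must be > 0")
        if self.trisomy_dosage <= 0:
            raise ConfigurationError("trisomy_dosage must be > 0")
        if self.counting not in ("multinomial", "poisson"):
            raise ConfigurationError(f"unknown counting {self.counting!r}")
        props = self.resolved_baseline()
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigurationError("baseline_props must sum to 1")
        for label in self.n_per_class:
            if label not in ("T13", "T18", "T21", "euploid"):
                raise ConfigurationError(f"unknown class label {label!r}")

    def resolved_baseline(self) -> dict[str, float]:
        return self.baseline_props or default_baseline_props()

    def with_seed(self, seed: int) -> "CohortSimConfig":
        return replace(self, seed=seed)


def _fetal_autosome_weights(
    baseline: np.ndarray, label: str, dosage: float
) -> np.ndarray:
    """Fetal autosome weights: dosage applied to the affected chromosome,
    renormalized (identity for euploid)."""
    w = baseline.copy()
    if label in LABEL_TO_CHROM:
        idx = AUTOSOMES.index(LABEL_TO_CHROM[label])
        w[idx] *= dosage
        w = w / w.sum()
    return w


def simulate_sample(
    config: CohortSimConfig,
    label: str,
    rng: np.random.Generator,
    sample_id: str | None = None,
) -> SampleRecord:
    """Draw one sample's fragment-size histogram.

    The cell intensity for (chromosome c, origin o, length l) is
    ``mix(o) * chrom_weight(o, c) * length_pmf(o, l)`` with
    ``mix = (1-f, f)``; counts are one multinomial draw of ``depth`` over
    all cells (or independent Poissons when configured).
    """
    if label not in ("T13", "T18", "T21", "euploid"):
        raise ConfigurationError(f"invalid sample label {label!r}")

    baseline = np.array(
        [config.resolved_baseline()[c] for c in AUTOSOMES], dtype=float
    )
    f = config.fetal_fraction.draw(rng)
    fetal_sex = rng.choice(["female", "male"])

    w = config.sex_chrom_weight
    maternal_chrom = np.concatenate([baseline, [w, 0.0]])  # + chrX, chrY
    fetal_auto = _fetal_autosome_weights(baseline, label, config.trisomy_dosage)
    if fetal_sex == "female":
        fetal_chrom = np.concatenate([fetal_auto, [w, 0.0]])
    else:
        fetal_chrom = np.concatenate([fetal_auto, [w / 2.0, w / 2.0]])

    if config.overdispersion_sigma > 0:
        # Sample-level technical bias: the same multiplicative factor per
        # chromosome hits both origins.
        jitter = np.exp(
            rng.normal(0.0, config.overdispersion_sigma, size=len(maternal_chrom))
        )
        maternal_chrom = maternal_chrom * jitter
        fetal_chrom = fetal_chrom * jitter
    maternal_chrom = maternal_chrom / maternal_chrom.sum()
    fetal_chrom = fetal_chrom / fetal_chrom.sum()

    support = (
        min(min(config.maternal_length_dist.lengths),
            min(config.fetal_length_dist.lengths)),
        max(max(config.maternal_length_dist.lengths),
            max(config.fetal_length_dist.lengths)),
    )
    pmf_m = config.maternal_length_dist.on_support(support)
    pmf_f = config.fetal_length_dist.on_support(support)

    # (chrom, length) intensity matrix, origins summed.
    cells = (1.0 - f) * np.outer(maternal_chrom, pmf_m) + f * np.outer(
        fetal_chrom, pmf_f
    )
    p = cells.ravel()
    p = p / p.sum()

    if config.counting == "multinomial":
        counts = rng.multinomial(config.depth, p)
    else:
        counts = rng.poisson(config.depth * p)
    counts = counts.reshape(cells.shape)

    chroms = AUTOSOMES + ("chrX", "chrY")
    lengths = np.arange(support[0], support[1] + 1)
    nz_c, nz_l = np.nonzero(counts)
    record_counts = {
        (chroms[ci], int(lengths[li])): int(counts[ci, li])
        for ci, li in zip(nz_c, nz_l)
    }
    sid = sample_id or f"{label}_sample"
    return SampleRecord(sid, label, record_counts)


def simulate_cohort(config: CohortSimConfig) -> SizeDistributionTable:
    """Simulate a labelled cohort, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    samples = []
    for label in ("T13", "T18", "T21", "euploid"):
        for i in range(config.n_per_class.get(label, 0)):
            samples.append(
                simulate_sample(config, label, rng, f"{label}_{i:03d}")
            )
    table = SizeDistributionTable(samples)
    table.validate()
    return table


def expected_statistic(
    config: CohortSimConfig,
    label: str,
    statistic_kind: str,
    size_range,
    target: str,
) -> float:
    """Closed-form expectation of a statistic under the generative model.

    Per autosome c the expected in-window intensity is

        m(c) = (1-f) * Lm * b(c) + f * Lf * b_fet(c)

    with Lm/Lf the window masses of the two length distributions and
    b_fet the dosage-adjusted fetal weights. The proportion expectation is
    m(target)/sum_autosomes m (exact for multinomial counting, conditional
    on the autosome total); the ratio expectation is
    m(target)/sum_other m (the large-depth limit of the count quotient).

    Requires a fixed fetal fraction and zero overdispersion; anything else
    has no single closed form and raises.
    """
    if config.fetal_fraction.kind != "fixed":
        raise ConfigurationError(
            "expected_statistic requires a fixed fetal fraction"
        )
    if config.overdispersion_sigma != 0.0:
        raise ConfigurationError(
            "expected_statistic requires overdispersion_sigma = 0"
        )
    if label not in ("T13", "T18", "T21", "euploid"):
        raise ConfigurationError(f"invalid label {label!r}")

    f = float(config.fetal_fraction.value)
    baseline = np.array(
        [config.resolved_baseline()[c] for c in AUTOSOMES], dtype=float
    )
    b_fet = _fetal_autosome_weights(baseline, label, config.trisomy_dosage)
    lm = config.maternal_length_dist.mass(size_range.lower_bp, size_range.upper_bp)
    lf = config.fetal_length_dist.mass(size_range.lower_bp, size_range.upper_bp)

    m = (1.0 - f) * lm * baseline + f * lf * b_fet
    if statistic_kind == "proportion":
        return float(m[AUTOSOMES.index(target)] / m.sum())
    if statistic_kind == "ratio":
        other = sum(m[AUTOSOMES.index(c)] for c in OTHER_AUTOSOMES)
        return float(m[AUTOSOMES.index(target)] / other)
    raise ConfigurationError(f"unknown statistic_kind {statistic_kind!r}")
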