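"""Forensic parameter estimation for Y-STR data.

All estimators are evaluated in exact rational arithmetic and rounded
half-up only for display, so recomputation of published 4-decimal tables
is deterministic.

Counting conventions (validated against a published 100-male Uyghur
dataset bundled with the package):

* every value of a duplicated call contributes one allele count, so the
  total number of allele observations ``n`` at a locus can exceed the
  number of sampled males (e.g. 101 copies at a locus where one man
  carries a duplication);
* a null call contributes one count to a distinct class ``"null"``;
* the (n-1)-bias factor of Nei's gene-diversity estimator uses the
  number of sampled individuals, while the squared frequencies are taken
  over all allele copies.  For ordinary single-copy loci the two numbers
  coincide.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from math import sqrt
from typing import Mapping, Optional, Sequence

from .errors import EstimatorError
from .haplotypes import (
    PanelDefinition,
    PopulationSample,
    canonical_key,
    project_panel,
)

__all__ = [
    "FrequencyTable",
    "HaplotypeSpectrum",
    "allele_frequencies",
    "pair_frequencies",
    "gene_diversity_exact",
    "gene_diversity",
    "haplotype_spectrum",
    "spectrum_from_counts",
    "haplotype_diversity",
    "haplotype_diversity_se",
    "match_probability",
    "discrimination_capacity",
    "proportion_unique",
    "forensic_report",
    "locus_report",
    "round4",
]


def round4(x: Fraction | float, places: int = 4) -> float:
    """Round half-up to ``places`` decimals (exact for rational input)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-places)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencyTable:
    """Allele counts and relative frequencies at one locus.

    ``n`` is the total number of allele observations (copies);
    ``n_samples`` is the number of individuals the copies came from, used
    by the bias factor of :func:`gene_diversity`.  When ``n_samples`` is
    None the estimator falls back to ``n`` (per-copy convention, e.g. for
    the multi-copy locus DYS385a/b).
    """

    locus: str
    counts: Mapping[str, int]
    n: int
    n_samples: Optional[int] = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.locus}: negative count")
        if sum(self.counts.values()) != self.n:
            raise ValueError(f"{self.locus}: counts do not sum to n={self.n}")

    @property
    def freqs(self) -> dict[str, Fraction]:
        return {a: Fraction(c, self.n) for a, c in self.counts.items()}


def allele_frequencies(sample: PopulationSample, locus: str) -> FrequencyTable:
    """Direct-counting allele frequencies at one locus."""
    if locus not in sample.panel.loci:
        raise KeyError(f"locus {locus!r} not in panel {sample.panel.name}")
    counts: Counter[str] = Counter()
    for h in sample.haplotypes:
        call = h.calls[locus]
        if call.state == "null":
            counts["null"] += 1
        else:
            for value in call.values:
                counts[_class_key(value)] += 1
    n = sum(counts.values())
    # multi-copy loci use the per-copy convention: bias factor over copies
    ns = None if locus in sample.panel.multi_copy else sample.n
    return FrequencyTable(locus, dict(counts), n, n_samples=ns)


def pair_frequencies(sample: PopulationSample, locus: str) -> FrequencyTable:
    """Frequencies of sorted value-multisets (per-pair convention for
    multi-copy loci such as DYS385a/b); n equals the sample count."""
    if locus not in sample.panel.loci:
        raise KeyError(f"locus {locus!r} not in panel {sample.panel.name}")
    counts: Counter[str] = Counter(
        h.calls[locus].to_text() for h in sample.haplotypes
    )
    return FrequencyTable(locus, dict(counts), sample.n, n_samples=sample.n)


def _class_key(value) -> str:
    from .haplotypes import format_repeat

    return format_repeat(value)


def gene_diversity(ft: FrequencyTable) -> float:
    """Nei's unbiased gene diversity n(1 - sum p_i^2)/(n - 1)."""
    return float(gene_diversity_exact(ft))


def gene_diversity_exact(ft: FrequencyTable) -> Fraction:
    ns = ft.n_samples if ft.n_samples is not None else ft.n
    if ns < 2 or ft.n < 2:
        raise EstimatorError(
            f"{ft.locus}: gene diversity undefined for n={ft.n}"
        )
    sum_p2 = sum(Fraction(c, ft.n) ** 2 for c in ft.counts.values())
    return Fraction(ns, ns - 1) * (1 - sum_p2)


@dataclass(frozen=True)
class HaplotypeSpectrum:
    """Multiplicity spectrum of distinct haplotypes under one panel."""

    panel: str
    counts: Mapping[str, int]
    n: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n:
            raise ValueError("spectrum counts do not sum to n")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("spectrum counts must be positive")

    @property
    def k(self) -> int:
        """Number of distinct haplotypes."""
        return len(self.counts)

    @property
    def u(self) -> int:
        """Number of haplotypes observed exactly once."""
        return sum(1 for c in self.counts.values() if c == 1)


def haplotype_spectrum(
    sample: PopulationSample, panel: Optional[PanelDefinition] = None
) -> HaplotypeSpectrum:
    """Spectrum over canonical haplotype keys after projecting to ``panel``."""
    panel = panel or sample.panel
    projected = project_panel(sample, panel)
    counts = Counter(canonical_key(h, panel) for h in projected.haplotypes)
    return HaplotypeSpectrum(panel.name, dict(counts), projected.n)


def spectrum_from_counts(counts: Sequence[int], panel: str = "") -> HaplotypeSpectrum:
    """Build a spectrum directly from a list of multiplicities."""
    return HaplotypeSpectrum(
        panel, {f"h{i}": int(c) for i, c in enumerate(counts)}, int(sum(counts))
    )


def _require_n(s: HaplotypeSpectrum, minimum: int) -> None:
    if s.n < minimum:
        raise EstimatorError(f"estimator undefined for spectrum of size {s.n}")


def haplotype_diversity(s: HaplotypeSpectrum) -> float:
    """HD = n(1 - sum p_i^2)/(n - 1) over haplotype frequencies."""
    _require_n(s, 2)
    return float(Fraction(s.n, s.n - 1) * (1 - _sum_p2(s)))


def match_probability(s: HaplotypeSpectrum) -> float:
    """MP = sum p_i^2, probability that two random samples match."""
    _require_n(s, 1)
    return float(_sum_p2(s))


def _sum_p2(s: HaplotypeSpectrum) -> Fraction:
    return sum(Fraction(c, s.n) ** 2 for c in s.counts.values())


def discrimination_capacity(s: HaplotypeSpectrum) -> float:
    _require_n(s, 1)
    return float(Fraction(s.k, s.n))


def proportion_unique(s: HaplotypeSpectrum) -> float:
    _require_n(s, 1)
    return float(Fraction(s.u, s.n))


def haplotype_diversity_se(s: HaplotypeSpectrum) -> float:
    """Standard error of HD via Nei's (1987) variance of heterozygosity.

    V(H) = 2/(n(n-1)) * { 2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2 }
    """
    _require_n(s, 2)
    n = s.n
    p2 = _sum_p2(s)
    p3 = sum(Fraction(c, n) ** 3 for c in s.counts.values())
    var = Fraction(2, n * (n - 1)) * (2 * (n - 2) * (p3 - p2**2) + p2 - p2**2)
    return sqrt(float(max(var, Fraction(0))))


def forensic_report(
    sample: PopulationSample, panels: Sequence[PanelDefinition]
) -> list[dict]:
    """One row of forensic parameters per panel (n, k, u, PUH, MP, DC, HD, SE)."""
    rows = []
    for panel in panels:
        s = haplotype_spectrum(sample, panel)
        rows.append(
            {
                "panel": panel.name,
                "n": s.n,
                "k": s.k,
                "u": s.u,
                "PUH": proportion_unique(s),
                "MP": match_probability(s),
                "DC": discrimination_capacity(s),
                "HD": haplotype_diversity(s),
                "SE": haplotype_diversity_se(s),
            }
        )
    return rows


def locus_report(sample: PopulationSample) -> list[dict]:
    """Per-locus allele frequencies and gene diversity."""
    rows = []
    for locus in sample.panel.loci:
        ft = allele_frequencies(sample, locus)
        row = {
            "locus": locus,
            "n": ft.n,
            "GD": round4(gene_diversity_exact(ft)),
            "frequencies": {a: round4(f) for a, f in sorted(ft.freqs.items())},
        }
        if locus in sample.panel.multi_copy:
            row["GD_pairs"] = round4(
                gene_diversity_exact(pair_frequencies(sample, locus))
            )
        rows.append(row)
    return rows
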