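"""Forward stepwise-mutation simulation of multi-population Y-STR data.

The model is deliberately simple: independent lineages under symmetric
+/-1 stepwise mutation with a reflecting floor at 1 repeat, a population
split tree for shared drift, optional admixture draws and injected
typing anomalies (null / duplication / intermediate alleles).  It exists
to exercise the R_ST / ordination / discriminant machinery with known
structure, not to be demographically realistic.

Each population's founder lineage accumulates shared drift from the root
(or from its parent at the split generation) until ``generations -
within_generations``; individuals then mutate independently for the last
``within_generations`` generations.  Divergence between populations
therefore grows with total ``generations`` while within-population
diversity stays roughly constant.

Marginal resampling (:func:`resample_from_marginals`) draws each locus
independently from published allele-frequency tables; this destroys
haplotype linkage, so haplotype-level parameters (HD/MP/DC) of resampled
data are not comparable to published haplotype tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError, SamplingError, ValidationError
from .forensic import FrequencyTable
from .haplotypes import (
    AlleleCall,
    Haplotype,
    PanelDefinition,
    PopulationSample,
    get_panel,
    parse_allele,
)

__all__ = [
    "SimConfig",
    "simulate_smm",
    "admix",
    "inject_anomalies",
    "resample_from_marginals",
]


@dataclass
class SimConfig:
    panel: PanelDefinition
    mutation_rate: float = 0.002
    generations: int = 100
    within_generations: int = 10
    # (parent, child, split_generation); root population springs from "" at 0
    splits: tuple[tuple[str, str, int], ...] = ()
    sizes: Mapping[str, int] = field(default_factory=dict)
    anomaly_rates: Mapping[str, float] = field(default_factory=dict)
    ancestral_repeat: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.panel.loci:
            raise ConfigError("panel has no loci")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation rate must be in [0,1]")
        for key, rate in self.anomaly_rates.items():
            if key not in ("null", "duplication", "intermediate"):
                raise ConfigError(f"unknown anomaly rate {key!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("anomaly rates must be in [0,1]")
        for pop, n in self.sizes.items():
            if n < 0:
                raise ConfigError(f"population size of {pop!r} must be >= 0")
        if self.generations < 0 or self.within_generations < 0:
            raise ConfigError("generation counts must be >= 0")

    @staticmethod
    def from_yaml(path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        panel = raw.pop("panel")
        if isinstance(panel, str):
            panel_def = get_panel(panel)
        else:
            loci = tuple(panel["loci"])
            panel_def = PanelDefinition(
                panel.get("name", "custom"),
                loci,
                frozenset(panel.get("multi_copy", ())),
            )
        raw["splits"] = tuple(tuple(s) for s in raw.get("splits", ()))
        return SimConfig(panel=panel_def, **raw)


def _mutate(sizes: np.ndarray, gens: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an integer repeat-size array in place for ``gens`` generations."""
    if rate == 0.0 or gens == 0:
        return sizes
    for _ in range(gens):
        hit = rng.random(sizes.shape) < rate
        step = rng.integers(0, 2, size=sizes.shape) * 2 - 1
        sizes = sizes + hit * step
        below = sizes < 1
        if below.any():
            sizes[below] = 2 - sizes[below]  # reflect at the 1-repeat floor
    return sizes


def _founding_order(config: SimConfig) -> list[tuple[str, Optional[str], int]]:
    children = {child for _, child, _ in config.splits}
    names = list(
        dict.fromkeys(
            [p for p, _, _ in ((parent, None, None) for parent, _, _ in config.splits)]
            + [child for _, child, _ in config.splits]
            + list(config.sizes)
        )
    )
    roots = [p for p in names if p not in children]
    order: list[tuple[str, Optional[str], int]] = [(p, None, 0) for p in roots]
    order += [(child, parent, gen) for parent, child, gen in config.splits]
    order.sort(key=lambda item: item[2])
    return order


def simulate_smm(config: SimConfig) -> list[PopulationSample]:
    """Simulate one haplotype table under the configured split topology."""
    rng = np.random.default_rng(config.seed)
    loci = config.panel.loci
    multi = config.panel.multi_copy
    copies = [2 if l in multi else 1 for l in loci]
    width = sum(copies)  # multi-copy loci carry two size columns
    shared_until = max(config.generations - config.within_generations, 0)

    order = _founding_order(config)
    known = {name for name, _, _ in order}
    for pop in config.sizes:
        if pop not in known:
            raise ConfigError(f"population {pop!r} has a size but no founding event")

    # founder lineages: advance parents lazily so a child copies its
    # parent's state exactly at the split generation
    state: dict[str, np.ndarray] = {}
    time: dict[str, int] = {}

    def advance(pop: str, until: int) -> None:
        gens = min(until, shared_until) - time[pop]
        if gens > 0:
            state[pop] = _mutate(state[pop], gens, config.mutation_rate, rng)
            time[pop] = min(until, shared_until)

    for name, parent, gen in order:
        if parent is None:
            state[name] = np.full(width, config.ancestral_repeat, dtype=np.int64)
            time[name] = min(gen, shared_until)
        else:
            if parent not in state:
                raise ConfigError(
                    f"split parent {parent!r} founded after child {name!r}"
                )
            advance(parent, gen)
            state[name] = state[parent].copy()
            time[name] = time[parent]

    samples: list[PopulationSample] = []
    for name, _, _ in order:
        advance(name, shared_until)
        n = config.sizes.get(name, 0)
        indep = config.generations - shared_until
        block = (
            np.tile(state[name], (n, 1)) if n else np.empty((0, width), dtype=np.int64)
        )
        block = _mutate(block, indep, config.mutation_rate, rng)
        haps = [
            Haplotype(f"{name}_{i}", _calls_from_row(block[i], loci, copies))
            for i in range(n)
        ]
        sample = PopulationSample(name, config.panel, haps)
        if config.anomaly_rates:
            sample = inject_anomalies(
                sample, config.anomaly_rates, seed=int(rng.integers(2**31))
            )
        samples.append(sample)
    return samples


def _calls_from_row(
    row: np.ndarray, loci: Sequence[str], copies: Sequence[int]
) -> dict[str, AlleleCall]:
    calls = {}
    col = 0
    for locus, c in zip(loci, copies):
        if c == 1:
            calls[locus] = AlleleCall.numeric(int(row[col]))
        else:
            calls[locus] = AlleleCall.duplicated(
                [int(v) for v in row[col : col + c]]
            )
        col += c
    return calls


def admix(
    popA: PopulationSample,
    popB: PopulationSample,
    alpha: float,
    n: int,
    seed: int = 0,
) -> PopulationSample:
    """Draw n haplotypes, each copied from popA with probability alpha,
    otherwise from popB."""
    if popA.panel.loci != popB.panel.loci:
        raise ValidationError("admixture sources must share a panel")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0,1]")
    rng = np.random.default_rng(seed)
    haps = []
    for i in range(n):
        source = popA if rng.random() < alpha else popB
        if source.n == 0:
            raise SamplingError(f"source population {source.population!r} is empty")
        donor = source.haplotypes[rng.integers(source.n)]
        haps.append(Haplotype(f"admixed_{i}", dict(donor.calls)))
    return PopulationSample("admixed", popA.panel, haps)


def inject_anomalies(
    sample: PopulationSample,
    rates: Mapping[str, float],
    seed: int = 0,
) -> PopulationSample:
    """Independently convert (sample, locus) calls into anomalies.

    Per call, with the given probabilities: become null; gain a
    duplicated second value at original +/-1; or gain a 0.1 partial
    repeat.  Multi-copy loci are left untouched.
    """
    p_null = rates.get("null", 0.0)
    p_dup = rates.get("duplication", 0.0)
    p_int = rates.get("intermediate", 0.0)
    if min(p_null, p_dup, p_int) < 0 or p_null + p_dup + p_int > 1:
        raise ValidationError("anomaly rates must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    haps = []
    for h in sample.haplotypes:
        calls = dict(h.calls)
        for locus in sample.panel.loci:
            if locus in sample.panel.multi_copy:
                continue
            call = calls[locus]
            if call.state != "numeric":
                continue
            u = rng.random()
            value = call.values[0]
            if u < p_null:
                calls[locus] = AlleleCall.null()
            elif u < p_null + p_dup:
                delta = 1 if rng.random() < 0.5 else -1
                second = max(value + delta, Fraction(1))
                if second == value:
                    second = value + 1
                calls[locus] = AlleleCall.duplicated([value, second])
            elif u < p_null + p_dup + p_int:
                calls[locus] = AlleleCall.intermediate(value + Fraction(1, 10))
        haps.append(Haplotype(h.sample_id, calls))
    return PopulationSample(sample.population, sample.panel, haps)


def resample_from_marginals(
    freq_tables: Sequence[FrequencyTable],
    n: int,
    seed: int = 0,
    population: str = "resample",
) -> PopulationSample:
    """Draw haplotypes locus-by-locus from marginal allele frequencies.

    Linkage between loci is NOT preserved, so only per-locus statistics
    of the output are meaningful.
    """
    loci = [ft.locus for ft in freq_tables]
    if len(set(loci)) != len(loci):
        raise ValidationError("duplicate loci among frequency tables")
    for ft in freq_tables:
        if sum(ft.freqs.values()) != 1:
            raise ValidationError(f"{ft.locus}: frequencies do not sum to 1")
    multi = frozenset(
        ft.locus for ft in freq_tables if any("," in a for a in ft.counts)
    )
    panel = PanelDefinition("marginals", tuple(loci), multi)
    rng = np.random.default_rng(seed)
    draws: dict[str, list[str]] = {}
    for ft in freq_tables:
        alleles = sorted(ft.counts)
        probs = np.array([ft.counts[a] for a in alleles], dtype=float)
        probs /= probs.sum()
        draws[ft.locus] = [alleles[i] for i in rng.choice(len(alleles), size=n, p=probs)]
    haps = []
    for i in range(n):
        calls = {
            locus: parse_allele(draws[locus][i], locus) for locus in loci
        }
        haps.append(Haplotype(f"{population}_{i}", calls))
    return PopulationSample(population, panel, haps)
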