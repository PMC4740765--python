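"""Pairwise R_ST and AMOVA on squared repeat-size differences.

The molecular distance between two haplotypes is the sum over included
single-copy loci of the squared difference in repeat size (the stepwise
mutation convention behind R_ST).  Loci where either call is null or
duplicated are dropped pairwise, with no renormalization — the sums stay
additive, which is what the SSD decomposition assumes.  The multi-copy
locus DYS385a/b is excluded by default; an optional policy pairs the
sorted values and adds both squared differences.

Variance components follow the standard two- and three-level AMOVA
moment equations with unequal sample sizes; Phi statistics may be
negative and are reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import (
    DegreesOfFreedomError,
    EmptyComparisonError,
    ValidationError,
)
from .haplotypes import Haplotype, PanelDefinition, PopulationSample

__all__ = [
    "DistancePolicy",
    "HaplotypeDistance",
    "AmovaResult",
    "GroupedAmovaResult",
    "DistanceMatrix",
    "haplotype_distance",
    "individual_distance_matrix",
    "amova_two_level",
    "amova_grouped",
    "pairwise_rst",
    "permutation_p",
]


@dataclass(frozen=True)
class DistancePolicy:
    """How non-standard calls enter the squared-size distance."""

    include_multi_copy: bool = False  # pair sorted DYS385a/b values if True
    # null and duplicated calls at single-copy loci are always dropped pairwise


@dataclass(frozen=True)
class HaplotypeDistance:
    value: float
    included_loci: tuple[str, ...]


def _locus_term(call1, call2, multi: bool, policy: DistancePolicy):
    """Return the squared-difference contribution or None to skip the locus."""
    if multi:
        if not policy.include_multi_copy:
            return None
        if call1.state == "null" or call2.state == "null":
            return None
        if len(call1.values) != len(call2.values):
            return None
        return float(
            sum((float(a) - float(b)) ** 2 for a, b in zip(call1.values, call2.values))
        )
    if call1.state in ("null", "duplicated") or call2.state in ("null", "duplicated"):
        return None
    return (float(call1.values[0]) - float(call2.values[0])) ** 2


def haplotype_distance(
    h1: Haplotype,
    h2: Haplotype,
    panel: PanelDefinition,
    policy: DistancePolicy = DistancePolicy(),
) -> HaplotypeDistance:
    total = 0.0
    included: list[str] = []
    for locus in panel.loci:
        term = _locus_term(
            h1.calls[locus], h2.calls[locus], locus in panel.multi_copy, policy
        )
        if term is None:
            continue
        total += term
        included.append(locus)
    if not included:
        raise EmptyComparisonError(
            f"no comparable loci between {h1.sample_id} and {h2.sample_id}"
        )
    return HaplotypeDistance(total, tuple(included))


def individual_distance_matrix(
    pops: Sequence[PopulationSample],
    policy: DistancePolicy = DistancePolicy(),
) -> tuple[np.ndarray, list[int]]:
    """Squared-size distances between all individuals of all populations.

    Returns (N x N matrix, per-population sizes); individuals are ordered
    population by population.
    """
    panel = pops[0].panel
    for p in pops[1:]:
        if p.panel.loci != panel.loci:
            raise ValidationError("all populations must share a panel")
    haps = [h for p in pops for h in p.haplotypes]
    sizes = [p.n for p in pops]
    n = len(haps)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haplotype_distance(haps[i], haps[j], panel, policy).value
            D[i, j] = D[j, i] = d
    return D, sizes


@dataclass
class AmovaResult:
    sigma2_among: float
    sigma2_within: float
    phi: float
    df_among: int
    df_within: int
    p_value: Optional[float] = None


@dataclass
class GroupedAmovaResult:
    sigma2_among_groups: float
    sigma2_among_pops: float
    sigma2_within: float
    phi_ct: float  # among groups / total
    phi_sc: float  # among pops / (within groups)
    phi_st: float  # (among groups + among pops) / total
    df_among_groups: int
    df_among_pops: int
    df_within: int
    p_value: Optional[float] = None


def _ssd(D: np.ndarray, idx: np.ndarray) -> float:
    """SSD of a group: sum of pairwise distances divided by group size."""
    sub = D[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def _phi(num: float, den: float) -> float:
    return 0.0 if den == 0 else num / den


def _amova_from_matrix(D: np.ndarray, labels: np.ndarray) -> AmovaResult:
    pops = list(dict.fromkeys(labels.tolist()))
    N = len(labels)
    P = len(pops)
    if N <= P:
        raise DegreesOfFreedomError(f"N={N} individuals <= P={P} populations")
    all_idx = np.arange(N)
    ssd_total = _ssd(D, all_idx)
    sizes = []
    ssd_within = 0.0
    for pop in pops:
        idx = np.flatnonzero(labels == pop)
        sizes.append(len(idx))
        ssd_within += _ssd(D, idx)
    ssd_among = ssd_total - ssd_within
    df_among, df_within = P - 1, N - P
    msd_among = ssd_among / df_among
    msd_within = ssd_within / df_within if df_within else 0.0
    sizes_arr = np.asarray(sizes, dtype=float)
    n_bar = (N - (sizes_arr**2).sum() / N) / (P - 1)
    sigma_within = msd_within
    sigma_among = (msd_among - msd_within) / n_bar
    phi = _phi(sigma_among, sigma_among + sigma_within)
    return AmovaResult(sigma_among, sigma_within, phi, df_among, df_within)


def amova_two_level(pops: Sequence[PopulationSample], policy: DistancePolicy = DistancePolicy()) -> AmovaResult:
    """Two-level AMOVA (among vs within populations) on squared-size distances."""
    if len(pops) < 2:
        raise DegreesOfFreedomError("need at least two populations")
    D, sizes = individual_distance_matrix(pops, policy)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return _amova_from_matrix(D, labels)


def amova_grouped(
    pops: Sequence[PopulationSample],
    grouping: Mapping[str, str],
    policy: DistancePolicy = DistancePolicy(),
) -> GroupedAmovaResult:
    """Three-level AMOVA: among groups / among populations within groups /
    within populations."""
    groups = list(dict.fromkeys(grouping[p.population] for p in pops))
    if len(groups) < 2:
        raise DegreesOfFreedomError(
            "grouping defines a single group; use amova_two_level"
        )
    D, sizes = individual_distance_matrix(pops, policy)
    pop_labels = np.repeat(np.arange(len(pops)), sizes)
    group_of_pop = np.asarray(
        [groups.index(grouping[p.population]) for p in pops]
    )
    return _grouped_from_matrix(D, pop_labels, group_of_pop)


def _grouped_from_matrix(
    D: np.ndarray, pop_labels: np.ndarray, group_of_pop: np.ndarray
) -> GroupedAmovaResult:
    N = len(pop_labels)
    P = int(pop_labels.max()) + 1
    G = int(group_of_pop.max()) + 1
    group_labels = group_of_pop[pop_labels]
    if N <= P:
        raise DegreesOfFreedomError(f"N={N} individuals <= P={P} populations")
    ssd_total = _ssd(D, np.arange(N))
    ssd_within = sum(
        _ssd(D, np.flatnonzero(pop_labels == p)) for p in range(P)
    )
    ssd_groups = sum(
        _ssd(D, np.flatnonzero(group_labels == g)) for g in range(G)
    )
    ssd_among_pops = ssd_groups - ssd_within
    ssd_among_groups = ssd_total - ssd_groups
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    msd_ag = ssd_among_groups / df_ag
    msd_ap = ssd_among_pops / df_ap if df_ap else 0.0
    msd_wp = ssd_within / df_wp if df_wp else 0.0
    sizes = np.bincount(pop_labels, minlength=P).astype(float)
    gsizes = np.bincount(group_labels, minlength=G).astype(float)
    # unequal-size coefficients of the three-level moment equations
    sum_sq_by_group = np.zeros(G)
    for p in range(P):
        sum_sq_by_group[group_of_pop[p]] += sizes[p] ** 2
    n1 = (N - (sum_sq_by_group / gsizes).sum()) / (P - G) if P > G else 1.0
    n2 = (
        ((sum_sq_by_group / gsizes).sum() - (sizes**2).sum() / N) / (G - 1)
    )
    n3 = (N - (gsizes**2).sum() / N) / (G - 1)
    sigma_c = msd_wp
    sigma_b = (msd_ap - sigma_c) / n1 if P > G else 0.0
    sigma_a = (msd_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    return GroupedAmovaResult(
        sigma2_among_groups=sigma_a,
        sigma2_among_pops=sigma_b,
        sigma2_within=sigma_c,
        phi_ct=_phi(sigma_a, total),
        phi_sc=_phi(sigma_b, sigma_b + sigma_c),
        phi_st=_phi(sigma_a + sigma_b, total),
        df_among_groups=df_ag,
        df_among_pops=df_ap,
        df_within=df_wp,
    )


@dataclass
class DistanceMatrix:
    """Symmetric labeled dissimilarity matrix (zero diagonal)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix must have a zero diagonal")
        if not np.isfinite(v).all():
            raise ValidationError("distance matrix must be finite")
        self.values = v

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(("", *self.labels)) + "\n")
            for label, row in zip(self.labels, self.values):
                fh.write("\t".join((label, *(repr(float(x)) for x in row))) + "\n")

    @staticmethod
    def from_tsv(path: str | Path) -> "DistanceMatrix":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                if line.strip():
                    rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
        return DistanceMatrix(tuple(header), np.asarray(rows))


def pairwise_rst(
    pops: Sequence[PopulationSample], policy: DistancePolicy = DistancePolicy()
) -> DistanceMatrix:
    """Matrix of two-level AMOVA Phi (R_ST) for every population pair.

    Negative values are retained; downstream consumers decide whether to
    clamp.
    """
    if len(pops) < 2:
        raise DegreesOfFreedomError("need at least two populations")
    labels = tuple(p.population for p in pops)
    if len(set(labels)) != len(labels):
        raise ValidationError("population names must be unique")
    m = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            res = amova_two_level([pops[i], pops[j]], policy)
            m[i, j] = m[j, i] = res.phi
    return DistanceMatrix(labels, m)


def permutation_p(
    pops: Sequence[PopulationSample],
    n_perm: int = 10_000,
    seed: int = 0,
    policy: DistancePolicy = DistancePolicy(),
) -> float:
    """Permutation p-value for the two-level Phi.

    Individuals are randomly reassigned to populations preserving sample
    sizes; p = (1 + #{perm Phi >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    D, sizes = individual_distance_matrix(pops, policy)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    observed = _amova_from_matrix(D, labels).phi
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _amova_from_matrix(D, perm).phi >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
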