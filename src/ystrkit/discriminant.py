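"""Multi-class linear discriminant analysis on Y-STR repeat sizes.

Markers are screened first: multi-copy loci (DYS385a/b) and the
DYS389I/II pair are excluded structurally, and any locus showing null or
duplication calls in more than one sample (pooled over populations) is
dropped — a locus with a single anomalous sample is retained.  Allele
sizes then enter the analysis as plain numeric repeat counts
(intermediate alleles as decimals); samples with remaining anomalies at
retained markers are dropped listwise with a logged count.

The axes solve the generalized eigenproblem of between-class versus
within-class scatter.  A singular within-class scatter is handled by a
small ridge (lambda = 1e-8 * trace/dim) with a warning.  Factor signs
are fixed so the loading of the first marker (panel order) on each
factor is non-negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .errors import MarkerSelectionError, ValidationError
from .haplotypes import PopulationSample

__all__ = [
    "LdaModel",
    "FactorScores",
    "select_lda_markers",
    "fit_lda",
    "transform",
    "variable_factor_correlations",
]

logger = logging.getLogger(__name__)

_STRUCTURAL_EXCLUSIONS = {"DYS389I", "DYS389II"}


def select_lda_markers(pops: Sequence[PopulationSample]) -> list[str]:
    """Apply the marker exclusion rule; returns survivors in panel order."""
    panel = pops[0].panel
    for p in pops[1:]:
        if p.panel.loci != panel.loci:
            raise ValidationError("all populations must share a panel")
    anomalous_samples: dict[str, int] = {l: 0 for l in panel.loci}
    for p in pops:
        for h in p.haplotypes:
            for locus in panel.loci:
                if locus in panel.multi_copy:
                    continue
                if h.calls[locus].state in ("null", "duplicated"):
                    anomalous_samples[locus] += 1
    markers = [
        l
        for l in panel.loci
        if l not in panel.multi_copy
        and l not in _STRUCTURAL_EXCLUSIONS
        and anomalous_samples[l] <= 1
    ]
    if len(markers) < 2:
        raise MarkerSelectionError(
            f"only {len(markers)} markers survive exclusion"
        )
    return markers


def _numeric_matrix(
    pops: Sequence[PopulationSample], markers: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack numeric size vectors; returns (X, class labels, dropped count)."""
    rows, labels, dropped = [], [], 0
    for p in pops:
        for h in p.haplotypes:
            calls = [h.calls[m] for m in markers]
            if any(c.state in ("null", "duplicated") for c in calls):
                dropped += 1
                continue
            rows.append([float(c.values[0]) for c in calls])
            labels.append(p.population)
    if dropped:
        logger.info("LDA: dropped %d samples with anomalies at retained markers", dropped)
    return np.asarray(rows, dtype=float), np.asarray(labels), dropped


@dataclass
class LdaModel:
    markers: tuple[str, ...]
    class_labels: tuple[str, ...]
    axes: np.ndarray  # markers x factors
    eigenvalues: np.ndarray
    percent_discrimination: np.ndarray
    class_means: np.ndarray  # classes x markers
    grand_mean: np.ndarray
    scale: Optional[np.ndarray] = None  # per-marker std when standardized
    dropped: int = 0

    @property
    def n_factors(self) -> int:
        return self.axes.shape[1]


@dataclass
class FactorScores:
    labels: np.ndarray  # class label per sample
    scores: np.ndarray  # samples x factors


def fit_lda(
    pops: Sequence[PopulationSample],
    markers: Sequence[str],
    standardize: bool = False,
) -> LdaModel:
    """Fit multi-class LDA of population labels on repeat sizes."""
    X, y, dropped = _numeric_matrix(pops, markers)
    classes = tuple(dict.fromkeys(y.tolist()))
    if len(classes) < 2:
        raise ValidationError("need at least two classes")
    if X.shape[0] <= len(classes):
        raise ValidationError("need more samples than classes")
    grand = X.mean(axis=0)
    scale = None
    if standardize:
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        X = (X - grand) / scale + grand
    p = X.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means = np.zeros((len(classes), p))
    for ci, c in enumerate(classes):
        Xc = X[y == c]
        means[ci] = Xc.mean(axis=0)
        centered = Xc - means[ci]
        Sw += centered.T @ centered
        diff = (means[ci] - grand)[:, None]
        Sb += len(Xc) * (diff @ diff.T)
    # ridge-regularize a singular within-class scatter
    try:
        cond_bad = np.linalg.cond(Sw) > 1e12
    except np.linalg.LinAlgError:  # pragma: no cover
        cond_bad = True
    if cond_bad:
        lam = 1e-8 * np.trace(Sw) / p
        if lam == 0:
            lam = 1e-8
        Sw = Sw + lam * np.eye(p)
        warnings.warn("singular within-class scatter; ridge term added")
    eigval, eigvec = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    m = min(p, len(classes) - 1)
    eigval = np.clip(eigval[:m], 0.0, None)
    axes = eigvec[:, :m]
    # sign convention: first marker's loading non-negative on each factor
    for j in range(m):
        col = axes[:, j]
        pivot = next((v for v in col if abs(v) > 1e-12), 1.0)
        if pivot < 0:
            axes[:, j] = -col
    total = eigval.sum()
    percent = (
        eigval / total * 100.0 if total > 0 else np.full(m, 100.0 / m)
    )
    return LdaModel(
        markers=tuple(markers),
        class_labels=classes,
        axes=axes,
        eigenvalues=eigval,
        percent_discrimination=percent,
        class_means=means,
        grand_mean=grand,
        scale=scale,
        dropped=dropped,
    )


def transform(model: LdaModel, pops: Sequence[PopulationSample]) -> FactorScores:
    """Project samples on the model's factors (centered at the fit mean)."""
    X, y, _ = _numeric_matrix(pops, model.markers)
    Xc = X - model.grand_mean
    if model.scale is not None:
        Xc = Xc / model.scale
    return FactorScores(labels=y, scores=Xc @ model.axes)


def variable_factor_correlations(
    model: LdaModel, pops: Sequence[PopulationSample]
) -> np.ndarray:
    """Pearson correlation of each marker's sizes with each factor's scores.

    Zero-variance markers yield NaN in their row.
    """
    X, _, _ = _numeric_matrix(pops, model.markers)
    scores = transform(model, pops).scores
    out = np.full((len(model.markers), model.n_factors), np.nan)
    for i in range(len(model.markers)):
        xi = X[:, i]
        if np.std(xi) == 0:
            continue
        for j in range(model.n_factors):
            sj = scores[:, j]
            if np.std(sj) == 0:
                continue
            out[i, j] = float(np.corrcoef(xi, sj)[0, 1])
    return out
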