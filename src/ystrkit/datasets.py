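"""Bundled reference datasets.

``load_uyghur_frequencies`` returns the per-locus allele-count tables of
a published 26-locus Y-STR survey of 100 unrelated Uyghur males
(southern Xinjiang).  Counts were reconstructed from the published
4-decimal frequency columns; ``n`` is the number of allele copies
observed at the locus (101 at DYS19 and DYS449 because of duplication
variants, 186 at the multi-copy locus DYS385a/b, 100 elsewhere) and
``n_samples`` the number of sampled males.  The dataset also carries the
published gene-diversity value per locus for cross-checking.
"""

from __future__ import annotations

import json
from importlib import resources

from .forensic import FrequencyTable

__all__ = ["load_uyghur_frequencies", "published_gene_diversity"]

_RESOURCE = "uyghur26_frequencies.json"


def _raw() -> dict:
    with resources.files(__package__).joinpath("data", _RESOURCE).open() as fh:
        return json.load(fh)


def load_uyghur_frequencies() -> dict[str, FrequencyTable]:
    """Per-locus allele-count tables of the bundled Uyghur survey."""
    tables = {}
    for locus, entry in _raw().items():
        tables[locus] = FrequencyTable(
            locus=locus,
            counts={str(a): int(c) for a, c in entry["counts"].items()},
            n=int(entry["n"]),
            n_samples=entry["n_samples"],
        )
    return tables


def published_gene_diversity() -> dict[str, float]:
    """Gene diversity per locus as printed in the original survey."""
    return {locus: float(entry["gd_printed"]) for locus, entry in _raw().items()}
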