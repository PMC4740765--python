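from __future__ import annotations

from fractions import Fraction

import pytest

from ystrkit.haplotypes import (
    AlleleCall,
    Haplotype,
    PanelDefinition,
    PopulationSample,
    get_panel,
    parse_allele,
)

NESTED_PANEL_NAMES = ["minimal9", "ppy12", "yfiler17", "ppy23", "26Y"]


def simple_panel(n_loci: int, name: str = "toy") -> PanelDefinition:
    return PanelDefinition(name, tuple(f"L{i + 1}" for i in range(n_loci)))


def make_pop(
    name: str, panel: PanelDefinition, rows: list[list], prefix: str = "s"
) -> PopulationSample:
    """Build a PopulationSample from per-row allele tokens/values."""
    haps = []
    for i, row in enumerate(rows):
        calls = {}
        for locus, value in zip(panel.loci, row):
            if isinstance(value, AlleleCall):
                calls[locus] = value
            elif isinstance(value, str):
                calls[locus] = parse_allele(value, locus)
            else:
                calls[locus] = AlleleCall.of(Fraction(value))
        haps.append(Haplotype(f"{prefix}{i}", calls))
    return PopulationSample(name, panel, haps)


def single_locus_pop(name: str, values: list[int]) -> PopulationSample:
    panel = simple_panel(1, "one")
    return make_pop(name, panel, [[v] for v in values], prefix=f"{name}_")


# ----------------------------------------------------------------------
# A 100-man 26-locus sample engineered so its projections onto the five
# nested panels reproduce the published haplotype count structure:
# distinct counts (89, 92, 97, 99, 99) and singleton counts
# (81, 85, 95, 98, 98).  Identity at each panel is controlled by writing
# a partition-class id into the first locus private to each panel tier.
# ----------------------------------------------------------------------

def _partition_classes(partition: list[list[int]], n: int = 100) -> dict[int, int]:
    cls = {}
    for cid, members in enumerate(partition):
        for m in members:
            cls[m] = cid
    nxt = len(partition)
    for i in range(n):
        if i not in cls:
            cls[i] = nxt
            nxt += 1
    return cls


MINIMAL9_PARTITION = [[2, 3, 4], [5, 6, 15], [7, 8, 16], [0, 1], [9, 10], [11, 12], [13, 14], [17, 18]]
PPY12_PARTITION = [[2, 3, 4], [0, 1], [5, 6], [7, 8], [9, 10], [11, 12], [13, 14]]
YFILER17_PARTITION = [[0, 1], [2, 3, 4]]
PPY23_PARTITION = [[0, 1]]


def table4_structured_sample() -> PopulationSample:
    panel = get_panel("26Y")
    tiers = {
        "DYS19": _partition_classes(MINIMAL9_PARTITION),
        "DYS437": _partition_classes(PPY12_PARTITION),
        "DYS448": _partition_classes(YFILER17_PARTITION),
        "DYS481": _partition_classes(PPY23_PARTITION),
    }
    haps = []
    for i in range(100):
        calls = {}
        for locus in panel.loci:
            if locus in tiers:
                calls[locus] = AlleleCall.numeric(10 + tiers[locus][i])
            elif locus == "DYS385ab":
                calls[locus] = AlleleCall.duplicated([13, 14])
            else:
                calls[locus] = AlleleCall.numeric(12)
        haps.append(Haplotype(f"u{i}", calls))
    return PopulationSample("structured", panel, haps)


@pytest.fixture
def structured_sample() -> PopulationSample:
    return table4_structured_sample()


@pytest.fixture
def nested_panels():
    return [get_panel(name) for name in NESTED_PANEL_NAMES]
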