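"""Core data model for Y-STR haplotypes.

Alleles are integer repeat counts stored as exact rationals so that
intermediate alleles (e.g. ``34.1``) are representable without binary
floating point and sort between their flanking integer alleles.  Four
call states are distinguished:

``numeric``
    a single integer repeat count;
``intermediate``
    a single non-integer repeat size (partial repeat);
``null``
    no amplification product — an empty value list;
``duplicated``
    two or more values at one locus.  This state covers both genuine
    multi-copy loci (DYS385a/b, which normally yield an unordered pair)
    and duplication variants at normally single-copy loci.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import (
    AlleleFormatError,
    ProjectionError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "AlleleCall",
    "PanelDefinition",
    "Haplotype",
    "PopulationSample",
    "parse_allele",
    "format_repeat",
    "canonical_key",
    "project_panel",
    "read_haplotype_table",
    "write_haplotype_table",
    "load_panel_config",
    "get_panel",
    "BUILTIN_PANELS",
]

_STATES = ("numeric", "intermediate", "null", "duplicated")


def format_repeat(value: Fraction) -> str:
    """Render a repeat size in forensic decimal nomenclature ("15", "34.1")."""
    if value.denominator == 1:
        return str(value.numerator)
    # expand to a terminating decimal when possible (allele nomenclature is decimal)
    scaled = value
    digits = 0
    while scaled.denominator != 1 and digits < 9:
        scaled *= 10
        digits += 1
    if scaled.denominator != 1:
        return f"{value.numerator}/{value.denominator}"
    text = str(scaled.numerator).rjust(digits + 1, "0")
    return f"{text[:-digits]}.{text[-digits:]}".rstrip("0").rstrip(".")


@dataclass(frozen=True)
class AlleleCall:
    """One typing result at one locus."""

    state: str
    values: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown allele state {self.state!r}")
        n = len(self.values)
        if self.state == "numeric" and not (
            n == 1 and self.values[0].denominator == 1
        ):
            raise ValueError("numeric call requires exactly one integer value")
        if self.state == "intermediate" and not (
            n == 1 and self.values[0].denominator != 1
        ):
            raise ValueError("intermediate call requires one non-integer value")
        if self.state == "null" and n != 0:
            raise ValueError("null call carries no values")
        if self.state == "duplicated":
            if n < 2:
                raise ValueError("duplicated call requires >=2 values")
            if tuple(sorted(self.values)) != self.values:
                raise ValueError("duplicated values must be sorted ascending")

    # -- constructors -------------------------------------------------
    @staticmethod
    def numeric(value: int | Fraction) -> "AlleleCall":
        return AlleleCall("numeric", (Fraction(value),))

    @staticmethod
    def intermediate(value: Fraction | str) -> "AlleleCall":
        return AlleleCall("intermediate", (Fraction(value),))

    @staticmethod
    def null() -> "AlleleCall":
        return AlleleCall("null", ())

    @staticmethod
    def duplicated(values: Iterable[Fraction | int | str]) -> "AlleleCall":
        vals = tuple(sorted(Fraction(v) for v in values))
        return AlleleCall("duplicated", vals)

    @staticmethod
    def of(value) -> "AlleleCall":
        """Build the appropriate single-value call for a repeat size."""
        v = Fraction(value)
        return AlleleCall.numeric(v) if v.denominator == 1 else AlleleCall.intermediate(v)

    # -- views --------------------------------------------------------
    @property
    def is_anomalous_at_single_copy(self) -> bool:
        return self.state in ("null", "duplicated")

    def to_text(self) -> str:
        if self.state == "null":
            return "null"
        return ",".join(format_repeat(v) for v in self.values)


def parse_allele(token: str, locus: str = "?") -> AlleleCall:
    """Parse one allele token.

    Accepts integer repeats ("15"), decimal intermediates ("34.1"), the
    literal "null" (case-insensitive) and multi-value duplications
    separated by commas or hyphens ("13,14" / "13-14").
    """
    text = token.strip()
    if not text:
        raise AlleleFormatError(f"empty allele token at locus {locus}")
    if text.lower() == "null":
        return AlleleCall.null()
    parts = text.split(",") if "," in text else text.split("-")
    if any(not p.strip() for p in parts):
        raise AlleleFormatError(
            f"cannot parse allele token {token!r} at locus {locus}"
        )
    try:
        values = [Fraction(p.strip()) for p in parts]
    except (ValueError, ZeroDivisionError) as exc:
        raise AlleleFormatError(
            f"cannot parse allele token {token!r} at locus {locus}"
        ) from exc
    if not values or any(v <= 0 for v in values):
        raise AlleleFormatError(
            f"cannot parse allele token {token!r} at locus {locus}"
        )
    if len(values) >= 2:
        return AlleleCall.duplicated(values)
    return AlleleCall.of(values[0])


@dataclass(frozen=True)
class PanelDefinition:
    """Named ordered list of loci with multi-copy metadata.

    ``effective_size`` counts each multi-copy locus (DYS385a/b) as two
    loci, matching the conventional "minimal 9 / 12 / 17 / 23 / 26"
    naming of forensic kits.
    """

    name: str
    loci: tuple[str, ...]
    multi_copy: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError(f"panel {self.name}: duplicate loci")
        if not self.multi_copy <= set(self.loci):
            raise ValidationError(f"panel {self.name}: multi_copy not a subset of loci")

    @property
    def effective_size(self) -> int:
        return len(self.loci) + len(self.multi_copy)

    def is_subpanel_of(self, other: "PanelDefinition") -> bool:
        return set(self.loci) <= set(other.loci)

    def restricted(self, name: str, loci: Sequence[str]) -> "PanelDefinition":
        missing = [l for l in loci if l not in self.loci]
        if missing:
            raise ProjectionError(f"loci {missing} absent from panel {self.name}")
        keep = [l for l in self.loci if l in set(loci)]
        return PanelDefinition(name, tuple(keep), self.multi_copy & set(keep))


_MINIMAL9 = (
    "DYS19", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392",
    "DYS393", "DYS385ab",
)
_PPY12 = _MINIMAL9 + ("DYS437", "DYS438", "DYS439")
_YFILER17 = _PPY12 + ("DYS448", "DYS456", "DYS458", "DYS635", "Y_GATA_H4")
_PPY23 = _YFILER17 + ("DYS481", "DYS533", "DYS549", "DYS570", "DYS576", "DYS643")
_Y26 = _PPY23 + ("DYS388", "DYS449", "DYS460")

BUILTIN_PANELS: dict[str, PanelDefinition] = {
    "minimal9": PanelDefinition("minimal9", _MINIMAL9, frozenset({"DYS385ab"})),
    "ppy12": PanelDefinition("ppy12", _PPY12, frozenset({"DYS385ab"})),
    "yfiler17": PanelDefinition("yfiler17", _YFILER17, frozenset({"DYS385ab"})),
    "ppy23": PanelDefinition("ppy23", _PPY23, frozenset({"DYS385ab"})),
    "26Y": PanelDefinition("26Y", _Y26, frozenset({"DYS385ab"})),
}

_PANEL_ALIASES = {
    "minimal-9": "minimal9", "min9": "minimal9",
    "powerplexy12": "ppy12", "powerplexy23": "ppy23",
    "yfiler": "yfiler17", "y-filer17": "yfiler17",
    "26y": "26Y", "y26": "26Y",
}


def get_panel(name: str) -> PanelDefinition:
    key = name.strip()
    key = _PANEL_ALIASES.get(key.lower(), key)
    key = key if key in BUILTIN_PANELS else _PANEL_ALIASES.get(key.lower(), key)
    if key not in BUILTIN_PANELS:
        lowered = {k.lower(): k for k in BUILTIN_PANELS}
        if key.lower() in lowered:
            key = lowered[key.lower()]
        else:
            raise KeyError(f"unknown panel {name!r}; built-ins: {sorted(BUILTIN_PANELS)}")
    return BUILTIN_PANELS[key]


def load_panel_config(path: str | Path) -> dict[str, PanelDefinition]:
    """Load user panels from a YAML/JSON mapping: name -> locus list or
    {loci: [...], multi_copy: [...]}."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    panels: dict[str, PanelDefinition] = {}
    for name, entry in raw.items():
        if isinstance(entry, Mapping):
            loci = tuple(entry["loci"])
            multi = frozenset(entry.get("multi_copy", ()))
        else:
            loci = tuple(entry)
            multi = frozenset(l for l in loci if l == "DYS385ab")
        panels[name] = PanelDefinition(name, loci, multi)
    return panels


@dataclass(frozen=True)
class Haplotype:
    """Ordered multi-locus profile of one male sample."""

    sample_id: str
    calls: Mapping[str, AlleleCall]

    def conforms_to(self, panel: PanelDefinition) -> bool:
        return all(locus in self.calls for locus in panel.loci)


@dataclass
class PopulationSample:
    """Named collection of haplotypes sharing a panel."""

    population: str
    panel: PanelDefinition
    haplotypes: list[Haplotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        for h in self.haplotypes:
            missing = [l for l in self.panel.loci if l not in h.calls]
            if missing:
                raise ValidationError(
                    f"sample {h.sample_id}: missing calls at {missing}"
                )

    @property
    def n(self) -> int:
        return len(self.haplotypes)


def canonical_key(h: Haplotype, panel: PanelDefinition) -> str:
    """Deterministic serialization used to define haplotype identity.

    Keys are equal iff all calls are equal; duplications compare as
    sorted multisets and null matches only null.
    """
    return "|".join(h.calls[locus].to_text() for locus in panel.loci)


def project_panel(sample: PopulationSample, target: PanelDefinition) -> PopulationSample:
    """Restrict every haplotype to the loci of ``target`` (a sub-panel)."""
    if not target.is_subpanel_of(sample.panel):
        extra = sorted(set(target.loci) - set(sample.panel.loci))
        raise ProjectionError(
            f"panel {target.name} has loci absent from {sample.panel.name}: {extra}"
        )
    if set(target.loci) == set(sample.panel.loci):
        return sample
    haps = [
        Haplotype(h.sample_id, {l: h.calls[l] for l in target.loci})
        for h in sample.haplotypes
    ]
    return PopulationSample(sample.population, target, haps)


# ----------------------------------------------------------------------
# Delimited-text I/O.  Header: SampleID, Population, then one column per
# panel locus.  Comma or tab delimited, UTF-8.
# ----------------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_haplotype_table(
    path: str | Path, panel: PanelDefinition
) -> list[PopulationSample]:
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise SchemaError(f"{path}: empty table")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        header = [c.strip() for c in next(reader)]
        for required in ("SampleID", "Population"):
            if required not in header:
                raise SchemaError(f"{path}: missing column {required!r}")
        missing = [l for l in panel.loci if l not in header]
        if missing:
            raise SchemaError(
                f"{path}: panel {panel.name} loci missing from header: {missing}"
            )
        idx = {name: header.index(name) for name in header}
        by_pop: dict[str, list[Haplotype]] = {}
        seen: set[tuple[str, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(c.strip() for c in row):
                continue
            sid = row[idx["SampleID"]].strip()
            pop = row[idx["Population"]].strip()
            if (pop, sid) in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate SampleID {sid!r} in population {pop!r}"
                )
            seen.add((pop, sid))
            calls = {
                locus: parse_allele(row[idx[locus]], locus) for locus in panel.loci
            }
            by_pop.setdefault(pop, []).append(Haplotype(sid, calls))
    return [PopulationSample(pop, panel, haps) for pop, haps in by_pop.items()]


def write_haplotype_table(
    samples: Sequence[PopulationSample],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    if not samples:
        raise ValidationError("nothing to write")
    panel = samples[0].panel
    for s in samples[1:]:
        if s.panel.loci != panel.loci:
            raise ValidationError("all samples must share a panel for writing")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["SampleID", "Population", *panel.loci])
        for s in samples:
            for h in s.haplotypes:
                writer.writerow(
                    [h.sample_id, s.population]
                    + [h.calls[l].to_text() for l in panel.loci]
                )
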