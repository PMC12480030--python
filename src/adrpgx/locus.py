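"""CYP2C19 locus model: gene structure and star-allele definitions.

The package ships a deliberately desk-scale locus model: nine ordered exons on
chromosome 10 and a star-allele definition table in which every non-reference
allele is defined by a single SNV. Real PharmVar definitions are multi-variant;
the table is a plain TSV precisely so that users can swap in fuller definitions
without touching code. ``*38`` is the sequence-reference haplotype (empty
defining set) and ``*1`` is kept as a distinct legacy label with its own tag
SNV. The structural allele ``*37`` (a ~61.8 kbp partial gene deletion removing
exons 1-5) is not part of the SNV table; it is called from copy-number
segments, see :mod:`adrpgx.star_alleles`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

#: label used for the CNV-defined partial-deletion allele
STAR37 = "*37"
#: reference haplotype label (no defining variants)
REFERENCE_ALLELE = "*38"
#: sentinel for a haplotype whose variant combination matches no allele
UNASSIGNED = "unassigned"

#: approximate length of the *37 partial gene deletion in bp
STAR37_DELETION_LENGTH = 61_800
#: exons (1-based indices) removed by the *37 deletion
STAR37_EXON_RANGE = (1, 5)


@dataclass(frozen=True)
class GeneModel:
    """Gene structure with 0-based half-open exon intervals, ordered 5'→3'."""

    name: str
    chromosome: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"malformed exon interval ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("exons must be non-overlapping and ordered")
            prev_end = end
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def exon_intervals(self, first: int, last: int) -> tuple[tuple[int, int], ...]:
        """Return intervals for exons ``first``..``last`` (1-based, inclusive)."""
        if not 1 <= first <= last <= len(self.exons):
            raise ValueError(f"exon range ({first}, {last}) outside 1..{len(self.exons)}")
        return self.exons[first - 1 : last]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class AlleleDefinitionTable:
    """Star-allele definitions over a fixed set of defining variant positions.

    ``entries`` maps an allele label to its defining set of
    ``(position, alt_base)`` pairs; the reference allele has an empty set.
    """

    entries: dict[str, frozenset[tuple[int, str]]]
    tier: dict[str, int]
    function: dict[str, str]
    variant_meta: pd.DataFrame = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if REFERENCE_ALLELE not in self.entries:
            raise ValueError(f"definition table lacks reference allele {REFERENCE_ALLELE}")
        if self.entries[REFERENCE_ALLELE]:
            raise ValueError("reference allele must have an empty defining set")
        seen: dict[frozenset, str] = {}
        for label, defs in self.entries.items():
            if defs in seen:
                raise ValueError(f"ambiguous definitions: {label} and {seen[defs]}")
            seen[defs] = label
        for label, fn in self.function.items():
            if fn not in {"normal", "increased", "no_function"}:
                raise ValueError(f"unknown function {fn!r} for {label}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def positions(self) -> tuple[int, ...]:
        """All defining positions, sorted by genomic coordinate."""
        pos = {p for defs in self.entries.values() for p, _ in defs}
        return tuple(sorted(pos))

    def defining_position(self, label: str) -> int | None:
        defs = self.entries[label]
        return next(iter(defs))[0] if defs else None


def _data_path(name: str):
    return resources.files("adrpgx.data").joinpath(name)


def load_gene_model() -> GeneModel:
    """Load the bundled CYP2C19 gene model."""
    raw = json.loads(_data_path("cyp2c19_gene.json").read_text())
    return GeneModel(
        name=raw["name"],
        chromosome=raw["chromosome"],
        exons=tuple((int(s), int(e)) for s, e in raw["exons"]),
        strand=raw["strand"],
    )


def load_allele_definitions(path=None) -> AlleleDefinitionTable:
    """Load star-allele definitions from ``path`` or the bundled table.

    The TSV has one row per allele with columns
    ``allele, tier, function, rsid, position, ref, alt``; ``.`` marks the
    reference allele's empty defining set.
    """
    src = path if path is not None else _data_path("cyp2c19_alleles.tsv")
    with resources.as_file(src) if path is None else _noop(src) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    entries: dict[str, frozenset[tuple[int, str]]] = {}
    tier: dict[str, int] = {}
    function: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.allele in entries:
            raise ValueError(f"duplicate allele label {row.allele}")
        if row.position == ".":
            entries[row.allele] = frozenset()
        else:
            entries[row.allele] = frozenset({(int(row.position), row.alt)})
        tier[row.allele] = int(row.tier)
        function[row.allele] = row.function
    return AlleleDefinitionTable(entries=entries, tier=tier, function=function, variant_meta=df)


class _noop:
    """Context manager passing a filesystem path through unchanged."""

    def __init__(self, path):
        self.path = path

    def __enter__(self):
        return self.path

    def __exit__(self, *exc):
        return False
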