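"""Translate CYP2C19 star-allele diplotypes into metaboliser phenotypes.

Five enzyme-activity classes are assigned from the number of deficient and
increased-function alleles in the diplotype: two deficient alleles → poor; one
→ intermediate; none → normal/rapid/ultrarapid by the number of *17 copies.
The counting rule (rather than an explicit lookup of every pair) is the
implementation; the enumerated diplotypes in the accompanying tests act as the
fixture. Note that a deficient+*17 compound heterozygote (e.g. *2/*17) is
intermediate under the literal "carrier of a deficient allele" rule, which
differs from activity-score systems that weight the increased-function allele.
"""

from __future__ import annotations

import pandas as pd

from .locus import STAR37

#: no-function alleles; carrying one makes a sample at least intermediate
DEFICIENT_ALLELES = frozenset({"*2", "*3", "*4", "*8", STAR37})
#: increased-function allele driving rapid/ultrarapid status
INCREASED_ALLELE = "*17"
#: normal-function labels (reference plus the legacy reference label)
NORMAL_ALLELES = frozenset({"*1", "*38"})

KNOWN_ALLELES = DEFICIENT_ALLELES | NORMAL_ALLELES | {INCREASED_ALLELE}

PHENOTYPES = ("poor", "intermediate", "normal", "rapid", "ultrarapid")

#: enzyme-activity rank, ascending (used by monotonicity checks)
ACTIVITY_RANK = {p: i for i, p in enumerate(PHENOTYPES)}


def is_deficient(allele: str) -> bool:
    """True iff ``allele`` is a no-function (deficient) allele."""
    if allele not in KNOWN_ALLELES:
        raise ValueError(f"unknown star allele {allele!r}")
    return allele in DEFICIENT_ALLELES


def assign_metaboliser(allele1: str, allele2: str) -> str:
    """Map an unordered diplotype to one of the five metaboliser phenotypes."""
    d = int(is_deficient(allele1)) + int(is_deficient(allele2))
    if d == 2:
        return "poor"
    if d == 1:
        return "intermediate"
    t = int(allele1 == INCREASED_ALLELE) + int(allele2 == INCREASED_ALLELE)
    return ("normal", "rapid", "ultrarapid")[t]


def add_phenotype_column(calls: pd.DataFrame, column: str = "metaboliser") -> pd.DataFrame:
    """Append a metaboliser column to a diplotype calls table."""
    out = calls.copy()
    out[column] = [
        assign_metaboliser(a1, a2) for a1, a2 in zip(calls["allele1"], calls["allele2"])
    ]
    return out
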