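"""CYP2C19 star-allele calling from phased variants and CNV segments.

Haplotypes are vectors of variant states over the defining positions of the
bundled :class:`~adrpgx.locus.AlleleDefinitionTable` (0 = reference,
1 = alternate, -1 = missing). SNV-based alleles are matched exactly: a
haplotype is assigned the unique allele whose defining set equals the set of
alternate states it carries; the reference label when it carries none; the
``unassigned`` sentinel otherwise. The structural ``*37`` allele is called
independently from deletion segments overlapping exons 1-5, then spliced into
the diplotype. Two matchers (a keyed lookup and an exhaustive scan of the
definition table) are run per sample and only concordant calls are retained,
mirroring a dual-caller consensus design.

Coordinates are 0-based half-open internally; VCF positions are converted on
read (:mod:`adrpgx.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locus import (
    REFERENCE_ALLELE,
    STAR37,
    STAR37_DELETION_LENGTH,
    STAR37_EXON_RANGE,
    UNASSIGNED,
    AlleleDefinitionTable,
    GeneModel,
)

#: samples with more than this fraction of missing defining positions are excluded
MAX_MISSING_FRACTION = 0.2
#: default relative tolerance around the expected *37 deletion length
STAR37_LENGTH_TOLERANCE = 0.5


def star_sort_key(label: str) -> tuple:
    """Canonical sort key for star-allele labels (numeric part, then text)."""
    if label == UNASSIGNED:
        return (1, float("inf"), label)
    digits = "".join(c for c in label if c.isdigit())
    return (0, int(digits) if digits else float("inf"), label)


@dataclass(frozen=True)
class StarDiplotype:
    """An unordered pair of star-allele calls for one sample."""

    sample_id: str
    allele1: str
    allele2: str

    def __post_init__(self):
        a, b = sorted((self.allele1, self.allele2), key=star_sort_key)
        object.__setattr__(self, "allele1", a)
        object.__setattr__(self, "allele2", b)

    @property
    def pair(self) -> frozenset:
        return frozenset({self.allele1, self.allele2}) if self.allele1 != self.allele2 else frozenset({self.allele1})

    def unordered(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)


def _observed_alt_set(haplotype: np.ndarray, defs: AlleleDefinitionTable) -> frozenset:
    positions = defs.positions
    if len(haplotype) != len(positions):
        raise ValueError(
            f"haplotype covers {len(haplotype)} positions, definition table has {len(positions)}"
        )
    alt_base = {p: a for defs_ in defs.entries.values() for p, a in defs_}
    return frozenset((p, alt_base[p]) for p, s in zip(positions, haplotype) if s == 1)


def match_haplotype(haplotype, defs: AlleleDefinitionTable) -> str:
    """Match one haplotype to a star allele by exact defining-set lookup.

    Missing states (-1) are treated as reference for matching (the caller
    tracks missingness separately). Returns ``unassigned`` when the observed
    alternate-state combination defines no allele.
    """
    haplotype = np.asarray(haplotype)
    observed = _observed_alt_set(haplotype, defs)
    lookup = {s: l for l, s in defs.entries.items()}
    return lookup.get(observed, REFERENCE_ALLELE if not observed else UNASSIGNED)


def match_haplotype_enumerate(haplotype, defs: AlleleDefinitionTable) -> str:
    """Second matcher: exhaustive scan over the definition table.

    Deliberately independent of :func:`match_haplotype`'s keyed lookup — it
    enumerates every allele and compares defining sets, raising on ambiguity.
    """
    haplotype = np.asarray(haplotype)
    observed = _observed_alt_set(haplotype, defs)
    candidates = [label for label, s in defs.entries.items() if s == observed and s]
    if len(candidates) > 1:
        raise ValueError(f"ambiguous match: {sorted(candidates)}")
    if candidates:
        return candidates[0]
    return REFERENCE_ALLELE if not observed else UNASSIGNED


def missing_fraction(haplotype) -> float:
    haplotype = np.asarray(haplotype)
    return float(np.mean(haplotype == -1)) if haplotype.size else 0.0


def call_star37(
    segments: pd.DataFrame,
    gene: GeneModel,
    *,
    expected_length: int = STAR37_DELETION_LENGTH,
    length_tolerance: float | None = STAR37_LENGTH_TOLERANCE,
) -> bool:
    """Return True iff the sample carries a *37-compatible deletion.

    A qualifying segment is a deletion with ≥1 bp intersection with the union
    of exons 1-5 whose length lies within ``expected_length * (1 ± tol)``;
    pass ``length_tolerance=None`` to accept any length. ``segments`` needs
    columns ``start``, ``end`` (0-based half-open) and ``svtype``
    (``DEL``/``DUP``).
    """
    if segments is None or len(segments) == 0:
        return False
    exons = gene.exon_intervals(*STAR37_EXON_RANGE)
    for row in segments.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end <= start:
            raise ValueError(f"malformed segment interval ({start}, {end})")
        if str(row.svtype).upper() != "DEL":
            continue
        length = end - start
        if length_tolerance is not None:
            lo = expected_length * (1 - length_tolerance)
            hi = expected_length * (1 + length_tolerance)
            if not lo <= length <= hi:
                continue
        if any(start < e_end and e_start < end for e_start, e_end in exons):
            return True
    return False


def call_diplotype(
    sample_id: str,
    hap1,
    hap2,
    star37: bool,
    defs: AlleleDefinitionTable,
    *,
    matcher=match_haplotype,
) -> StarDiplotype:
    """Combine two SNV-matched haplotypes and the *37 carrier flag.

    When ``star37`` is true exactly one haplotype label is replaced by *37:
    the one whose SNV-based match is the reference label, or — if neither
    matches the reference — the later-sorted label. The rule is isolated here
    so it can be swapped without touching the matchers.
    """
    labels = [matcher(hap1, defs), matcher(hap2, defs)]
    if star37:
        ref_idx = [i for i, l in enumerate(labels) if l == REFERENCE_ALLELE]
        if ref_idx:
            labels[ref_idx[0]] = STAR37
        else:
            later = max(range(2), key=lambda i: star_sort_key(labels[i]))
            labels[later] = STAR37
    return StarDiplotype(sample_id=sample_id, allele1=labels[0], allele2=labels[1])


def consensus_calls(a: StarDiplotype, b: StarDiplotype) -> StarDiplotype | None:
    """Retain the diplotype iff both callers agree as unordered pairs.

    Returns None (sample excluded from pharmacogenetic analyses) on
    disagreement or when either caller produced an unassigned haplotype.
    """
    if a.sample_id != b.sample_id:
        raise ValueError(f"sample-id mismatch: {a.sample_id} vs {b.sample_id}")
    if UNASSIGNED in a.unordered() or UNASSIGNED in b.unordered():
        return None
    return a if a.unordered() == b.unordered() else None


class VectorisedMatcher:
    """Fast exact matcher over many haplotypes at once.

    Encodes each haplotype's alternate states as a bit key over the defining
    positions and maps keys through a lookup table; identical logic to
    :func:`match_haplotype`, vectorised for simulation-scale cohorts.
    """

    def __init__(self, defs: AlleleDefinitionTable):
        self.defs = defs
        self.positions = defs.positions
        npos = len(self.positions)
        if npos > 62:
            raise ValueError("bit-key matcher supports at most 62 defining positions")
        pos_index = {p: i for i, p in enumerate(self.positions)}
        self._weights = (1 << np.arange(npos)).astype(np.int64)
        self._lookup: dict[int, str] = {}
        for label, s in defs.entries.items():
            key = sum(1 << pos_index[p] for p, _ in s)
            self._lookup[key] = label

    def __call__(self, states: np.ndarray) -> np.ndarray:
        """Match a (n_haplotypes, n_positions) state matrix to labels."""
        states = np.asarray(states)
        clean = np.where(states == 1, 1, 0).astype(np.int64)
        keys = clean @ self._weights
        uniq, inv = np.unique(keys, return_inverse=True)
        labels = np.array([self._lookup.get(int(k), UNASSIGNED) for k in uniq], dtype=object)
        return labels[inv]


def call_cohort(
    sample_ids,
    states: np.ndarray,
    cnv_segments: pd.DataFrame | None,
    defs: AlleleDefinitionTable,
    gene: GeneModel,
    *,
    consensus: bool = True,
    max_missing: float = MAX_MISSING_FRACTION,
    length_tolerance: float | None = STAR37_LENGTH_TOLERANCE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call diplotypes for a cohort; returns (calls, exclusion report).

    ``states`` has shape (n_samples, 2, n_positions). ``cnv_segments`` is a
    BED-like frame with a ``sample_id`` column. With ``consensus`` both
    matchers run per sample and discordant or unassigned calls are excluded,
    each with a logged reason.
    """
    sample_ids = list(sample_ids)
    states = np.asarray(states)
    n = len(sample_ids)
    if states.shape[0] != n or states.shape[1] != 2:
        raise ValueError("states must have shape (n_samples, 2, n_positions)")

    fast = VectorisedMatcher(defs)
    flat = states.reshape(n * 2, -1)
    labels_a = fast(flat).reshape(n, 2)
    miss = (flat == -1).mean(axis=1).reshape(n, 2)

    seg_by_sample: dict = {}
    if cnv_segments is not None and len(cnv_segments):
        seg_by_sample = dict(tuple(cnv_segments.groupby("sample_id", sort=False)))

    rows, excluded = [], []
    for i, sid in enumerate(sample_ids):
        if miss[i].max() > max_missing:
            excluded.append((sid, "missing_genotype", f"missing fraction {miss[i].max():.2f}"))
            continue
        star37 = call_star37(seg_by_sample.get(sid), gene, length_tolerance=length_tolerance)
        dip_a = call_diplotype(sid, states[i, 0], states[i, 1], star37, defs)
        if UNASSIGNED in dip_a.unordered():
            # both haplotypes unmatchable is a hard exclusion; one unmatchable
            # still fails consensus below
            if dip_a.unordered() == (UNASSIGNED, UNASSIGNED):
                excluded.append((sid, "unassigned", "both haplotypes match no allele"))
                continue
        if consensus:
            dip_b = call_diplotype(
                sid, states[i, 0], states[i, 1], star37, defs, matcher=match_haplotype_enumerate
            )
            kept = consensus_calls(dip_a, dip_b)
            if kept is None:
                excluded.append((sid, "no_consensus", f"{dip_a.unordered()} vs {dip_b.unordered()}"))
                continue
            dip_a = kept
        elif UNASSIGNED in dip_a.unordered():
            excluded.append((sid, "unassigned", "haplotype matches no allele"))
            continue
        rows.append(
            {
                "sample_id": sid,
                "allele1": dip_a.allele1,
                "allele2": dip_a.allele2,
                "star37": star37,
                "missing_frac": float(miss[i].max()),
            }
        )
    calls = pd.DataFrame(rows, columns=["sample_id", "allele1", "allele2", "star37", "missing_frac"])
    report = pd.DataFrame(excluded, columns=["sample_id", "reason", "detail"])
    return calls, report
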