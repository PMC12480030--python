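"""Cohort construction: layer harmonisation, case/control definition, demographics.

Side-effect records arrive from three sources — two questionnaires (ADEQ,
MHoS) and rule-extracted electronic health records (EHR) — and are merged on
the key ``(sample, drug, side_effect, present)``. Presence/absence conflicts
between sources resolve to *present* (any-source-positive): questionnaires
capture milder subjective effects and EHRs more severe ones, so a positive in
any layer is treated as a genuine report. Cases for an (outcome, drug-group)
cell are users with at least one present record for the outcome on a group
drug; controls are users of the group without one. Analysis cells with fewer
than 100 cases are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("ADEQ", "MHoS", "EHR")

#: the 23 side effects reported by at least 100 individuals
SIDE_EFFECTS = (
    "sleepiness",
    "mouth_dryness",
    "constipation",
    "headache",
    "weight_gain",
    "heart_palpitations",
    "sexual_dysfunction",
    "nausea",
    "weight_loss",
    "blood_pressure_increase",
    "blood_pressure_decrease",
    "insomnia",
    "agitation",
    "allergic_reaction",
    "diarrhoea",
    "sweating",
    "mood_change",
    "irritability",
    "dizziness",
    "grogginess",
    "anxiety",
    "rash",
    "chills",
)

#: pooled outcome codes and their constituent effects
POOLED_OUTCOMES = {
    "any": frozenset(SIDE_EFFECTS) | {"any"},
    "cardiometabolic": frozenset({"heart_palpitations", "weight_gain", "blood_pressure_increase"}),
}

#: controlled vocabulary accepted in records ("any" marks an unspecified effect)
RECORD_VOCABULARY = frozenset(SIDE_EFFECTS) | {"any"}

MIN_CASES = 100

#: ICD-10 codes defining the depression subgroup: F32*, F33* prefixes, F41.2 exact
DEPRESSION_PREFIXES = ("F32", "F33")
DEPRESSION_EXACT = ("F41.2",)


def _load_drug_table() -> pd.DataFrame:
    with resources.as_file(resources.files("adrpgx.data").joinpath("drug_classes.tsv")) as p:
        return pd.read_csv(p, sep="\t")


_DRUGS = _load_drug_table()

ALL_DRUGS = tuple(_DRUGS["drug"])

DRUG_GROUPS: dict[str, frozenset[str]] = {
    "ALL": frozenset(ALL_DRUGS),
    "SSRI": frozenset(_DRUGS.loc[_DRUGS.drug_class == "SSRI", "drug"]),
    "SNRI_ATYP": frozenset(_DRUGS.loc[_DRUGS.drug_class == "SNRI_ATYP", "drug"]),
    "TCA": frozenset(_DRUGS.loc[_DRUGS.drug_class == "TCA", "drug"]),
    "CYP2C19_SET": frozenset(_DRUGS.loc[_DRUGS.cyp2c19_metabolised == 1, "drug"]),
}

ATC_PREFIX = {"SSRI": "N06AB", "TCA": "N06AA", "SNRI_ATYP": "N06AX"}


def resolve_group(group: str | frozenset | set) -> frozenset[str]:
    """Resolve a group name, single drug label, or explicit set to drug labels."""
    if isinstance(group, (set, frozenset)):
        members = frozenset(group)
    elif group in DRUG_GROUPS:
        members = DRUG_GROUPS[group]
    elif group in ALL_DRUGS:
        members = frozenset({group})
    else:
        raise ValueError(f"unknown drug group {group!r}")
    if not members:
        raise ValueError("empty drug group")
    unknown = members - set(ALL_DRUGS)
    if unknown:
        raise ValueError(f"unknown drugs in group: {sorted(unknown)}")
    return members


def resolve_outcome(outcome: str) -> frozenset[str]:
    """Expand an outcome code to the set of record codes that count towards it."""
    if outcome in POOLED_OUTCOMES:
        return POOLED_OUTCOMES[outcome]
    if outcome in SIDE_EFFECTS:
        return frozenset({outcome})
    raise ValueError(f"unknown outcome {outcome!r}")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching printed table style."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def harmonise_layers(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Merge multi-layer records; returns (harmonised records, report).

    Exact duplicates on ``(sample_id, drug, side_effect, present)`` collapse to
    one record (their source layers are concatenated); presence/absence
    conflicts resolve to present. Records with unknown side-effect codes are
    rejected and logged. Idempotent.
    """
    required = {"sample_id", "drug", "side_effect", "present", "layer"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    df = records.copy()
    bad = ~df["side_effect"].isin(RECORD_VOCABULARY)
    n_rejected = int(bad.sum())
    if n_rejected:
        for code in df.loc[bad, "side_effect"].unique():
            logger.warning("rejected records with unknown side-effect code %r", code)
        df = df.loc[~bad]

    key = ["sample_id", "drug", "side_effect", "present"]
    n_before = len(df)
    # layers sort ADEQ < EHR < MHoS; the retained record keeps the first layer
    dedup = (
        df.sort_values(key + ["layer"], kind="mergesort")
        .drop_duplicates(subset=key, keep="first")
        .reset_index(drop=True)
    )
    n_duplicates = n_before - len(dedup)

    # present-wins conflict resolution on (sample, drug, side_effect)
    conflict_key = ["sample_id", "drug", "side_effect"]
    has_present = dedup.groupby(conflict_key, sort=False)["present"].transform("max").astype(bool)
    conflicting = (~dedup["present"].astype(bool)) & has_present
    n_conflicts = int(conflicting.sum())
    out = dedup.loc[~conflicting].reset_index(drop=True)
    report = {
        "n_input": int(len(records)),
        "n_rejected": n_rejected,
        "n_duplicates_removed": int(n_duplicates),
        "n_conflicts_resolved": n_conflicts,
        "n_output": int(len(out)),
    }
    return out, report


class CaseControlBuilder:
    """Index harmonised records for fast case/control construction.

    Precomputes, per drug, the set of users (any record) and, per
    (drug, side-effect), the set of samples with a present record, so that an
    (outcome, group) cell reduces to set unions.
    """

    def __init__(self, records: pd.DataFrame):
        self.records = records
        grouped = records.groupby("drug", sort=False)["sample_id"]
        self._users_by_drug = {d: set(s) for d, s in grouped}
        present = records.loc[records["present"].astype(bool)]
        self._present_by_drug_effect = {
            k: set(s) for k, s in present.groupby(["drug", "side_effect"], sort=False)["sample_id"]
        }

    def users(self, group) -> set:
        drugs = resolve_group(group)
        out: set = set()
        for d in drugs:
            out |= self._users_by_drug.get(d, set())
        return out

    def cases(self, outcome: str, group) -> set:
        drugs = resolve_group(group)
        codes = resolve_outcome(outcome)
        out: set = set()
        for d in drugs:
            for c in codes:
                out |= self._present_by_drug_effect.get((d, c), set())
        return out

    def table(self, outcome: str, group) -> pd.DataFrame:
        """One row per group user with a ``case`` flag (case XOR control)."""
        users = self.users(group)
        cases = self.cases(outcome, group) & users
        ids = sorted(users)
        df = pd.DataFrame(
            {
                "sample_id": ids,
                "outcome": outcome,
                "group": group if isinstance(group, str) else ";".join(sorted(group)),
                "case": [s in cases for s in ids],
            }
        )
        return df


def define_cases_controls(records: pd.DataFrame, outcome: str, group) -> pd.DataFrame:
    """Build the case/control table for one (outcome, drug-group) cell."""
    return CaseControlBuilder(records).table(outcome, group)


def filter_min_cases(table: pd.DataFrame, threshold: int = MIN_CASES) -> bool:
    """True iff the analysis cell has at least ``threshold`` cases."""
    return int(table["case"].sum()) >= threshold


def depression_subgroup(table: pd.DataFrame, diagnoses: dict) -> pd.DataFrame:
    """Restrict to samples with an ICD-10 depression code (F32*, F33*, F41.2)."""

    def qualifies(codes) -> bool:
        return any(
            str(c).startswith(DEPRESSION_PREFIXES) or str(c) in DEPRESSION_EXACT for c in codes
        )

    keep = table["sample_id"].map(lambda s: qualifies(diagnoses.get(s, ())))
    return table.loc[keep].reset_index(drop=True)


@dataclass
class DemographicsRow:
    characteristic: str
    subcategory: str
    n_cases: float
    pct_cases: float | None
    n_controls: float
    pct_controls: float | None
    n_total: float
    pct_total: float | None


def _pct(n: int, denom: int) -> float | None:
    return round_half_up(100.0 * n / denom, 1) if denom else None


def tabulate_demographics(df: pd.DataFrame) -> pd.DataFrame:
    """Tabulate counts and percentages by sex, metaboliser and subgroup.

    ``df`` has one row per sample with columns ``case`` (bool), ``sex``
    (female/male), optional ``metaboliser`` (five levels; NaN = incomplete
    CNV/star-allele information), optional ``depression`` (bool) and optional
    ``age``. Case/control percentages are within the case/control totals for
    the characteristic; total percentages use the full cohort, except for the
    metaboliser rows which use the complete-information denominator.
    Percentages are half-up rounded to one decimal; empty strata report a zero
    count with the percentage omitted.
    """
    rows: list[DemographicsRow] = []
    is_case = df["case"].astype(bool)
    n_cases_all, n_controls_all, n_all = int(is_case.sum()), int((~is_case).sum()), len(df)

    for sex in ("female", "male"):
        m = df["sex"] == sex
        rows.append(
            DemographicsRow(
                "sex", sex,
                int((m & is_case).sum()), _pct(int((m & is_case).sum()), n_cases_all),
                int((m & ~is_case).sum()), _pct(int((m & ~is_case).sum()), n_controls_all),
                int(m.sum()), _pct(int(m.sum()), n_all),
            )
        )

    if "age" in df.columns:
        def fmt(series):
            if not len(series):
                return np.nan, None
            mean = round_half_up(float(series.mean()), 1)
            sd = round_half_up(float(series.std(ddof=1)), 1) if len(series) > 1 else None
            return mean, sd
        mc, sc = fmt(df.loc[is_case, "age"])
        mk, sk = fmt(df.loc[~is_case, "age"])
        mt, st = fmt(df["age"])
        rows.append(DemographicsRow("age", "mean_sd", mc, sc, mk, sk, mt, st))

    if "metaboliser" in df.columns:
        known = df["metaboliser"].notna()
        den_case = int((known & is_case).sum())
        den_ctrl = int((known & ~is_case).sum())
        den_tot = int(known.sum())
        from .phenotype import PHENOTYPES

        for pheno in PHENOTYPES:
            m = df["metaboliser"] == pheno
            rows.append(
                DemographicsRow(
                    "metaboliser", pheno,
                    int((m & is_case).sum()), _pct(int((m & is_case).sum()), den_case),
                    int((m & ~is_case).sum()), _pct(int((m & ~is_case).sum()), den_ctrl),
                    int(m.sum()), _pct(int(m.sum()), den_tot),
                )
            )

    if "depression" in df.columns:
        m = df["depression"].astype(bool)
        # printed tables report this row against the whole cohort
        rows.append(
            DemographicsRow(
                "subgroup", "depression",
                int((m & is_case).sum()), _pct(int((m & is_case).sum()), n_all),
                int((m & ~is_case).sum()), _pct(int((m & ~is_case).sum()), n_all),
                int(m.sum()), _pct(int(m.sum()), n_all),
            )
        )

    return pd.DataFrame([r.__dict__ for r in rows])


def tabulate_prevalence(counts: dict[str, int], n_total: int) -> pd.DataFrame:
    """Per-outcome prevalence table (count, half-up percentage of ``n_total``)."""
    rows = [
        {"outcome": k, "n": int(v), "pct": _pct(int(v), n_total)} for k, v in counts.items()
    ]
    return pd.DataFrame(rows)
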