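"""In-package fixtures reconstructed from printed marginal counts.

The original individual-level biobank data are access-restricted, but the
published demographics table and results text print exact marginal counts.
These constructors rebuild a synthetic individual-level table with those
marginals so the tabulators can be exercised end-to-end. Only marginal
structure is reproduced — the joint distribution across characteristics is
arbitrary (each characteristic is tabulated independently). The age column is
an affine-scaled synthetic vector matching the printed total mean/SD; the
printed case/control age breakdown is internally inconsistent with the total
and is not reproduced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_TOTAL = 13_729
N_CASES = 7_141
N_CYP2C19_SET = 9_563

#: metaboliser counts (cases, controls) from the demographics table
METABOLISER_COUNTS = {
    "poor": (108, 73),
    "intermediate": (1221, 1137),
    "normal": (1806, 1690),
    "rapid": (1528, 1379),
    "ultrarapid": (288, 333),
}

SEX_COUNTS = {"female": (5932, 5084), "male": (1209, 1504)}

DEPRESSION_COUNTS = (5923, 4991)

AGE_MEAN, AGE_SD = 49.9, 14.3

#: printed side-effect report counts across all antidepressant users
PREVALENCE_COUNTS = {
    "any": 7141,
    "nausea": 2155,
    "weight_gain": 2099,
    "sleepiness": 2055,
    "chills": 103,
    "blood_pressure_decrease": 134,
    "allergic_reaction": 145,
}

N_DEPRESSION_SUBGROUP = 10_914

#: printed 2x2 metaboliser-by-any-side-effect counts (cases, controls)
TWO_BY_TWO = {
    "poor": (108, 73),
    "normal": (1806, 1690),
    "ultrarapid": (288, 333),
}


def _fill(n: int, values: list[tuple[object, int]], fill=np.nan) -> np.ndarray:
    out = np.full(n, fill, dtype=object)
    i = 0
    for value, count in values:
        out[i : i + count] = value
        i += count
    return out


def _scaled_ages(n: int, mean: float, sd: float) -> np.ndarray:
    base = np.linspace(-1.0, 1.0, n)
    base = base - base.mean()
    return mean + base * (sd / base.std(ddof=1))


def table1_individuals() -> pd.DataFrame:
    """Synthetic individual-level table with the printed total-column marginals."""
    n_controls = N_TOTAL - N_CASES
    case = np.concatenate([np.ones(N_CASES, bool), np.zeros(n_controls, bool)])

    sex = np.concatenate(
        [
            _fill(N_CASES, [("female", SEX_COUNTS["female"][0]), ("male", SEX_COUNTS["male"][0])]),
            _fill(n_controls, [("female", SEX_COUNTS["female"][1]), ("male", SEX_COUNTS["male"][1])]),
        ]
    )
    metab = np.concatenate(
        [
            _fill(N_CASES, [(k, v[0]) for k, v in METABOLISER_COUNTS.items()]),
            _fill(n_controls, [(k, v[1]) for k, v in METABOLISER_COUNTS.items()]),
        ]
    )
    depression = np.concatenate(
        [
            _fill(N_CASES, [(True, DEPRESSION_COUNTS[0])], fill=False),
            _fill(n_controls, [(True, DEPRESSION_COUNTS[1])], fill=False),
        ]
    ).astype(bool)

    return pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(N_TOTAL)],
            "case": case,
            "sex": sex,
            "metaboliser": metab,
            "depression": depression,
            "age": _scaled_ages(N_TOTAL, AGE_MEAN, AGE_SD),
        }
    )


def two_by_two_rows(level: str, reference: str = "normal") -> pd.DataFrame:
    """Expand the printed 2x2 counts for ``level`` vs ``reference`` to rows."""
    rows = []
    for lab in (reference, level):
        n_case, n_ctrl = TWO_BY_TWO[lab]
        rows.append(pd.DataFrame({"case": [True] * n_case + [False] * n_ctrl, "level": lab}))
    df = pd.concat(rows, ignore_index=True)
    df["exposed"] = (df["level"] != reference).astype(int)
    return df
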