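"""Fixed-effects inverse-variance-weighted meta-analysis across cohorts.

Per-drug logistic estimates for three side-effect phenotypes (weight gain,
headache, insomnia) from two cohorts are combined on the log-odds scale with
weights w_i = 1/se_i²: beta = Σw·b / Σw, se = (Σw)^(-1/2), two-sided normal p.
The 3-phenotype × 9-drug family (27 tests) is BH-FDR corrected. Cells present
in only one cohort pass through as k=1 meta-results. No heterogeneity model is
fitted (fixed effects only); Cochran's Q is emitted as an optional diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import Z95, bh_fdr

logger = logging.getLogger(__name__)

META_DRUGS = (
    "duloxetine",
    "mirtazapine",
    "escitalopram",
    "fluoxetine",
    "sertraline",
    "citalopram",
    "paroxetine",
    "amitriptyline",
    "venlafaxine",
)

META_PHENOTYPES = ("weight_gain", "headache", "insomnia")

META_FAMILY_SIZE = len(META_DRUGS) * len(META_PHENOTYPES)


@dataclass(frozen=True)
class MetaInput:
    """One cohort's estimate for one (drug, phenotype) cell, on log-OR scale."""

    cohort: str
    drug: str
    phenotype: str
    beta: float
    se: float

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"standard error must be positive, got {self.se}")
        if self.drug not in META_DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.phenotype not in META_PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


@dataclass
class MetaResult:
    drug: str
    phenotype: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    k: int
    q_het: float
    q: float = np.nan


def or_ci_to_beta_se(or_: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Convert a printed OR with 95% CI to (log-OR, SE): se = CI log-width / 3.92."""
    if not 0 < ci_low < or_ < ci_high:
        raise ValueError("require 0 < ci_low < OR < ci_high")
    return float(np.log(or_)), float((np.log(ci_high) - np.log(ci_low)) / (2 * Z95))


def ivw_meta(inputs: list[MetaInput]) -> MetaResult:
    """Fixed-effects IVW combination of one cell's per-cohort estimates."""
    if not inputs:
        raise ValueError("need at least one input")
    drug = inputs[0].drug
    phenotype = inputs[0].phenotype
    if any(i.drug != drug or i.phenotype != phenotype for i in inputs):
        raise ValueError("inputs mix drugs or phenotypes")
    b = np.array([i.beta for i in inputs])
    w = np.array([1.0 / i.se**2 for i in inputs])
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    q_het = float((w * (b - beta) ** 2).sum())
    return MetaResult(
        drug=drug,
        phenotype=phenotype,
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p=float(2.0 * norm.sf(abs(beta / se))),
        k=len(inputs),
        q_het=q_het,
    )


def _frame_to_inputs(df: pd.DataFrame, cohort: str) -> tuple[list[MetaInput], pd.DataFrame]:
    inputs, rejected = [], []
    for row in df.itertuples(index=False):
        try:
            inputs.append(
                MetaInput(
                    cohort=getattr(row, "cohort", cohort),
                    drug=row.drug,
                    phenotype=row.phenotype,
                    beta=float(row.beta),
                    se=float(row.se),
                )
            )
        except ValueError as err:
            logger.warning("rejected meta input row %s: %s", tuple(row), err)
            rejected.append({**row._asdict(), "reason": str(err)})
    return inputs, pd.DataFrame(rejected)


def run_meta_scan(
    estbb_results: pd.DataFrame,
    agds_results: pd.DataFrame,
    *,
    family_size: int = META_FAMILY_SIZE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IVW-combine two cohorts' per-drug results and FDR-correct the family.

    Input frames need columns ``drug, phenotype, beta, se``. Cells available
    in only one cohort are meta-analysed as k=1 (pass-through estimate, family
    level q). Returns (27-row tidy table, rejected-row log).
    """
    in_a, rej_a = _frame_to_inputs(estbb_results, "EstBB-like")
    in_b, rej_b = _frame_to_inputs(agds_results, "AGDS-like")
    by_cell: dict[tuple[str, str], list[MetaInput]] = {}
    for inp in in_a + in_b:
        by_cell.setdefault((inp.drug, inp.phenotype), []).append(inp)

    results = [
        ivw_meta(by_cell[(d, ph)])
        for ph in META_PHENOTYPES
        for d in META_DRUGS
        if (d, ph) in by_cell
    ]
    q = bh_fdr([r.p for r in results], max(family_size, len(results)))
    for r, qi in zip(results, q):
        r.q = float(qi)
    out = pd.DataFrame([r.__dict__ for r in results])
    rejected = (
        pd.concat([rej_a, rej_b], ignore_index=True)
        if (len(rej_a) or len(rej_b))
        else pd.DataFrame()
    )
    return out, rejected
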