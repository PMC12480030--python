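"""Logistic association scans, BH-FDR, forward stepwise selection.

Associations between side effects and either the categorical CYP2C19
metaboliser phenotype (normal metaboliser as reference) or continuous
standardised polygenic scores are estimated by maximum-likelihood logistic
regression, adjusting for birth year, sex and the first ten genotype PCs.
Inference is Wald (symmetric on the log-odds scale): CI = exp(beta ± 1.96·se),
two-sided normal p. Multiple testing uses the Benjamini-Hochberg step-up
procedure over the family a scan plan declares; cells below the 100-case
threshold are emitted as not-reported and excluded from the family, as are
flagged (separated / non-converged) fits. Collinearity between polygenic
scores is handled by forward stepwise selection of independent effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .cohort import MIN_CASES, SIDE_EFFECTS, CaseControlBuilder
from .simulate import PSYCHIATRIC_PGS, TRAIT_SPECIFIC_MAP

logger = logging.getLogger(__name__)

Z95 = norm.ppf(0.975)

DEFAULT_COVARIATES = ("birth_year", "female") + tuple(f"pc{i}" for i in range(1, 11))

METABOLISER_REFERENCE = "normal"

#: |beta| or SE beyond which a fit is flagged as separated
_SEP_BETA, _SEP_SE = 15.0, 50.0


@dataclass
class AssociationResult:
    """One association test in the tidy results table."""

    outcome: str
    predictor: str
    group: str
    n_cases: int
    n_controls: int
    beta: float = np.nan
    se: float = np.nan
    or_: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    q: float = np.nan
    flag: str = ""

    @classmethod
    def from_fit(cls, beta, se, **kw):
        return cls(
            beta=float(beta),
            se=float(se),
            or_=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z95 * se)),
            ci_high=float(np.exp(beta + Z95 * se)),
            p=float(2.0 * norm.sf(abs(beta / se))),
            **kw,
        )


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    cols = [f.name for f in fields(AssociationResult)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)


def bh_fdr(pvalues, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q(i) = min_{j ≥ i} m·p(j)/j clipped to 1, with family size m defaulting to
    the number of tests; a larger declared family may be passed when some of
    its tests are absent.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError("family_size smaller than the number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _attach_q(results: list[AssociationResult], family_size: int | None = None) -> None:
    fitted = [r for r in results if not r.flag and np.isfinite(r.p)]
    if not fitted:
        return
    m = family_size if family_size is not None and family_size >= len(fitted) else None
    q = bh_fdr([r.p for r in fitted], m if m is not None else None)
    for r, qi in zip(fitted, q):
        r.q = float(qi)


def _wald_rows(res, names, wanted):
    """Extract (beta, se) for the requested design columns."""
    out = {}
    for name in wanted:
        j = names.index(name)
        out[name] = (res.params[j], res.bse[j])
    return out


def fit_logistic(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=(),
    *,
    reference: str | None = None,
    standardise: bool = True,
    group: str = "ALL",
    outcome_label: str | None = None,
) -> list[AssociationResult]:
    """ML logistic fit of one outcome on one predictor plus covariates.

    Categorical predictors yield one result per non-reference level (odds
    ratio vs ``reference``); continuous predictors are standardised to unit SD
    within the analysis sample, so the OR is per SD. Non-convergence or
    separation is flagged, not raised.
    """
    outcome_label = outcome_label or outcome
    use = [outcome, predictor, *covariates]
    data = df[use].dropna()
    y = data[outcome].astype(float).to_numpy()
    n_cases, n_controls = int(y.sum()), int(len(y) - y.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(f"outcome {outcome!r} needs at least one case and one control")

    categorical = not np.issubdtype(np.asarray(data[predictor]).dtype, np.number)
    cols, names = [np.ones(len(data))], ["const"]
    meta: list[tuple[str, int, int]] = []  # (design name, level cases, level controls)
    if categorical:
        if reference is None:
            raise ValueError("categorical predictor requires a reference level")
        levels = [l for l in pd.unique(data[predictor]) if l != reference]
        if reference not in set(data[predictor]):
            raise ValueError(f"reference level {reference!r} absent from data")
        for level in sorted(levels):
            x = (data[predictor] == level).to_numpy(dtype=float)
            cols.append(x)
            names.append(str(level))
            meta.append((str(level), int(y[x == 1].sum()), int((1 - y)[x == 1].sum())))
    else:
        x = data[predictor].to_numpy(dtype=float)
        if standardise:
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"predictor {predictor!r} is constant")
            x = (x - x.mean()) / sd
        cols.append(x)
        names.append(predictor)
        meta.append((predictor, n_cases, n_controls))
    for c in covariates:
        v = data[c].to_numpy(dtype=float)
        cols.append(v)
        names.append(c)
    X = np.column_stack(cols)

    flag = ""
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        if not getattr(res, "converged", True):
            flag = "non_converged"
        elif np.max(np.abs(res.params[1:])) > _SEP_BETA or np.max(res.bse) > _SEP_SE:
            flag = "separation"
    except Exception as err:  # perfect separation raises inside IRLS
        logger.warning("logistic fit failed for %s/%s: %s", outcome_label, predictor, err)
        res, flag = None, "fit_error"

    results = []
    for name, lvl_cases, lvl_controls in meta:
        label = f"{predictor}:{name}" if categorical else name
        if res is None:
            results.append(
                AssociationResult(
                    outcome=outcome_label, predictor=label, group=group,
                    n_cases=n_cases, n_controls=n_controls, flag=flag,
                )
            )
            continue
        beta, se = _wald_rows(res, names, [name])[name]
        r = AssociationResult.from_fit(
            beta, se,
            outcome=outcome_label, predictor=label, group=group,
            n_cases=n_cases, n_controls=n_controls, flag=flag,
        )
        results.append(r)
    return results


def run_cyp2c19_scan(
    table: pd.DataFrame,
    *,
    outcome: str = "se_any",
    per_drug: bool = False,
    covariates=DEFAULT_COVARIATES,
) -> list[AssociationResult]:
    """Categorical metaboliser association among users of the CYP2C19 set.

    One result per non-reference metaboliser level versus normal; with
    ``per_drug`` the fit is repeated within each drug stratum. ``table`` is a
    sample-level frame with ``drug_*`` exposure columns and a ``metaboliser``
    column; levels absent from the data are omitted with a log entry.
    """
    from .cohort import DRUG_GROUPS
    from .phenotype import PHENOTYPES

    cyp_drugs = sorted(DRUG_GROUPS["CYP2C19_SET"])
    present_cols = [f"drug_{d}" for d in cyp_drugs if f"drug_{d}" in table.columns]
    users = table.loc[table[present_cols].any(axis=1)] if present_cols else table.iloc[0:0]

    strata = [("CYP2C19_SET", users)]
    if per_drug:
        strata += [
            (d, users.loc[users[f"drug_{d}"]])
            for d in cyp_drugs
            if f"drug_{d}" in users.columns and users[f"drug_{d}"].any()
        ]
    results: list[AssociationResult] = []
    for label, sub in strata:
        sub = sub.dropna(subset=["metaboliser"])
        observed = set(sub["metaboliser"])
        for lvl in PHENOTYPES:
            if lvl not in observed:
                logger.info("metaboliser level %r absent in stratum %s; omitted", lvl, label)
        results.extend(
            fit_logistic(
                sub, outcome, "metaboliser", covariates,
                reference=METABOLISER_REFERENCE, group=label, outcome_label="any",
            )
        )
    _attach_q(results)
    return results


@dataclass(frozen=True)
class ScanPlan:
    """A declared family of (outcome, predictor, group) association tests."""

    name: str
    outcomes: tuple
    predictors: dict  # outcome -> tuple of PGS names
    groups: tuple

    @property
    def cells(self) -> list[tuple[str, str, str]]:
        return [
            (o, p, g) for g in self.groups for o in self.outcomes for p in self.predictors[o]
        ]

    @property
    def family_size(self) -> int:
        return len(self.cells)


def psychiatric_plan() -> ScanPlan:
    """25 outcomes × 8 psychiatric scores × 4 drug groups = 800 tests."""
    outcomes = tuple(SIDE_EFFECTS) + ("any", "cardiometabolic")
    return ScanPlan(
        name="psychiatric",
        outcomes=outcomes,
        predictors={o: tuple(PSYCHIATRIC_PGS) for o in outcomes},
        groups=("ALL", "SSRI", "SNRI_ATYP", "TCA"),
    )


def trait_plan() -> ScanPlan:
    """12 outcomes, one trait-matched score per model, 4 drug groups = 48 tests."""
    return ScanPlan(
        name="trait_specific",
        outcomes=tuple(TRAIT_SPECIFIC_MAP),
        predictors={o: (p,) for o, p in TRAIT_SPECIFIC_MAP.items()},
        groups=("ALL", "SSRI", "SNRI_ATYP", "TCA"),
    )


def run_pgs_scans(
    records: pd.DataFrame,
    samples: pd.DataFrame,
    plan: ScanPlan,
    *,
    adjust_metaboliser: bool = False,
    min_cases: int = MIN_CASES,
    covariates=DEFAULT_COVARIATES,
) -> list[AssociationResult]:
    """Run a PGS scan plan over harmonised records.

    ``samples`` carries one row per sample (covariates, ``pgs_*`` columns and
    optionally ``metaboliser``). Cells with fewer than ``min_cases`` cases are
    emitted with the ``not_reported`` flag (the grey cells of the published
    heat map) and excluded from the BH family, which otherwise spans all
    emitted cells of the plan. With ``adjust_metaboliser`` the fit gains
    metaboliser indicator covariates and is restricted to samples with a
    called phenotype.
    """
    builder = CaseControlBuilder(records)
    samples = samples.reset_index(drop=True)
    results: list[AssociationResult] = []
    for outcome, pgs_name, group in plan.cells:
        cc = builder.table(outcome, group)
        df = cc.merge(samples, on="sample_id", how="inner")
        n_cases = int(df["case"].sum())
        n_controls = int(len(df) - n_cases)
        if n_cases < min_cases:
            results.append(
                AssociationResult(
                    outcome=outcome, predictor=f"pgs_{pgs_name}", group=group,
                    n_cases=n_cases, n_controls=n_controls, flag="not_reported",
                )
            )
            continue
        covs = list(covariates)
        if adjust_metaboliser:
            df = df.dropna(subset=["metaboliser"])
            for lvl in sorted(set(df["metaboliser"])):
                if lvl == METABOLISER_REFERENCE:
                    continue
                col = f"metab_{lvl}"
                df[col] = (df["metaboliser"] == lvl).astype(float)
                covs.append(col)
        results.extend(
            fit_logistic(
                df, "case", f"pgs_{pgs_name}", covs,
                group=group, outcome_label=outcome,
            )
        )
    _attach_q(results)
    return results


def forward_stepwise(
    df: pd.DataFrame,
    outcome: str,
    candidates,
    covariates=(),
    *,
    alpha: float = 0.05,
) -> tuple[list[str], list[AssociationResult]]:
    """Forward selection of independent PGS effects.

    At each step the remaining candidate with the smallest Wald p-value in the
    current multivariate model (candidate + already-selected + covariates) is
    added, provided p < alpha; ties break lexicographically so the outcome is
    independent of candidate input order. The final multivariate model is
    refitted and FDR-corrected across the retained predictors.
    """
    remaining = sorted(candidates)
    selected: list[str] = []
    while remaining:
        best = None
        for cand in remaining:
            fit = _multivariate_fit(df, outcome, selected + [cand], covariates)
            p = fit[cand][2]
            if best is None or (p, cand) < best[:2]:
                best = (p, cand)
        p, cand = best
        if not np.isfinite(p) or p >= alpha:
            break
        selected.append(cand)
        remaining.remove(cand)
    if not selected:
        return [], []
    final = _multivariate_fit(df, outcome, selected, covariates)
    y = df[outcome].astype(bool)
    results = [
        AssociationResult.from_fit(
            final[name][0], final[name][1],
            outcome=outcome, predictor=name, group="multivariate",
            n_cases=int(y.sum()), n_controls=int((~y).sum()),
        )
        for name in selected
    ]
    _attach_q(results)
    return selected, results


def _multivariate_fit(df, outcome, predictors, covariates):
    """Fit outcome ~ predictors + covariates; returns {name: (beta, se, p)}."""
    data = df[[outcome, *predictors, *covariates]].dropna()
    y = data[outcome].astype(float).to_numpy()
    cols, names = [np.ones(len(data))], ["const"]
    for c in [*predictors, *covariates]:
        x = data[c].to_numpy(dtype=float)
        if c in predictors:
            sd = x.std(ddof=0)
            x = (x - x.mean()) / sd if sd > 0 else x
        cols.append(x)
        names.append(c)
    X = np.column_stack(cols)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    out = {}
    for name in predictors:
        j = names.index(name)
        b, s = res.params[j], res.bse[j]
        out[name] = (b, s, float(2.0 * norm.sf(abs(b / s))))
    return out


def pgs_correlations(pgs: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlations between scores.

    Returns the symmetric unit-diagonal matrix and a list of flagged constant
    columns (their entries are undefined / NaN).
    """
    cols = [c for c in pgs.columns if c != "sample_id"]
    if len(cols) < 2:
        raise ValueError("need at least two scores")
    data = pgs[cols]
    flagged = [c for c in cols if float(data[c].std(ddof=0)) == 0.0]
    corr = data.corr(method="pearson")
    return corr, flagged
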