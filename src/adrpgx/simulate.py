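"""Synthetic biobank-like cohort generator.

Every downstream stage of the pipeline is testable without protected data:
this module draws a cohort with the statistical structure the analysis
assumes. Haplotypes are drawn as whole star-allele labels under Hardy-Weinberg
equilibrium and expanded to variant states (guaranteeing matchable
haplotypes); *37 carriers receive a ~61.8 kbp deletion segment covering exons
1-5; polygenic scores are multivariate normal with standard-normal marginals
and a configurable correlation matrix; side-effect presence follows a
per-sample logistic model whose coefficients are the configured log
odds-ratios — the exact generative inverse of the fitted association model.
Present records are attributed to a taken drug (preferring the effect's drug
group) and emitted across three source layers with configurable duplicate and
presence/absence-conflict rates.

All generators are deterministic given the config seed; independent seed
streams per component keep each ``simulate_*`` function reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import log

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import expit

from . import star_alleles
from .cohort import ALL_DRUGS, DRUG_GROUPS, LAYERS, RECORD_VOCABULARY, resolve_group
from .locus import REFERENCE_ALLELE, STAR37_DELETION_LENGTH, STAR37_EXON_RANGE, load_allele_definitions, load_gene_model
from .phenotype import PHENOTYPES, assign_metaboliser

# fixed per-component seed-stream tags
_STREAMS = {
    "haplotypes": 11,
    "cnv": 12,
    "pgs": 13,
    "covariates": 14,
    "drugs": 15,
    "outcomes": 16,
    "records": 17,
    "summary": 18,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([_STREAMS[component], int(seed)]))


#: Estonian-like star-allele haplotype frequencies; under HWE (plus the 1.5%
#: *37 carrier rate) these reproduce the published five-phenotype split to
#: within a percentage point.
DEFAULT_HAPLOTYPE_FREQS = {
    "*38": 0.550,
    "*1": 0.0647,
    "*17": 0.255,
    "*2": 0.120,
    "*3": 0.0013,
    "*4": 0.004,
    "*8": 0.005,
}

#: psychiatric-trait scores entering the 25x8x4 scan
PSYCHIATRIC_PGS = ("MDD", "SCZ", "BIP", "ANX", "NEU", "ADHD", "NONREM", "CROSS")

#: outcome → corresponding trait PGS for the 12x4 trait-specific scan
TRAIT_SPECIFIC_MAP = {
    "sleepiness": "SLEEPINESS",
    "constipation": "CONSTIPATION",
    "diarrhoea": "DIARRHOEA",
    "headache": "HEADACHE",
    "weight_gain": "BMI",
    "heart_palpitations": "HEART_RATE",
    "nausea": "NAUSEA",
    "weight_loss": "BMI",
    "blood_pressure_increase": "SBP",
    "blood_pressure_decrease": "SBP",
    "insomnia": "INSOMNIA",
    "anxiety": "ANX",
}

DEFAULT_PGS_NAMES = tuple(PSYCHIATRIC_PGS) + tuple(
    sorted(set(TRAIT_SPECIFIC_MAP.values()) - set(PSYCHIATRIC_PGS))
)

#: drug assignment probabilities shaped to the published class shares
#: (SSRI ≈ 77%, SNRI+atypicals ≈ 41%, TCA ≈ 13%, CYP2C19 set ≈ 70%)
DEFAULT_DRUG_PROBS = {
    "escitalopram": 0.45,
    "citalopram": 0.18,
    "sertraline": 0.18,
    "fluoxetine": 0.09,
    "paroxetine": 0.04,
    "venlafaxine": 0.15,
    "duloxetine": 0.07,
    "mirtazapine": 0.12,
    "bupropion": 0.05,
    "trazodone": 0.04,
    "vortioxetine": 0.03,
    "agomelatine": 0.02,
    "tianeptine": 0.01,
    "amitriptyline": 0.10,
    "clomipramine": 0.02,
    "nortriptyline": 0.01,
}

#: marginal per-side-effect report rates used by the default scenario; printed
#: values where the source text gives them, plausible interpolations otherwise
DEFAULT_PREVALENCE = {
    "nausea": 0.157,
    "weight_gain": 0.153,
    "sleepiness": 0.150,
    "mouth_dryness": 0.120,
    "headache": 0.110,
    "insomnia": 0.080,
    "dizziness": 0.070,
    "sexual_dysfunction": 0.060,
    "constipation": 0.050,
    "sweating": 0.050,
    "heart_palpitations": 0.050,
    "weight_loss": 0.040,
    "grogginess": 0.040,
    "diarrhoea": 0.040,
    "agitation": 0.030,
    "mood_change": 0.030,
    "irritability": 0.030,
    "anxiety": 0.030,
    "blood_pressure_increase": 0.025,
    "rash": 0.015,
    "allergic_reaction": 0.011,
    "blood_pressure_decrease": 0.010,
    "chills": 0.008,
}

#: published point estimates used as generating effects in the default scenario
DEFAULT_EFFECTS = {
    ("metaboliser:poor", "any", "CYP2C19_SET"): log(1.49),
    ("metaboliser:ultrarapid", "any", "CYP2C19_SET"): log(0.83),
    ("pgs:SCZ", "any", "ALL"): log(1.15),
    ("pgs:MDD", "any", "ALL"): log(1.14),
    ("pgs:BMI", "weight_gain", "ALL"): log(1.10),
    ("pgs:SBP", "blood_pressure_increase", "ALL"): log(1.27),
    ("pgs:ANX", "anxiety", "ALL"): log(1.34),
    ("pgs:HEADACHE", "headache", "sertraline"): log(1.12),
}

#: covariate log-OR defaults for the demo scenario, consistent with the
#: published case/control sex split and age gap (female excess among cases;
#: younger cases). Applied to centred covariates.
DEFAULT_COVARIATE_EFFECTS = {"female": 0.37, "birth_year": 0.037}


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort (the 'stated world')."""

    n_samples: int = 13_729
    haplotype_freqs: dict = field(default_factory=lambda: dict(DEFAULT_HAPLOTYPE_FREQS))
    star37_carrier_freq: float = 0.015
    pgs_names: tuple = DEFAULT_PGS_NAMES
    pgs_corr: np.ndarray | None = None
    effects: dict = field(default_factory=dict)
    baseline_logit: dict = field(default_factory=lambda: {"any": 0.08})
    covariate_effects: dict = field(default_factory=dict)
    frailty_sd: float = 0.0
    drug_assignment_probs: dict = field(default_factory=lambda: dict(DEFAULT_DRUG_PROBS))
    birth_year_range: tuple = (1940, 2005)
    female_frac: float = 0.8
    layer_duplication_rate: float = 0.05
    conflict_rate: float = 0.01
    decoy_segment_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        for name, p in [
            ("star37_carrier_freq", self.star37_carrier_freq),
            ("layer_duplication_rate", self.layer_duplication_rate),
            ("conflict_rate", self.conflict_rate),
            ("decoy_segment_rate", self.decoy_segment_rate),
            ("female_frac", self.female_frac),
            *[(f"freq[{k}]", v) for k, v in self.haplotype_freqs.items()],
            *[(f"drug_prob[{k}]", v) for k, v in self.drug_assignment_probs.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if self.pgs_corr is not None:
            c = np.asarray(self.pgs_corr, dtype=float)
            k = len(self.pgs_names)
            if c.shape != (k, k):
                raise ValueError(f"pgs_corr shape {c.shape} does not match {k} scores")
            if not np.allclose(c, c.T, atol=1e-12):
                raise ValueError("pgs_corr must be symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-12):
                raise ValueError("pgs_corr must have unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ValueError("pgs_corr is not positive semi-definite")
        unknown_drugs = set(self.drug_assignment_probs) - set(ALL_DRUGS)
        if unknown_drugs:
            raise ValueError(f"unknown drugs: {sorted(unknown_drugs)}")
        for (pred, outcome, group) in self.effects:
            kind, _, name = pred.partition(":")
            if kind == "metaboliser":
                if name not in PHENOTYPES:
                    raise ValueError(f"unknown metaboliser level in effect key {pred!r}")
            elif kind == "pgs":
                if name not in self.pgs_names:
                    raise ValueError(f"unknown PGS in effect key {pred!r}")
            else:
                raise ValueError(f"unknown predictor key {pred!r}")
            if outcome != "any" and outcome not in self.baseline_logit:
                raise ValueError(f"effect outcome {outcome!r} not among simulated outcomes")
            resolve_group(group)
        bad_codes = set(self.baseline_logit) - RECORD_VOCABULARY
        if bad_codes:
            raise ValueError(f"unknown outcome codes: {sorted(bad_codes)}")

    @property
    def outcomes(self) -> tuple:
        return tuple(self.baseline_logit)


@dataclass
class SimulatedHaplotypes:
    sample_ids: list
    labels: np.ndarray  # (n, 2) star-allele labels
    states: np.ndarray  # (n, 2, n_positions) variant states


@dataclass
class SyntheticCohort:
    config: CohortConfig
    sample_ids: list
    haplotypes: SimulatedHaplotypes
    cnv_segments: pd.DataFrame
    star37_carrier: np.ndarray
    pgs: pd.DataFrame
    covariates: pd.DataFrame
    exposure: pd.DataFrame
    true_phenotype: np.ndarray
    outcomes: pd.DataFrame
    records: pd.DataFrame | None


def _sample_ids(n: int) -> list:
    return [f"S{i:06d}" for i in range(n)]


def simulate_haplotypes(config: CohortConfig, defs=None) -> SimulatedHaplotypes:
    """Draw two star-allele haplotypes per sample i.i.d. (Hardy-Weinberg)."""
    defs = defs or load_allele_definitions()
    labels_, freqs = zip(*config.haplotype_freqs.items())
    unknown = set(labels_) - set(defs.labels)
    if unknown:
        raise ValueError(f"haplotype frequencies for alleles not in the table: {sorted(unknown)}")
    rng = _rng(config.seed, "haplotypes")
    idx = rng.choice(len(labels_), size=(config.n_samples, 2), p=np.asarray(freqs))
    positions = defs.positions
    pos_index = {p: i for i, p in enumerate(positions)}
    proto = np.zeros((len(labels_), len(positions)), dtype=np.int8)
    for j, lab in enumerate(labels_):
        for p, _ in defs.entries[lab]:
            proto[j, pos_index[p]] = 1
    return SimulatedHaplotypes(
        sample_ids=_sample_ids(config.n_samples),
        labels=np.asarray(labels_, dtype=object)[idx],
        states=proto[idx],
    )


def simulate_cnv_segments(
    config: CohortConfig, gene=None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate per-sample CNV segments; returns (BED-like frame, carrier truth).

    Carriers receive one ~61.8 kbp deletion fully covering exons 1-5; a small
    fraction of non-carriers receive decoy segments (intronic deletions or a
    whole-gene duplication) that a correct *37 caller must ignore.
    """
    gene = gene or load_gene_model()
    rng = _rng(config.seed, "cnv")
    n = config.n_samples
    ids = _sample_ids(n)
    carrier = rng.random(n) < config.star37_carrier_freq
    decoy = (~carrier) & (rng.random(n) < config.decoy_segment_rate)

    exons15 = gene.exon_intervals(*STAR37_EXON_RANGE)
    u_start, u_end = exons15[0][0], exons15[-1][1]
    rows = []
    for i in np.nonzero(carrier)[0]:
        length = int(STAR37_DELETION_LENGTH * rng.uniform(0.97, 1.03))
        start = int(rng.integers(u_end - length, u_start + 1))
        rows.append((ids[i], gene.chromosome, start, start + length, "DEL", 1))
    gap_start, gap_end = u_end + 2_000, gene.exons[STAR37_EXON_RANGE[1]][0] - 2_000
    for i in np.nonzero(decoy)[0]:
        if rng.random() < 0.5:
            length = int(rng.integers(20_000, min(40_000, gap_end - gap_start)))
            start = int(rng.integers(gap_start, gap_end - length))
            rows.append((ids[i], gene.chromosome, start, start + length, "DEL", 1))
        else:
            s, e = gene.span
            rows.append((ids[i], gene.chromosome, s - 1_000, e + 1_000, "DUP", 3))
    segments = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "svtype", "copy_number"]
    )
    return segments, carrier


def simulate_pgs(config: CohortConfig) -> pd.DataFrame:
    """Multivariate-normal scores with standard-normal marginals."""
    rng = _rng(config.seed, "pgs")
    k = len(config.pgs_names)
    z = rng.standard_normal((config.n_samples, k))
    if config.pgs_corr is not None:
        c = np.asarray(config.pgs_corr, dtype=float)
        w, v = np.linalg.eigh(c)
        root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
        z = z @ root
    df = pd.DataFrame(z, columns=[f"pgs_{n}" for n in config.pgs_names])
    df.insert(0, "sample_id", _sample_ids(config.n_samples))
    return df


def simulate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Birth year (uniform over range), sex (Bernoulli female), 10 standard-normal PCs."""
    rng = _rng(config.seed, "covariates")
    n = config.n_samples
    lo, hi = config.birth_year_range
    birth_year = rng.integers(lo, hi + 1, size=n)
    female = (rng.random(n) < config.female_frac).astype(int)
    pcs = rng.standard_normal((n, 10))
    df = pd.DataFrame({"sample_id": _sample_ids(n), "birth_year": birth_year, "female": female})
    df["sex"] = np.where(female == 1, "female", "male")
    for j in range(10):
        df[f"pc{j + 1}"] = pcs[:, j]
    return df


def simulate_drug_exposure(config: CohortConfig) -> pd.DataFrame:
    """Per-drug exposure indicators; every sample takes at least one drug."""
    rng = _rng(config.seed, "drugs")
    drugs = list(config.drug_assignment_probs)
    probs = np.array([config.drug_assignment_probs[d] for d in drugs])
    took = rng.random((config.n_samples, len(drugs))) < probs
    none = ~took.any(axis=1)
    if none.any():
        forced = rng.choice(len(drugs), size=int(none.sum()), p=probs / probs.sum())
        took[np.nonzero(none)[0], forced] = True
    df = pd.DataFrame(took, columns=[f"drug_{d}" for d in drugs])
    df.insert(0, "sample_id", _sample_ids(config.n_samples))
    return df


def true_metaboliser(labels: np.ndarray, carrier: np.ndarray) -> np.ndarray:
    """Generative-truth phenotype from haplotype labels and *37 carrier status.

    Applies the same replacement rule as the caller: the deletion replaces the
    reference-matching haplotype, otherwise the later-sorted label.
    """
    out = np.empty(len(labels), dtype=object)
    cache: dict = {}
    for i, ((a, b), c) in enumerate(zip(labels, carrier)):
        key = (a, b, bool(c))
        if key not in cache:
            pair = [a, b]
            if c:
                if REFERENCE_ALLELE in pair:
                    pair[pair.index(REFERENCE_ALLELE)] = "*37"
                else:
                    j = max(range(2), key=lambda t: star_alleles.star_sort_key(pair[t]))
                    pair[j] = "*37"
            cache[key] = assign_metaboliser(*pair)
        out[i] = cache[key]
    return out


def _effect_design(config, outcome, phenotype, pgs, exposure):
    """Sum of configured genetic effects on one outcome's linear predictor."""
    n = len(phenotype)
    lp = np.zeros(n)
    for (pred, out_key, group), beta in config.effects.items():
        if out_key != outcome and out_key != "any":
            continue
        drugs = resolve_group(group)
        in_group = np.zeros(n, dtype=bool)
        for d in drugs:
            col = f"drug_{d}"
            if col in exposure.columns:
                in_group |= exposure[col].to_numpy()
        kind, _, name = pred.partition(":")
        if kind == "metaboliser":
            x = (phenotype == name).astype(float)
        else:
            x = pgs[f"pgs_{name}"].to_numpy()
        lp += beta * x * in_group
    return lp


def simulate_outcomes(
    config: CohortConfig,
    phenotype: np.ndarray,
    pgs: pd.DataFrame,
    covariates: pd.DataFrame,
    exposure: pd.DataFrame,
) -> pd.DataFrame:
    """Bernoulli side-effect presence per (sample, outcome).

    logit P(present) = baseline + shared frailty + covariate terms (centred)
    + configured genetic effects gated on drug-group exposure.
    """
    rng = _rng(config.seed, "outcomes")
    n = config.n_samples
    lo, hi = config.birth_year_range
    base_cov = np.zeros(n)
    for cov, beta in config.covariate_effects.items():
        if cov == "female":
            base_cov += beta * (covariates["female"].to_numpy() - config.female_frac)
        elif cov == "birth_year":
            base_cov += beta * (covariates["birth_year"].to_numpy() - (lo + hi) / 2.0)
        elif cov in covariates.columns:
            base_cov += beta * covariates[cov].to_numpy()
        else:
            raise ValueError(f"unknown covariate {cov!r} in covariate_effects")
    frailty = config.frailty_sd * rng.standard_normal(n) if config.frailty_sd > 0 else 0.0

    out = {}
    for outcome, b0 in config.baseline_logit.items():
        lp = b0 + base_cov + frailty + _effect_design(config, outcome, phenotype, pgs, exposure)
        out[outcome] = rng.random(n) < expit(lp)
    df = pd.DataFrame(out)
    df.insert(0, "sample_id", _sample_ids(n))
    return df


def simulate_records(
    config: CohortConfig,
    outcomes: pd.DataFrame,
    exposure: pd.DataFrame,
) -> pd.DataFrame:
    """Emit per-(sample, drug, side-effect) records across the three layers.

    Present outcomes are attributed to one taken drug — preferring drugs in
    the group of a configured effect on that outcome, so that group-level
    case/control construction recovers the generative model. Duplicate records
    appear in a second layer at ``layer_duplication_rate``; conflicting
    (flipped-presence) records at ``conflict_rate``.
    """
    rng = _rng(config.seed, "records")
    drugs = [c.removeprefix("drug_") for c in exposure.columns if c.startswith("drug_")]
    E = exposure[[f"drug_{d}" for d in drugs]].to_numpy()
    n, D = E.shape

    # attribution: random priority over taken drugs, boosted inside effect groups
    group_by_outcome: dict[str, frozenset] = {}
    for (pred, out_key, group), _beta in config.effects.items():
        for oc in config.outcomes:
            if out_key == oc or out_key == "any":
                group_by_outcome.setdefault(oc, resolve_group(group))

    sample_idx, drug_idx = np.nonzero(E)
    frames = []
    for outcome in config.outcomes:
        y = outcomes[outcome].to_numpy()
        prio = rng.random((n, D))
        prio[~E] = -np.inf
        boost = group_by_outcome.get(outcome)
        if boost is not None:
            in_grp = np.array([d in boost for d in drugs])
            prio[:, in_grp] += np.where(E[:, in_grp], 2.0, 0.0)
        attributed = prio.argmax(axis=1)
        present = y[sample_idx] & (attributed[sample_idx] == drug_idx)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.asarray(_sample_ids(n), dtype=object)[sample_idx],
                    "drug": np.asarray(drugs, dtype=object)[drug_idx],
                    "side_effect": outcome,
                    "present": present,
                }
            )
        )
    rec = pd.concat(frames, ignore_index=True)
    m = len(rec)
    layer_idx = rng.choice(len(LAYERS), size=m, p=[0.30, 0.35, 0.35])
    rec["layer"] = np.asarray(LAYERS, dtype=object)[layer_idx]

    dup_mask = rng.random(m) < config.layer_duplication_rate
    dups = rec.loc[dup_mask].copy()
    dups["layer"] = np.asarray(LAYERS, dtype=object)[
        (layer_idx[dup_mask] + rng.integers(1, 3, size=int(dup_mask.sum()))) % 3
    ]
    conf_mask = rng.random(m) < config.conflict_rate
    confs = rec.loc[conf_mask].copy()
    confs["present"] = ~confs["present"].to_numpy()
    confs["layer"] = np.asarray(LAYERS, dtype=object)[
        (layer_idx[conf_mask] + rng.integers(1, 3, size=int(conf_mask.sum()))) % 3
    ]
    out = pd.concat([rec, dups, confs], ignore_index=True)
    return out.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def simulate_cohort(config: CohortConfig, *, include_records: bool = True) -> SyntheticCohort:
    """Run every generator and bundle the results."""
    defs = load_allele_definitions()
    gene = load_gene_model()
    haps = simulate_haplotypes(config, defs)
    cnv, carrier = simulate_cnv_segments(config, gene)
    pgs = simulate_pgs(config)
    cov = simulate_covariates(config)
    exposure = simulate_drug_exposure(config)
    pheno = true_metaboliser(haps.labels, carrier)
    outcomes = simulate_outcomes(config, pheno, pgs, cov, exposure)
    records = simulate_records(config, outcomes, exposure) if include_records else None
    return SyntheticCohort(
        config=config,
        sample_ids=haps.sample_ids,
        haplotypes=haps,
        cnv_segments=cnv,
        star37_carrier=carrier,
        pgs=pgs,
        covariates=cov,
        exposure=exposure,
        true_phenotype=pheno,
        outcomes=outcomes,
        records=records,
    )


def analysis_table(
    cohort: SyntheticCohort, *, consensus: bool = False, via_caller: bool = True
) -> pd.DataFrame:
    """Assemble the sample-level analysis frame (covariates, PGS, exposure,
    metaboliser, outcome indicators with a pooled ``se_any`` column).

    With ``via_caller`` the metaboliser column comes from the full calling
    pipeline (variant matcher + *37 CNV caller, optionally dual-caller
    consensus); otherwise the generative truth is used.
    """
    df = cohort.covariates.merge(cohort.pgs, on="sample_id").merge(
        cohort.exposure, on="sample_id"
    )
    if via_caller:
        from .phenotype import add_phenotype_column

        calls, _report = star_alleles.call_cohort(
            cohort.sample_ids,
            cohort.haplotypes.states,
            cohort.cnv_segments,
            load_allele_definitions(),
            load_gene_model(),
            consensus=consensus,
        )
        calls = add_phenotype_column(calls)
        df = df.merge(calls[["sample_id", "metaboliser"]], on="sample_id", how="left")
    else:
        df["metaboliser"] = cohort.true_phenotype
    outcome_cols = cohort.outcomes.rename(
        columns={c: f"se_{c}" for c in cohort.outcomes.columns if c != "sample_id"}
    )
    df = df.merge(outcome_cols, on="sample_id")
    se_cols = [c for c in df.columns if c.startswith("se_")]
    df["se_any"] = df[se_cols].any(axis=1)
    return df


# ---------------------------------------------------------------------------
# scenario calibration


def calibrate_baseline_logits(prevalences: dict, latent_sd: float, nodes: int = 41) -> dict:
    """Baseline logits whose marginal prevalence matches ``prevalences`` when a
    N(0, latent_sd²) latent term (frailty + covariate effects) is integrated out."""
    x, w = hermegauss(nodes)
    w = w / w.sum()

    def marginal(b):
        return float(w @ expit(b + latent_sd * x))

    out = {}
    for outcome, p in prevalences.items():
        if not 0 < p < 1:
            raise ValueError(f"prevalence for {outcome!r} outside (0, 1)")
        bound = 20.0 + 10.0 * latent_sd
        out[outcome] = brentq(lambda b: marginal(b) - p, -bound, bound, xtol=1e-10)
    return out


def calibrate_frailty_sd(
    prevalences: dict, target_pooled: float, covariate_var: float = 0.0, nodes: int = 41
) -> float:
    """Shared-frailty SD such that pooled any-side-effect prevalence hits target.

    Side effects co-occur in real cohorts; a shared per-sample latent term
    reproduces that. Marginals are held at ``prevalences`` (baselines are
    recalibrated inside the solve); ``covariate_var`` is the variance already
    contributed by shared covariate effects.
    """
    x, w = hermegauss(nodes)
    w = w / w.sum()

    def pooled(total_sd):
        b = calibrate_baseline_logits(prevalences, total_sd, nodes)
        none = np.ones_like(x)
        for outcome in prevalences:
            none = none * (1.0 - expit(b[outcome] + total_sd * x))
        return float(w @ (1.0 - none))

    indep = pooled(np.sqrt(covariate_var))
    if target_pooled >= indep:
        return 0.0
    total = brentq(lambda s: pooled(s) - target_pooled, np.sqrt(covariate_var), 25.0, xtol=1e-8)
    return float(np.sqrt(max(total**2 - covariate_var, 0.0)))


@lru_cache(maxsize=1)
def _default_calibration() -> tuple[float, tuple]:
    lo, hi = 1940, 2005
    cov_var = (
        DEFAULT_COVARIATE_EFFECTS["female"] ** 2 * 0.8 * 0.2
        + DEFAULT_COVARIATE_EFFECTS["birth_year"] ** 2 * (hi - lo + 1) ** 2 / 12.0
    )
    frailty = calibrate_frailty_sd(DEFAULT_PREVALENCE, 0.52, covariate_var=cov_var)
    latent = float(np.sqrt(frailty**2 + cov_var))
    baselines = calibrate_baseline_logits(DEFAULT_PREVALENCE, latent)
    return frailty, tuple(baselines.items())


def default_scenario(n_samples: int = 13_729, seed: int = 0) -> CohortConfig:
    """The faithful demo scenario: published metaboliser frequencies, published
    point-estimate effects, 23 side effects at their stated marginal rates, and
    a shared frailty calibrated so pooled prevalence ≈ 52%."""
    frailty, baselines = _default_calibration()
    return CohortConfig(
        n_samples=n_samples,
        effects=dict(DEFAULT_EFFECTS),
        baseline_logit=dict(baselines),
        covariate_effects=dict(DEFAULT_COVARIATE_EFFECTS),
        frailty_sd=frailty,
        seed=seed,
    )


def cyp2c19_scenario(
    n_samples: int = 9_563,
    seed: int = 0,
    *,
    poor_or: float = 1.49,
    ultrarapid_or: float = 0.83,
    null: bool = False,
) -> CohortConfig:
    """Cohort of users of the four CYP2C19-metabolised drugs with a single
    pooled any-side-effect outcome — the generative inverse of the primary
    pharmacogenetic model."""
    cyp_drugs = sorted(DRUG_GROUPS["CYP2C19_SET"])
    probs = {d: DEFAULT_DRUG_PROBS[d] for d in cyp_drugs}
    effects = {} if null else {
        ("metaboliser:poor", "any", "CYP2C19_SET"): log(poor_or),
        ("metaboliser:ultrarapid", "any", "CYP2C19_SET"): log(ultrarapid_or),
    }
    return CohortConfig(
        n_samples=n_samples,
        effects=effects,
        baseline_logit={"any": 0.08},
        covariate_effects=dict(DEFAULT_COVARIATE_EFFECTS),
        drug_assignment_probs=probs,
        seed=seed,
    )


def simulate_summary_stats(
    true_beta: dict, se: dict, cohort: str, seed: int
) -> pd.DataFrame:
    """Per-(drug, phenotype) summary statistics for a cohort: beta ~ N(true, se).

    Stands in for a second cohort's published per-drug logistic estimates in
    meta-analysis simulations.
    """
    rng = _rng(seed, "summary")
    rows = []
    for key, b in true_beta.items():
        drug, phenotype = key
        s = se[key]
        rows.append(
            {
                "cohort": cohort,
                "drug": drug,
                "phenotype": phenotype,
                "beta": float(b + s * rng.standard_normal()),
                "se": float(s),
            }
        )
    return pd.DataFrame(rows)
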