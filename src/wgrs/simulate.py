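"""Synthetic genotype-phenotype cohorts with the structure the analysis assumes.

The generative model is logistic throughout (the source study is
observational and implies no generative model; this one is the package's
own choice, documented in the methods note):

* genotypes: independent SNPs in Hardy-Weinberg equilibrium, effect-allele
  count ``X_i ~ Binomial(2, p_i)``; no linkage disequilibrium.
* disease: ``is_case ~ Bernoulli(sigmoid(case_intercept + sum_i W_i X_i))``
  — the panel weights are the generative per-allele log-ORs, so the raw
  weighted score *is* the genetic liability.
* diathesis (cases only): each feature ``f ~ Bernoulli(sigmoid(a_f +
  gamma_f * wGRS))``; controls carry no diathesis or recurrence values.
* recurrence (cases only): ``Bernoulli(sigmoid(a_r + beta * wGRS +
  sum_f delta_f * f))``.
* sex: ``Bernoulli(male_fraction)``, independent of genotype.

Missingness is MCAR, applied after the complete-data truth is drawn and
retained, so parameter-recovery tests can compare against exact targets.
Ectopic disease is never masked by default, mirroring a chain in which it
had no missing data.

Cohorts of a fixed case/control composition are drawn by rejection: keep
sampling individuals from the population model until the requested numbers
of cases and controls are collected.  This reproduces case ascertainment —
cases are genuinely enriched for risk alleles, which is what separates the
case and control score means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError
from .io_formats import (
    CASE_ONLY_PHENOTYPES,
    BINARY_PHENOTYPES,
    GenotypeMatrix,
    PhenotypeTable,
    WeightPanel,
)
from .panel import default_allele_freqs, default_panel
from .rng import substream

__all__ = [
    "DiathesisEffect",
    "RecurrenceModel",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "apply_missingness",
    "simulate_two_cohorts",
    "default_config",
    "default_two_cohort_configs",
]

DIATHESIS = ["family_history", "early_onset", "bilateral", "ectopic"]
#: phenotype columns eligible for MCAR masking (ectopic stays complete)
MASKABLE_PHENOTYPES = ["sex", "family_history", "early_onset", "bilateral", "recurrence"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class DiathesisEffect:
    """Logistic model of one diathesis feature on the score."""

    intercept: float
    slope: float  # per-unit wGRS log-OR


@dataclass(frozen=True)
class RecurrenceModel:
    """Logistic model of recurrence on the score and the four features."""

    intercept: float
    beta: float  # per-unit wGRS log-OR
    deltas: Mapping[str, float]  # per-feature log-ORs

    def __post_init__(self) -> None:
        missing = [f for f in DIATHESIS if f not in self.deltas]
        if missing:
            raise ConfigError(f"recurrence model missing feature effects: {missing}")


@dataclass(frozen=True)
class SimulationConfig:
    label: str
    n_cases: int
    n_controls: int
    allele_freqs: tuple[float, ...]
    true_panel: WeightPanel
    case_intercept: float
    diathesis_effects: Mapping[str, DiathesisEffect]
    recurrence_model: RecurrenceModel
    male_fraction: float = 0.75
    genotype_missing_rate: float = 0.0
    phenotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.allele_freqs)
        object.__setattr__(self, "allele_freqs", freqs)
        if self.n_cases <= 0:
            raise ConfigError("n_cases must be positive")
        if self.n_controls < 0:
            raise ConfigError("n_controls must be non-negative")
        if len(freqs) != self.true_panel.panel_size:
            raise ConfigError(
                f"allele_freqs length {len(freqs)} != panel size {self.true_panel.panel_size}"
            )
        if any(not (0.0 < f < 1.0) for f in freqs):
            raise ConfigError("allele frequencies must lie strictly in (0, 1)")
        for name, rate in (
            ("genotype_missing_rate", self.genotype_missing_rate),
            ("phenotype_missing_rate", self.phenotype_missing_rate),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ConfigError("male_fraction must lie in [0, 1]")
        missing = [f for f in DIATHESIS if f not in self.diathesis_effects]
        if missing:
            raise ConfigError(f"diathesis_effects missing features: {missing}")

    def to_dict(self) -> dict:
        """JSON/YAML-serialisable provenance record of every parameter."""
        return {
            "label": self.label,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "allele_freqs": list(self.allele_freqs),
            "panel": self.true_panel.to_frame().to_dict("records"),
            "case_intercept": self.case_intercept,
            "diathesis_effects": {
                k: {"intercept": v.intercept, "slope": v.slope}
                for k, v in self.diathesis_effects.items()
            },
            "recurrence_model": {
                "intercept": self.recurrence_model.intercept,
                "beta": self.recurrence_model.beta,
                "deltas": dict(self.recurrence_model.deltas),
            },
            "male_fraction": self.male_fraction,
            "genotype_missing_rate": self.genotype_missing_rate,
            "phenotype_missing_rate": self.phenotype_missing_rate,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SimulatedCohort:
    """A cohort plus the complete-data truth behind it."""

    genotypes: GenotypeMatrix  # post-missingness (observed)
    phenotypes: PhenotypeTable  # post-missingness (observed)
    config: SimulationConfig
    true_wgrs: pd.Series  # latent complete-data score per sample
    true_genotypes: GenotypeMatrix = None  # pre-missingness truth
    true_phenotypes: PhenotypeTable = None

    def __post_init__(self) -> None:
        if self.true_genotypes is None:
            object.__setattr__(self, "true_genotypes", self.genotypes)
        if self.true_phenotypes is None:
            object.__setattr__(self, "true_phenotypes", self.phenotypes)


def simulate_genotypes(
    n: int,
    freqs,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "S",
) -> GenotypeMatrix:
    """Draw n individuals' effect-allele counts under Hardy-Weinberg.

    Each SNP is independent Binomial(2, p_i).  Provide either ``seed`` or an
    existing generator.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ConfigError("freqs must be a non-empty 1-d array")
    if ((freqs <= 0.0) | (freqs >= 1.0)).any():
        raise ConfigError("allele frequencies must lie strictly in (0, 1)")
    if rng is None:
        rng = substream(0 if seed is None else seed, "genotypes")
    counts = rng.binomial(2, freqs, size=(n, freqs.size)).astype(float)
    index = pd.Index([f"{id_prefix}{i + 1:06d}" for i in range(n)], name="sample_id")
    snp_ids = [f"snp{j + 1:02d}" for j in range(freqs.size)]
    return GenotypeMatrix(pd.DataFrame(counts, index=index, columns=snp_ids))


def _phenotype_frame(
    index: pd.Index,
    raw_score: np.ndarray,
    is_case: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(index)
    data = pd.DataFrame(index=index, columns=BINARY_PHENOTYPES, dtype=float)
    data["sex"] = (rng.random(n) < config.male_fraction).astype(float)
    data["is_case"] = is_case.astype(float)
    case = is_case.astype(bool)
    feats = {}
    for f in DIATHESIS:
        eff = config.diathesis_effects[f]
        p = _sigmoid(eff.intercept + eff.slope * raw_score[case])
        feats[f] = (rng.random(case.sum()) < p).astype(float)
        col = np.full(n, np.nan)
        col[case] = feats[f]
        data[f] = col
    rm = config.recurrence_model
    eta = rm.intercept + rm.beta * raw_score[case]
    for f in DIATHESIS:
        eta = eta + rm.deltas[f] * feats[f]
    rec = np.full(n, np.nan)
    rec[case] = (rng.random(case.sum()) < _sigmoid(eta)).astype(float)
    data["recurrence"] = rec
    return data


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> SimulatedCohort:
    """Assign case status, diathesis and recurrence to complete genotypes.

    Case status is a population Bernoulli draw here (no quota); use
    :func:`simulate_cohort` for a fixed case/control composition.
    Genotypes must be complete — missingness is applied afterwards with
    :func:`apply_missingness`.
    """
    counts = genotypes.counts
    if list(counts.columns) != config.true_panel.snp_ids:
        raise ConfigError("genotype snp_ids do not match the config panel")
    if counts.isna().any().any():
        raise ConfigError("simulate_phenotypes requires complete genotypes")
    rng = substream(config.seed, "phenotypes")
    raw = counts.to_numpy() @ config.true_panel.weights
    is_case = (rng.random(len(counts)) < _sigmoid(config.case_intercept + raw)).astype(float)
    data = _phenotype_frame(counts.index, raw, is_case, config, rng)
    true_wgrs = pd.Series(raw, index=counts.index, name="true_wgrs")
    return SimulatedCohort(
        genotypes=genotypes,
        phenotypes=PhenotypeTable(data),
        config=config,
        true_wgrs=true_wgrs,
    )


_BATCH = 8192


def simulate_cohort(config: SimulationConfig, apply_missing: bool = True) -> SimulatedCohort:
    """Draw a cohort with exactly the configured case/control numbers.

    Individuals are sampled from the population model and kept until both
    quotas fill (rejection sampling), preserving the ascertainment-induced
    score shift between cases and controls.  Missingness is then applied at
    the configured MCAR rates unless ``apply_missing`` is False.
    """
    freqs = np.asarray(config.allele_freqs)
    w = config.true_panel.weights
    rng_g = substream(config.seed, "genotypes")
    rng_p = substream(config.seed, "phenotypes")
    kept_counts: list[np.ndarray] = []
    kept_case: list[np.ndarray] = []
    n_case = n_ctrl = 0
    while n_case < config.n_cases or n_ctrl < config.n_controls:
        x = rng_g.binomial(2, freqs, size=(_BATCH, freqs.size)).astype(float)
        raw = x @ w
        is_case = rng_p.random(_BATCH) < _sigmoid(config.case_intercept + raw)
        keep = np.zeros(_BATCH, dtype=bool)
        for i in range(_BATCH):
            if is_case[i] and n_case < config.n_cases:
                keep[i] = True
                n_case += 1
            elif not is_case[i] and n_ctrl < config.n_controls:
                keep[i] = True
                n_ctrl += 1
        kept_counts.append(x[keep])
        kept_case.append(is_case[keep].astype(float))
    counts = np.concatenate(kept_counts)[: config.n_cases + config.n_controls]
    is_case = np.concatenate(kept_case)[: config.n_cases + config.n_controls]
    index = pd.Index(
        [f"{config.label}_{i + 1:06d}" for i in range(len(counts))], name="sample_id"
    )
    snp_ids = config.true_panel.snp_ids
    genotypes = GenotypeMatrix(pd.DataFrame(counts, index=index, columns=snp_ids))
    raw = counts @ w
    data = _phenotype_frame(index, raw, is_case, config, rng_p)
    cohort = SimulatedCohort(
        genotypes=genotypes,
        phenotypes=PhenotypeTable(data),
        config=config,
        true_wgrs=pd.Series(raw, index=index, name="true_wgrs"),
    )
    if apply_missing and (config.genotype_missing_rate > 0 or config.phenotype_missing_rate > 0):
        cohort = apply_missingness(
            cohort,
            config.genotype_missing_rate,
            config.phenotype_missing_rate,
            seed=config.seed,
        )
    return cohort


def apply_missingness(
    cohort: SimulatedCohort,
    genotype_rate: float,
    phenotype_rate: float,
    seed: int,
) -> SimulatedCohort:
    """Mask cells missing-completely-at-random at the given rates.

    Every genotype cell, and every imputable phenotype cell (sex,
    family history, early onset, bilateral, recurrence — never ectopic,
    never case status), is masked independently.  Masking starts from the
    complete-data truth retained in the cohort, so re-applying missingness
    does not compound.
    """
    for name, rate in (("genotype", genotype_rate), ("phenotype", phenotype_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ConfigError(f"{name} missingness rate must lie in [0, 1]")
    rng = substream(seed, "missingness")
    gcounts = cohort.true_genotypes.counts.copy()
    mask = rng.random(gcounts.shape) < genotype_rate
    gvals = gcounts.to_numpy()
    gvals[mask] = np.nan
    gcounts = pd.DataFrame(gvals, index=gcounts.index, columns=gcounts.columns)

    pdata = cohort.true_phenotypes.data.copy()
    is_case = pdata["is_case"].to_numpy() == 1.0
    for col in MASKABLE_PHENOTYPES:
        eligible = is_case if col in CASE_ONLY_PHENOTYPES else np.ones(len(pdata), dtype=bool)
        hit = (rng.random(len(pdata)) < phenotype_rate) & eligible
        vals = pdata[col].to_numpy()
        vals[hit] = np.nan
        pdata[col] = vals

    return SimulatedCohort(
        genotypes=GenotypeMatrix(gcounts),
        phenotypes=PhenotypeTable(pdata),
        config=cohort.config,
        true_wgrs=cohort.true_wgrs,
        true_genotypes=cohort.true_genotypes,
        true_phenotypes=cohort.true_phenotypes,
    )


def simulate_two_cohorts(
    config_a: SimulationConfig, config_b: SimulationConfig
) -> tuple[SimulatedCohort, SimulatedCohort]:
    """Two independently seeded cohorts (the two-cohort replication design)."""
    if config_a.seed == config_b.seed and config_a.label == config_b.label:
        raise ConfigError("the two cohorts must differ in seed or label")
    return simulate_cohort(config_a), simulate_cohort(config_b)


# ---------------------------------------------------------------------------
# default configurations, calibrated against the population score distribution


_CAL_SEED = 20260901  # internal calibration stream, independent of user seeds
_CAL_N = 40000


def _calibrate_intercept(target: float, eta_without_intercept: np.ndarray, weights: np.ndarray) -> float:
    """Intercept a such that weighted mean of sigmoid(a + eta) hits ``target``."""

    def gap(a: float) -> float:
        return float(np.average(_sigmoid(a + eta_without_intercept), weights=weights) - target)

    return brentq(gap, -40.0, 40.0)


def default_config(
    label: str = "uk",
    n_cases: int = 6126,
    n_controls: int = 6126,
    seed: int = 0,
    *,
    panel: WeightPanel | None = None,
    allele_freqs=None,
    per_unit_recurrence_or: float = 1.18,
    diathesis_prevalence: Mapping[str, float] | None = None,
    diathesis_slope_or: float = 1.2,
    recurrence_prevalence: float = 0.45,
    recurrence_feature_ors: Mapping[str, float] | None = None,
    case_fraction: float = 0.5,
    genotype_missing_rate: float = 0.01,
    phenotype_missing_rate: float = 0.05,
    male_fraction: float = 0.75,
) -> SimulationConfig:
    """Build a cohort configuration with intercepts calibrated by root-finding.

    Marginal targets (case fraction during sampling, diathesis feature
    prevalences among cases, recurrence prevalence among cases) are turned
    into intercepts by solving the corresponding one-dimensional mean
    equations on a fixed internal calibration sample, so the shipped
    defaults land near the prevalences the study tabulates (bilateral most
    common at ~63%/40%, ectopic rarest at ~12%).
    """
    panel = panel or default_panel()
    freqs = np.asarray(default_allele_freqs() if allele_freqs is None else allele_freqs, dtype=float)
    if diathesis_prevalence is None:
        diathesis_prevalence = {
            "family_history": 0.45,
            "early_onset": 0.40,
            "bilateral": 0.63,
            "ectopic": 0.12,
        }
    if recurrence_feature_ors is None:
        recurrence_feature_ors = {
            "family_history": 1.4,
            "early_onset": 2.0,
            "bilateral": 1.5,
            "ectopic": 1.6,
        }
    rng = substream(_CAL_SEED, "calibration")
    x = rng.binomial(2, freqs, size=(_CAL_N, freqs.size)).astype(float)
    raw = x @ panel.weights
    uniform = np.ones_like(raw)
    case_intercept = _calibrate_intercept(case_fraction, raw, uniform)
    case_w = _sigmoid(case_intercept + raw)  # importance weights for "given case"

    gamma = math.log(diathesis_slope_or)
    effects = {}
    feat_draws = {}
    for f in DIATHESIS:
        a_f = _calibrate_intercept(diathesis_prevalence[f], gamma * raw, case_w)
        effects[f] = DiathesisEffect(intercept=a_f, slope=gamma)
        feat_draws[f] = (rng.random(_CAL_N) < _sigmoid(a_f + gamma * raw)).astype(float)

    beta = math.log(per_unit_recurrence_or)
    deltas = {f: math.log(recurrence_feature_ors[f]) for f in DIATHESIS}
    eta_rec = beta * raw + sum(deltas[f] * feat_draws[f] for f in DIATHESIS)
    a_r = _calibrate_intercept(recurrence_prevalence, eta_rec, case_w)

    return SimulationConfig(
        label=label,
        n_cases=n_cases,
        n_controls=n_controls,
        allele_freqs=tuple(freqs.tolist()),
        true_panel=panel,
        case_intercept=case_intercept,
        diathesis_effects=effects,
        recurrence_model=RecurrenceModel(intercept=a_r, beta=beta, deltas=deltas),
        male_fraction=male_fraction,
        genotype_missing_rate=genotype_missing_rate,
        phenotype_missing_rate=phenotype_missing_rate,
        seed=seed,
    )


def default_two_cohort_configs(
    seed: int = 0,
    n_cases_a: int = 6126,
    n_cases_b: int = 1730,
    n_controls_a: int = 6126,
    n_controls_b: int = 1000,
) -> tuple[SimulationConfig, SimulationConfig]:
    """The two-cohort replication setup.

    Cohort A mirrors the larger UK-style discovery cohort (6126 cases,
    per-unit recurrence OR 1.18, near-complete genotyping); cohort B the
    smaller Dutch-style cohort (1730 cases, per-unit OR 1.22, ~4 of 26
    panel SNPs not directly genotyped, bilateral disease less common).
    """
    cfg_a = default_config(
        label="uk",
        n_cases=n_cases_a,
        n_controls=n_controls_a,
        seed=int(substream(seed, "cohort_a").integers(2**31)),
        per_unit_recurrence_or=1.18,
        genotype_missing_rate=0.01,
    )
    cfg_b = default_config(
        label="nl",
        n_cases=n_cases_b,
        n_controls=n_controls_b,
        seed=int(substream(seed, "cohort_b").integers(2**31)),
        per_unit_recurrence_or=1.22,
        diathesis_prevalence={
            "family_history": 0.45,
            "early_onset": 0.40,
            "bilateral": 0.40,
            "ectopic": 0.12,
        },
        genotype_missing_rate=0.15,
    )
    return cfg_a, cfg_b
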