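"""Synthetic case-control cohort generation.

Two generators are provided:

``simulate_cohort``
    A disease-model generator. Controls are drawn genotype-wise from
    Hardy-Weinberg proportions at the configured control risk-allele
    frequencies (or from a configured haplotype block), with covariates from
    the control covariate model. Cases are obtained by *exponential tilting*:
    candidates drawn from the same control model are accepted with
    probability exp(lp - bound), where lp = sum_l ln(OR_l) g_l + covariate
    terms and the bound makes the acceptance probability at most 1. Tilting
    makes the case distribution proportional to P(x) exp(lp), so the
    retrospective (case vs control) logistic model recovers exactly the
    configured per-allele log odds ratios at any acceptance rate - unlike
    acceptance through a logistic link, which attenuates retrospective odds
    ratios by roughly a factor (1 - prevalence).

``simulate_from_published_tables``
    A model-free generator that draws genotypes per group directly from a
    published group-specific genotype-frequency table. This is the fixture
    for checks against a study's printed summary tables: the group sizes
    default to the source study's 137 cases / 150 controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ALCOHOL_LEVELS, COVARIATE_COLUMNS, DIET_LEVELS, Cohort, Locus
from .errors import ConfigError, SimulationError

_AGE_BOUND_SD = 6.0  # age support used when bounding the tilt


@dataclass(frozen=True)
class CovariateModel:
    """Sampling distributions for the lifestyle covariates of one group."""

    age_mean: float = 55.0
    age_sd: float = 12.0
    p_male: float = 0.4
    diet_probs: tuple[float, float, float] = (0.1, 0.7, 0.2)  # veg / mixed / meat
    alcohol_probs: tuple[float, float, float, float] = (0.45, 0.3, 0.1, 0.15)
    p_smoker: float | None = None  # None: smoking column left missing


@dataclass
class SimConfig:
    """Configuration of the disease-model cohort generator.

    ``allele_or`` holds per-allele odds ratios (default 1 at every locus);
    ``covariate_logodds`` maps design-column names (``age``, ``sex_male``,
    ``diet_vegetarian``, ``diet_mostly_meat``, ``alcohol_score``,
    ``smoking_ever``) to log-odds effects on disease.
    """

    n_case: int
    n_control: int
    loci: Sequence[Locus]
    control_freqs: Mapping[str, float]
    allele_or: Mapping[str, float] = field(default_factory=dict)
    haplotype_block: tuple[Sequence[str], Mapping[tuple[int, ...], float]] | None = None
    covariates: CovariateModel | None = None
    covariate_logodds: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate locus ids")
        for locus_id in ids:
            f = self.control_freqs.get(locus_id)
            if f is None:
                raise ConfigError(f"no control frequency for locus {locus_id!r}")
            if not (0.0 < f < 1.0):
                raise ConfigError(f"{locus_id}: control frequency must be in (0,1), got {f}")
        for locus_id, or_ in self.allele_or.items():
            if locus_id not in ids:
                raise ConfigError(f"allele_or references unknown locus {locus_id!r}")
            if not or_ > 0:
                raise ConfigError(f"{locus_id}: odds ratio must be positive")
        if self.haplotype_block is not None:
            block_loci, hap_freqs = self.haplotype_block
            if any(l not in ids for l in block_loci):
                raise ConfigError("haplotype block references unknown loci")
            total = sum(hap_freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"haplotype frequencies sum to {total}, expected 1")


def _draw_covariates(model: CovariateModel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    diet = rng.choice(np.array(DIET_LEVELS, dtype=object), size=n,
                      p=np.asarray(model.diet_probs) / np.sum(model.diet_probs))
    alcohol = rng.choice(np.array(ALCOHOL_LEVELS, dtype=object), size=n,
                         p=np.asarray(model.alcohol_probs) / np.sum(model.alcohol_probs))
    frame = pd.DataFrame(
        {
            "age": rng.normal(model.age_mean, model.age_sd, size=n),
            "sex": np.where(rng.random(n) < model.p_male, "male", "female"),
            "diet": diet,
            "alcohol": alcohol,
        }
    )
    if model.p_smoker is None:
        frame["smoking"] = pd.Series([None] * n, dtype=object)
    else:
        frame["smoking"] = np.where(rng.random(n) < model.p_smoker, "ever", "never")
    return frame


def _covariate_lp(frame: pd.DataFrame, logodds: Mapping[str, float]) -> np.ndarray:
    lp = np.zeros(len(frame))
    for name, beta in logodds.items():
        if name == "age":
            lp += beta * frame["age"].to_numpy(dtype=float)
        elif name == "sex_male":
            lp += beta * (frame["sex"] == "male").to_numpy(dtype=float)
        elif name.startswith("diet_"):
            lp += beta * (frame["diet"] == name.removeprefix("diet_")).to_numpy(dtype=float)
        elif name == "alcohol_score":
            score = frame["alcohol"].map({lvl: i for i, lvl in enumerate(ALCOHOL_LEVELS)})
            lp += beta * score.to_numpy(dtype=float)
        elif name == "smoking_ever":
            lp += beta * (frame["smoking"] == "ever").to_numpy(dtype=float)
        else:
            raise ConfigError(f"unknown covariate effect {name!r}")
    return lp


def _lp_bound(config: SimConfig) -> float:
    bound = 0.0
    for locus in config.loci:
        log_or = np.log(config.allele_or.get(locus.locus_id, 1.0))
        bound += max(0.0, 2.0 * log_or)
    cm = config.covariates
    for name, beta in config.covariate_logodds.items():
        if cm is None:
            raise ConfigError("covariate effects configured without a covariate model")
        if name == "age":
            lo = cm.age_mean - _AGE_BOUND_SD * cm.age_sd
            hi = cm.age_mean + _AGE_BOUND_SD * cm.age_sd
            bound += max(beta * lo, beta * hi)
        elif name == "alcohol_score":
            bound += max(0.0, beta * (len(ALCOHOL_LEVELS) - 1))
        else:
            bound += max(0.0, beta)
    return bound


def _draw_genotypes(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    ids = [l.locus_id for l in config.loci]
    geno = np.empty((n, len(ids)))
    block_cols: set[int] = set()
    if config.haplotype_block is not None:
        block_loci, hap_freqs = config.haplotype_block
        haps = list(hap_freqs)
        probs = np.array([hap_freqs[h] for h in haps], dtype=float)
        probs /= probs.sum()
        pick = rng.choice(len(haps), size=(n, 2), p=probs)
        hap_arr = np.array(haps)  # (n_hap, block width)
        block_dosage = hap_arr[pick[:, 0]] + hap_arr[pick[:, 1]]
        for k, locus_id in enumerate(block_loci):
            j = ids.index(locus_id)
            geno[:, j] = block_dosage[:, k]
            block_cols.add(j)
    for j, locus_id in enumerate(ids):
        if j in block_cols:
            continue
        geno[:, j] = rng.binomial(2, config.control_freqs[locus_id], size=n)
    return geno


def _genetic_lp(config: SimConfig, geno: np.ndarray) -> np.ndarray:
    lp = np.zeros(len(geno))
    for j, locus in enumerate(config.loci):
        or_ = config.allele_or.get(locus.locus_id, 1.0)
        if or_ != 1.0:
            lp += np.log(or_) * geno[:, j]
    return lp


def _assemble(status: str, geno: np.ndarray,
              covs: pd.DataFrame | None, start: int) -> pd.DataFrame:
    n = len(geno)
    frame = pd.DataFrame(
        {
            "sample_id": [f"S{start + i:05d}" for i in range(n)],
            "status": status,
        }
    )
    if covs is not None:
        for column in ("age", "sex", "diet", "alcohol", "smoking"):
            frame[column] = covs[column].to_numpy()
    else:
        frame["age"] = np.nan
        for column in ("sex", "diet", "alcohol", "smoking"):
            frame[column] = pd.Series([None] * n, dtype=object)
    return frame


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a case-control cohort under the configured disease model.

    Fully reproducible given ``config.seed``; raises ``SimulationError`` if
    the tilted acceptance rate is too low to produce the requested number of
    cases within a bounded number of candidate draws.
    """
    rng = np.random.default_rng(config.seed)

    # controls: straight draws from the control model
    control_geno = _draw_genotypes(config, config.n_control, rng)
    control_covs = _draw_covariates(config.covariates, config.n_control, rng) \
        if config.covariates is not None else None

    # cases: exponential tilting of the control model
    bound = _lp_bound(config)
    case_geno = np.empty((0, len(config.loci)))
    case_cov_parts: list[pd.DataFrame] = []
    max_candidates = max(200_000, 400 * config.n_case)
    drawn = 0
    batch = max(4 * config.n_case, 1000)
    while len(case_geno) < config.n_case:
        if drawn >= max_candidates:
            raise SimulationError(
                f"acceptance rate too low: {len(case_geno)} cases after {drawn} candidates"
            )
        geno = _draw_genotypes(config, batch, rng)
        covs = _draw_covariates(config.covariates, batch, rng) \
            if config.covariates is not None else None
        lp = _genetic_lp(config, geno)
        if covs is not None and config.covariate_logodds:
            lp = lp + _covariate_lp(covs, config.covariate_logodds)
        accept = rng.random(batch) < np.exp(np.minimum(lp - bound, 0.0))
        drawn += batch
        case_geno = np.vstack([case_geno, geno[accept]])
        if covs is not None:
            case_cov_parts.append(covs.loc[accept])
    case_geno = case_geno[: config.n_case]
    case_covs = None
    if case_cov_parts:
        case_covs = pd.concat(case_cov_parts, ignore_index=True).iloc[: config.n_case]

    cases = _assemble("case", case_geno, case_covs, 0)
    controls = _assemble("control", control_geno, control_covs, config.n_case)
    samples = pd.concat([cases, controls], ignore_index=True)
    genotypes = np.vstack([case_geno, control_geno])
    return Cohort(list(config.loci), samples, genotypes)


def simulate_from_published_tables(
    genotype_freqs: Mapping[str, Mapping[str, Sequence[float]]],
    loci: Sequence[Locus],
    n_case: int = 137,
    n_control: int = 150,
    seed: int = 0,
    covariate_models: Mapping[str, CovariateModel] | None = None,
    sum_slack: float = 0.035,
) -> Cohort:
    """Draw genotypes per group directly from published genotype frequencies.

    ``genotype_freqs[locus_id][group]`` is the (hom non-risk, het, hom risk)
    frequency triple. Triples deviating from sum 1 by more than ``sum_slack``
    raise a ``ConfigError``; smaller deviations (2-decimal rounding of the
    printed table) are renormalised with a warning. No disease model is
    imposed: group differences come entirely from the supplied frequencies.
    """
    rng = np.random.default_rng(seed)
    group_sizes = {"case": n_case, "control": n_control}
    geno_parts = {}
    for group, n in group_sizes.items():
        geno = np.empty((n, len(loci)))
        for j, locus in enumerate(loci):
            try:
                triple = np.asarray(genotype_freqs[locus.locus_id][group], dtype=float)
            except KeyError:
                raise ConfigError(f"no {group} genotype frequencies for {locus.locus_id!r}")
            if triple.shape != (3,) or (triple < 0).any():
                raise ConfigError(f"{locus.locus_id}/{group}: need 3 non-negative frequencies")
            total = triple.sum()
            if abs(total - 1.0) > sum_slack:
                raise ConfigError(
                    f"{locus.locus_id}/{group}: genotype frequencies sum to {total:.3f}"
                )
            if abs(total - 1.0) > 1e-9:
                warnings.warn(
                    f"{locus.locus_id}/{group}: frequencies sum to {total:.2f}; renormalised"
                )
                triple = triple / total
            geno[:, j] = rng.choice(3, size=n, p=triple)
        geno_parts[group] = geno

    frames = []
    start = 0
    for group in ("case", "control"):
        covs = None
        if covariate_models is not None:
            covs = _draw_covariates(covariate_models[group], group_sizes[group], rng)
        frames.append(_assemble(group, geno_parts[group], covs, start))
        start += group_sizes[group]
    samples = pd.concat(frames, ignore_index=True)
    genotypes = np.vstack([geno_parts["case"], geno_parts["control"]])
    return Cohort(list(loci), samples, genotypes)
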