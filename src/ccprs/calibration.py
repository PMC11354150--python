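"""Simulation-based calibration and parameter-recovery checks.

These routines exercise the package's own estimators (the IRLS logistic fit,
the likelihood-ratio test, the Hardy-Weinberg tests) on data simulated at
desk scale, and are what the acceptance checks and several property tests
run. All randomness flows from a single integer seed through spawned
``numpy`` generators.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .association import fit_logistic, _intercept_only_loglik
from .freq_hwe import GenotypeCounts, hwe_chi_square, hwe_exact
from .cohort import Locus
from .simulate import SimConfig, simulate_cohort


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def lrt_type1_error(n_case: int = 137, n_control: int = 150, freq: float = 0.3,
                    n_sim: int = 10_000, alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the per-allele (log-additive) LRT when genotypes are
    independent of status: both groups drawn Binomial(2, freq)."""
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    y = np.concatenate([np.ones(n_case), np.zeros(n_control)])
    null_ll = _intercept_only_loglik(y)
    X = np.ones((n, 2))
    rejections = 0
    genotypes = rng.binomial(2, freq, size=(n_sim, n))
    for s in range(n_sim):
        X[:, 1] = genotypes[s]
        fit = fit_logistic(y, X)
        lr = max(0.0, 2.0 * (fit.loglik - null_ll))
        if stats.chi2.sf(lr, df=1) < alpha:
            rejections += 1
    return rejections / n_sim


def hwe_type1_error(n: int = 150, freq: float = 0.3, n_sim: int = 10_000,
                    alpha: float = 0.05, method: str = "chi_square",
                    seed: int = 0) -> float:
    """Rejection rate of an HWE test on genotypes truly drawn from HWE."""
    rng = np.random.default_rng(seed)
    probs = ((1 - freq) ** 2, 2 * freq * (1 - freq), freq**2)
    draws = rng.multinomial(n, probs, size=n_sim)
    test = hwe_chi_square if method == "chi_square" else hwe_exact
    rejections = 0
    for n_aa, n_ab, n_bb in draws:
        if test(GenotypeCounts(int(n_aa), int(n_ab), int(n_bb))).p_value < alpha:
            rejections += 1
    return rejections / n_sim


def _single_locus_config(freq: float, or_: float, n_case: int, n_control: int,
                         seed: int) -> SimConfig:
    locus = Locus("L1", "A", "B", "B")
    return SimConfig(n_case=n_case, n_control=n_control, loci=[locus],
                     control_freqs={"L1": freq}, allele_or={"L1": or_}, seed=seed)


def recover_per_allele_log_or(freq: float = 0.3, or_: float = 2.0,
                              n_case: int = 25_000, n_control: int = 25_000,
                              seed: int = 0) -> tuple[float, float]:
    """Simulate one large cohort at the given per-allele odds ratio and refit
    the log-additive logistic model. Returns (beta_hat, se)."""
    return _recover_once(freq, or_, n_case, n_control, seed)


def wald_ci_coverage(freq: float = 0.3, or_: float = 2.0, n_case: int = 1000,
                     n_control: int = 1000, n_rep: int = 1000,
                     seed: int = 0) -> float:
    """Fraction of replicates whose 95% Wald CI for the per-allele log odds
    ratio covers the simulation truth."""
    truth = math.log(or_)
    seeds = np.random.SeedSequence(seed).generate_state(n_rep) % (2**31)
    covered = 0
    for s in seeds:
        beta, se = _recover_once(freq, or_, n_case, n_control, int(s))
        if beta - 1.96 * se <= truth <= beta + 1.96 * se:
            covered += 1
    return covered / n_rep


def _recover_once(freq, or_, n_case, n_control, seed) -> tuple[float, float]:
    cohort = simulate_cohort(_single_locus_config(freq, or_, n_case, n_control, seed))
    y = cohort.is_case.astype(float)
    X = np.column_stack([np.ones(cohort.n_individuals), cohort.genotypes[:, 0]])
    fit = fit_logistic(y, X)
    return float(fit.params[1]), float(fit.se()[1])
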