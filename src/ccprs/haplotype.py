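"""EM haplotype frequency estimation from unphased genotypes, pairwise LD
statistics, and haplotype association via expected-dosage logistic regression.

The EM treats each individual's unphased dosage vector as a mixture over the
phase pairs compatible with it. Haplotypes are encoded as bit tuples over the
selected loci: bit 1 is the allele whose dosage the cohort stores (the risk
allele), bit 0 the other allele; labels concatenate the corresponding allele
characters.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort
from .errors import EstimationError, UndefinedStatisticError
from .association import covariate_design, fit_logistic, likelihood_ratio_test


def _hap_label(bits: tuple[int, ...], loci) -> str:
    return "".join(l.risk_allele if b else l.other_allele for b, l in zip(bits, loci))


def _compatible_pairs(n_loci: int):
    """Map dosage pattern -> list of (hap_i, hap_j) unordered index pairs."""
    haps = list(itertools.product((0, 1), repeat=n_loci))
    pairs: dict[tuple[int, ...], list[tuple[int, int]]] = {}
    for i, h1 in enumerate(haps):
        for j in range(i, len(haps)):
            h2 = haps[j]
            pattern = tuple(a + b for a, b in zip(h1, h2))
            pairs.setdefault(pattern, []).append((i, j))
    return haps, pairs


@dataclass
class HaplotypeTable:
    loci: list  # Locus objects, in analysis order
    hap_bits: list[tuple[int, ...]]
    frequencies: np.ndarray  # aligned with hap_bits, sums to 1
    loglik: float
    n_iterations: int
    converged: bool
    n: int  # individuals with complete genotypes used in the fit

    @property
    def labels(self) -> list[str]:
        return [_hap_label(b, self.loci) for b in self.hap_bits]

    @property
    def freqs(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.frequencies)))

    def frequency(self, label: str) -> float:
        return self.freqs[label]


@dataclass
class LdStats:
    d: float
    d_prime: float
    r2: float
    p_value: float


@dataclass
class HaplotypeAssociationRow:
    label: str
    frequency: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    reference: bool = False


@dataclass
class HaplotypeAssociation:
    loci: list
    reference: str
    rows: list[HaplotypeAssociationRow]
    adjusted: bool
    covariates: tuple[str, ...] = ()


def _complete_dosages(cohort: Cohort, loci: list[str]) -> np.ndarray:
    idx = [cohort.locus_index(l) for l in loci]
    sub = cohort.genotypes[:, idx]
    return sub


def em_haplotypes(cohort: Cohort, loci: list[str], tol: float = 1e-8,
                  max_iter: int = 1000, init: str = "uniform",
                  seed: int | None = None) -> HaplotypeTable:
    """Estimate haplotype frequencies over 2-3 loci by EM.

    E-step: each individual's compatible phase pairs receive posterior weight
    proportional to the product of current haplotype frequencies (doubled for
    heterozygous pairs). M-step: frequencies are re-estimated from expected
    haplotype counts. Iteration stops when the largest frequency change is
    below ``tol`` or after ``max_iter`` iterations; the log-likelihood is
    checked to be non-decreasing every iteration. Initialisation is uniform
    by default; ``init="random"`` draws a seeded Dirichlet start.
    """
    if not (2 <= len(loci) <= 3):
        raise EstimationError("haplotype estimation supports 2 or 3 loci")
    sub = _complete_dosages(cohort, loci)
    complete = np.isfinite(sub).all(axis=1)
    sub = sub[complete].astype(int)
    if sub.shape[0] == 0:
        raise EstimationError("no individuals with complete genotypes at the requested loci")

    haps, pair_map = _compatible_pairs(len(loci))
    patterns = Counter(map(tuple, sub))
    n = sub.shape[0]
    k = len(haps)
    if init == "random":
        rng = np.random.default_rng(seed)
        freqs = rng.dirichlet(np.ones(k))
    else:
        freqs = np.full(k, 1.0 / k)

    loglik = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        expected = np.zeros(k)
        new_loglik = 0.0
        for pattern, count in patterns.items():
            pairs = pair_map[pattern]
            weights = np.array(
                [(2.0 if i != j else 1.0) * freqs[i] * freqs[j] for i, j in pairs])
            total = weights.sum()
            if total <= 0:
                # all compatible phases currently have zero mass; restart them
                weights = np.ones(len(pairs))
                total = weights.sum()
            new_loglik += count * math.log(total) if total > 0 else -np.inf
            weights /= total
            for w, (i, j) in zip(weights, pairs):
                expected[i] += count * w
                expected[j] += count * w
        if new_loglik < loglik - 1e-9 * (abs(loglik) + 1.0):
            raise EstimationError("EM log-likelihood decreased; numerical failure")
        new_freqs = expected / (2 * n)
        delta = np.abs(new_freqs - freqs).max()
        freqs = new_freqs
        loglik = new_loglik
        if delta < tol:
            converged = True
            break

    locus_objs = [cohort.locus(l) for l in loci]
    return HaplotypeTable(locus_objs, haps, freqs, loglik, n_iter, converged, n)


def expected_haplotype_dosages(table: HaplotypeTable, cohort: Cohort,
                               loci: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual expected haplotype dosages under the fitted frequencies.

    Returns (dosage matrix over complete individuals aligned with
    ``table.hap_bits``, boolean mask of complete individuals).
    """
    sub = _complete_dosages(cohort, loci)
    complete = np.isfinite(sub).all(axis=1)
    sub_int = sub[complete].astype(int)
    haps, pair_map = _compatible_pairs(len(loci))
    dosages = np.zeros((sub_int.shape[0], len(haps)))
    freqs = table.frequencies
    cache: dict[tuple[int, ...], np.ndarray] = {}
    for row, pattern in enumerate(map(tuple, sub_int)):
        if pattern not in cache:
            pairs = pair_map[pattern]
            weights = np.array(
                [(2.0 if i != j else 1.0) * freqs[i] * freqs[j] for i, j in pairs])
            total = weights.sum()
            weights = weights / total if total > 0 else np.ones(len(pairs)) / len(pairs)
            d = np.zeros(len(haps))
            for w, (i, j) in zip(weights, pairs):
                d[i] += w
                d[j] += w
            cache[pattern] = d
        dosages[row] = cache[pattern]
    return dosages, complete


def ld_stats(table: HaplotypeTable, n: int | None = None) -> LdStats:
    """Pairwise linkage disequilibrium (D, D', r2) from a 2-locus haplotype
    table, with a chi-square test of D = 0 (statistic 2n * r2 on 1 df)."""
    if len(table.loci) != 2:
        raise UndefinedStatisticError("LD statistics are defined for exactly 2 loci")
    n = table.n if n is None else n
    f = {bits: float(freq) for bits, freq in zip(table.hap_bits, table.frequencies)}
    p1 = f[(1, 1)] + f[(1, 0)]
    p2 = f[(1, 1)] + f[(0, 1)]
    q1, q2 = 1.0 - p1, 1.0 - p2
    if min(p1, q1, p2, q2) <= 0:
        raise UndefinedStatisticError("LD undefined at a monomorphic locus")
    d = f[(1, 1)] - p1 * p2
    d_max = min(p1 * q2, q1 * p2) if d > 0 else min(p1 * p2, q1 * q2)
    d_prime = abs(d) / d_max if d != 0 else 0.0
    r2 = d * d / (p1 * q1 * p2 * q2)
    chi2_stat = 2 * n * r2
    return LdStats(d, d_prime, r2, float(stats.chi2.sf(chi2_stat, df=1)))


def haplotype_association(cohort: Cohort, loci: list[str],
                          covariates: tuple[str, ...] = (),
                          freq_floor: float = 0.01,
                          em_kwargs: dict | None = None) -> HaplotypeAssociation:
    """Per-haplotype odds ratios against the most frequent haplotype.

    Haplotype dosages are expected counts under the pooled (cases +
    controls) EM fit; haplotypes below ``freq_floor`` are pooled into a
    "rare" class. A single joint logistic model regresses case status on
    all non-reference haplotype dosages (plus covariates); per-haplotype
    p-values are likelihood-ratio tests of that haplotype's term.
    """
    table = em_haplotypes(cohort, loci, **(em_kwargs or {}))
    dosages, complete = expected_haplotype_dosages(table, cohort, loci)
    labels = table.labels
    freqs = table.frequencies

    present = [i for i, f in enumerate(freqs) if f > 1e-12]
    order = sorted(present, key=lambda i: (-freqs[i], labels[i]))
    ref = order[0]
    if len(order) > 1 and math.isclose(freqs[order[0]], freqs[order[1]], abs_tol=1e-12):
        warnings.warn("reference haplotype tie broken lexicographically")

    kept = [i for i in order[1:] if freqs[i] >= freq_floor]
    rare = [i for i in order[1:] if freqs[i] < freq_floor]

    columns, names, row_freqs = [], [], []
    for i in kept:
        columns.append(dosages[:, i])
        names.append(labels[i])
        row_freqs.append(float(freqs[i]))
    if rare:
        columns.append(dosages[:, rare].sum(axis=1))
        names.append("rare")
        row_freqs.append(float(freqs[rare].sum()))

    y = cohort.is_case.astype(float)[complete]
    samples = cohort.samples.loc[complete].reset_index(drop=True)
    if covariates:
        cov_matrix, cov_names, cov_mask, _ = covariate_design(samples, covariates)
    else:
        cov_matrix, cov_names = np.empty((len(samples), 0)), []
        cov_mask = np.ones(len(samples), dtype=bool)
    H = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    mask = cov_mask
    X = np.hstack([np.ones((mask.sum(), 1)), H[mask], cov_matrix[mask]])
    fit = fit_logistic(y[mask], X, names=("intercept", *names, *cov_names))

    rows = [HaplotypeAssociationRow(labels[ref], float(freqs[ref]),
                                    1.0, 1.0, 1.0, float("nan"), reference=True)]
    n_hap = len(names)
    for k, (name, freq) in enumerate(zip(names, row_freqs)):
        beta = fit.params[1 + k]
        se = fit.se()[1 + k]
        # LRT dropping this haplotype's column
        keep = [0] + [1 + j for j in range(n_hap) if j != k] + \
            [1 + n_hap + j for j in range(len(cov_names))]
        null = fit_logistic(y[mask], X[:, keep])
        p = likelihood_ratio_test(fit, null.loglik, df=1)
        rows.append(HaplotypeAssociationRow(
            name, freq, math.exp(beta),
            math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se), p))
    return HaplotypeAssociation(table.loci, labels[ref], rows,
                                adjusted=bool(cov_names), covariates=tuple(cov_names))
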