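"""Genotype counts, allele frequencies, Hardy-Weinberg tests, and
reconstruction of integer genotype counts from published rounded frequencies.

Counts are always oriented as (n_aa, n_ab, n_bb) where ``b`` is the locus'
risk allele, i.e. the allele whose dosage the cohort matrix stores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .errors import UndefinedStatisticError

GROUPS = ("case", "control", "all")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one locus in one group.

    n_aa: homozygous for the non-risk allele (dosage 0)
    n_ab: heterozygous (dosage 1)
    n_bb: homozygous for the risk allele (dosage 2)
    """

    n_aa: int
    n_ab: int
    n_bb: int
    locus_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_ab, self.n_bb) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_aa, self.n_ab, self.n_bb)

    def swapped(self) -> "GenotypeCounts":
        """Counts after relabelling which allele is 'b'."""
        return GenotypeCounts(self.n_bb, self.n_ab, self.n_aa, self.locus_id, self.group)


@dataclass(frozen=True)
class HweResult:
    method: str  # "chi_square" | "exact"
    p_value: float
    statistic: float | None = None


@dataclass(frozen=True)
class LocusSummary:
    locus_id: str
    group: str
    counts: GenotypeCounts
    freq_a: float
    freq_b: float
    genotype_freqs: tuple[float, float, float]
    hwe: HweResult


def genotype_counts(cohort: Cohort, locus_id: str, group: str = "all") -> GenotypeCounts:
    """Tabulate non-missing dosages at one locus for one group."""
    if group not in GROUPS:
        raise KeyError(f"group must be one of {GROUPS}, got {group!r}")
    g = cohort.dosage(locus_id)
    if group != "all":
        g = g[cohort.samples["status"].to_numpy() == group]
    g = g[np.isfinite(g)]
    return GenotypeCounts(
        int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()),
        locus_id=locus_id, group=group,
    )


def allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of allele b (the risk allele): (n_ab + 2 n_bb) / 2n."""
    if counts.n == 0:
        raise UndefinedStatisticError("allele frequency undefined for n = 0")
    return (counts.n_ab + 2 * counts.n_bb) / (2 * counts.n)


def allele_frequency_from_genotype_freqs(f_aa: float, f_ab: float, f_bb: float) -> float:
    """Allele-b frequency implied by genotype *frequencies*: f_bb + f_ab / 2.

    Useful when only a published rounded frequency table is available; the
    result is on the same scale as the inputs (no renormalisation).
    """
    return f_bb + f_ab / 2.0


def hwe_chi_square(counts: GenotypeCounts) -> HweResult:
    """One-degree-of-freedom goodness-of-fit chi-square test for HWE.

    Expected genotype counts come from the estimated allele frequency; a
    monomorphic locus returns the degenerate result (statistic 0, p = 1).
    """
    if counts.n == 0:
        raise UndefinedStatisticError("HWE test undefined for n = 0")
    p = allele_frequency(counts)
    if p in (0.0, 1.0):
        return HweResult("chi_square", 1.0, 0.0)
    n = counts.n
    expected = np.array([(1 - p) ** 2 * n, 2 * p * (1 - p) * n, p**2 * n])
    observed = np.array(counts.as_tuple, dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return HweResult("chi_square", float(stats.chi2.sf(statistic, df=1)), statistic)


def hwe_exact(counts: GenotypeCounts) -> HweResult:
    """Exact conditional HWE test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity) whose conditional probability does
    not exceed the observed one.
    """
    if counts.n == 0:
        raise UndefinedStatisticError("HWE test undefined for n = 0")
    n = counts.n
    n_b = counts.n_ab + 2 * counts.n_bb
    rare = min(n_b, 2 * n - n_b)
    if rare == 0:
        return HweResult("exact", 1.0)

    # log-probability of each feasible heterozygote count, up to a constant
    hets = range(rare % 2, rare + 1, 2)
    log_probs = []
    for n_ab in hets:
        n_rr = (rare - n_ab) // 2
        n_cc = n - n_ab - n_rr
        if n_cc < 0:
            log_probs.append(-np.inf)
            continue
        log_probs.append(
            n_ab * math.log(2)
            - math.lgamma(n_rr + 1) - math.lgamma(n_ab + 1) - math.lgamma(n_cc + 1)
        )
    log_probs = np.array(log_probs)
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    observed = dict(zip(hets, probs))[counts.n_ab]
    p = float(probs[probs <= observed * (1 + 1e-12)].sum())
    return HweResult("exact", min(p, 1.0))


def locus_summary(cohort: Cohort, locus_id: str, group: str = "all",
                  hwe_method: str = "exact") -> LocusSummary:
    counts = genotype_counts(cohort, locus_id, group)
    freq_b = allele_frequency(counts)
    test = hwe_exact(counts) if hwe_method == "exact" else hwe_chi_square(counts)
    return LocusSummary(
        locus_id=locus_id,
        group=group,
        counts=counts,
        freq_a=1.0 - freq_b,
        freq_b=freq_b,
        genotype_freqs=tuple(c / counts.n for c in counts.as_tuple),
        hwe=test,
    )


def summary_table(cohort: Cohort, hwe_method: str = "exact") -> pd.DataFrame:
    """Per-locus, per-group frequency/HWE summary shaped like a published
    allele-frequency table (one row per locus x group)."""
    rows = []
    for locus in cohort.loci:
        for group in ("case", "control"):
            s = locus_summary(cohort, locus.locus_id, group, hwe_method)
            rows.append(
                {
                    "locus": locus.locus_id,
                    "group": group,
                    "n": s.counts.n,
                    "non_risk_allele": locus.other_allele,
                    "freq_non_risk": round(s.freq_a, 4),
                    "risk_allele": locus.risk_allele,
                    "freq_risk": round(s.freq_b, 4),
                    "geno_freq_0": round(s.genotype_freqs[0], 4),
                    "geno_freq_1": round(s.genotype_freqs[1], 4),
                    "geno_freq_2": round(s.genotype_freqs[2], 4),
                    "hwe_p": round(s.hwe.p_value, 4),
                }
            )
    return pd.DataFrame(rows)


def _rounds_to(count: int, n: int, target: float, decimals: int) -> bool:
    # integer half-away-from-zero check: round(count / n, decimals) == target
    scale = 10**decimals
    rounded = (2 * count * scale + n) // (2 * n)  # floor((count/n)*scale + 0.5)
    return rounded == round(target * scale)


def reconstruct_counts(genotype_freqs: Sequence[float], n: int,
                       decimals: int = 2) -> list[GenotypeCounts]:
    """All integer genotype-count triples summing to ``n`` whose frequencies
    round (half away from zero) to the printed values.

    Returns candidates ordered by L2 distance to ``n * genotype_freqs``
    (ties broken lexicographically); the list is empty when the printed
    frequencies are mutually inconsistent at this sample size.
    """
    f_aa, f_ab, f_bb = genotype_freqs
    if not all(0.0 <= f <= 1.0 for f in (f_aa, f_ab, f_bb)):
        raise ValueError("genotype frequencies must lie in [0, 1]")
    if n <= 0:
        raise ValueError("group size must be positive")

    def candidate_range(freq: float) -> range:
        lo = max(0, math.floor((freq - 0.5 / 10**decimals) * n) - 1)
        hi = min(n, math.ceil((freq + 0.5 / 10**decimals) * n) + 1)
        return range(lo, hi + 1)

    target = np.array([f_aa * n, f_ab * n, f_bb * n])
    found = []
    for n_aa in candidate_range(f_aa):
        if not _rounds_to(n_aa, n, f_aa, decimals):
            continue
        for n_ab in candidate_range(f_ab):
            n_bb = n - n_aa - n_ab
            if n_bb < 0 or not _rounds_to(n_ab, n, f_ab, decimals):
                continue
            if not _rounds_to(n_bb, n, f_bb, decimals):
                continue
            triple = (n_aa, n_ab, n_bb)
            distance = float(((np.array(triple) - target) ** 2).sum())
            found.append((distance, triple))
    found.sort(key=lambda item: (item[0], item[1]))
    return [GenotypeCounts(*triple) for _, triple in found]
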