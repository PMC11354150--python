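"""Unweighted and weighted polygenic risk scores and their case/control
comparison.

The score for individual i is S_i = sum_l w_l * g_il, where g_il is the
risk-allele dosage (0/1/2) and w_l a per-locus weight: 1 for the unweighted
score, or a per-allele odds ratio (crude or covariate-adjusted) for the
weighted score. Weights are raw odds ratios, not log-odds: the weighted
score is the dosage-weighted sum the source study design calls for, and its
between-group mean difference obeys the closed-form identity
2 * sum_l w_l * (p_case,l - p_control,l), which the unweighted variant
reproduces exactly from published allele frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort
from .errors import ConfigError, UndefinedStatisticError

WEIGHT_SOURCES = ("unit", "crude_allelic_or", "adjusted_allelic_or", "external")


@dataclass(frozen=True)
class WeightScheme:
    source: str
    weights: Mapping[str, float]  # locus_id -> w_l > 0

    def __post_init__(self) -> None:
        if self.source not in WEIGHT_SOURCES:
            raise ConfigError(f"unknown weight source {self.source!r}")
        for locus_id, w in self.weights.items():
            if not w > 0:
                raise ConfigError(f"weight for {locus_id} must be positive, got {w}")
        if self.source == "unit" and any(w != 1.0 for w in self.weights.values()):
            raise ConfigError("unit scheme requires all weights equal to 1")

    @classmethod
    def unit(cls, locus_ids: Sequence[str]) -> "WeightScheme":
        return cls("unit", {l: 1.0 for l in locus_ids})


@dataclass
class PrsResult:
    scores: np.ndarray  # aligned with the included individuals
    sample_ids: list[str]
    status: np.ndarray  # bool, True = case, aligned with scores
    scheme: WeightScheme
    n_loci: int
    excluded: list[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    mean_case: float
    mean_control: float
    mean_difference: float
    pooled_sd: float
    t_statistic: float
    df: int
    p_value: float


def compute_prs(cohort: Cohort, scheme: WeightScheme) -> PrsResult:
    """Per-individual polygenic score over the scheme's loci.

    Individuals missing a genotype at any scored locus are excluded from the
    score and listed in ``result.excluded``.
    """
    missing = [l for l in scheme.weights if l not in cohort.locus_ids]
    if missing:
        raise ConfigError(f"scheme references loci absent from the cohort: {missing}")
    locus_ids = list(scheme.weights)
    idx = [cohort.locus_index(l) for l in locus_ids]
    G = cohort.genotypes[:, idx]
    w = np.array([scheme.weights[l] for l in locus_ids])
    complete = np.isfinite(G).all(axis=1)
    scores = G[complete] @ w
    ids = cohort.samples["sample_id"].tolist()
    return PrsResult(
        scores=scores,
        sample_ids=[s for s, ok in zip(ids, complete) if ok],
        status=cohort.is_case[complete],
        scheme=scheme,
        n_loci=len(locus_ids),
        excluded=[s for s, ok in zip(ids, complete) if not ok],
    )


def compare_groups(prs: PrsResult) -> GroupComparison:
    """Independent two-sample pooled-variance t-test of case vs control scores."""
    cases = prs.scores[prs.status]
    controls = prs.scores[~prs.status]
    n1, n2 = len(cases), len(controls)
    if n1 < 2 or n2 < 2:
        raise UndefinedStatisticError("both groups need at least 2 scored members")
    df = n1 + n2 - 2
    diff = float(cases.mean() - controls.mean())
    pooled_var = ((n1 - 1) * cases.var(ddof=1) + (n2 - 1) * controls.var(ddof=1)) / df
    if pooled_var <= 0:
        raise UndefinedStatisticError("pooled variance is zero; t undefined")
    pooled_sd = math.sqrt(pooled_var)
    t = diff / (pooled_sd * math.sqrt(1 / n1 + 1 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return GroupComparison(float(cases.mean()), float(controls.mean()),
                           diff, pooled_sd, t, df, p)


def prs_mean_diff_identity(case_freqs: Mapping[str, float],
                           control_freqs: Mapping[str, float],
                           scheme: WeightScheme) -> float:
    """Closed-form expected PRS mean difference from risk-allele frequencies.

    E[S | group] = 2 * sum_l w_l * p_{group,l} under dosage ~ Binomial(2, p),
    so the case-minus-control difference is 2 * sum_l w_l * (p_case - p_ctrl).
    """
    loci = set(scheme.weights)
    if set(case_freqs) < loci or set(control_freqs) < loci:
        raise ConfigError("frequencies must cover every scored locus")
    return 2.0 * sum(
        scheme.weights[l] * (case_freqs[l] - control_freqs[l]) for l in scheme.weights
    )


@dataclass
class DistributionReport:
    bin_edges: np.ndarray
    case_counts: np.ndarray
    control_counts: np.ndarray
    path: str | None


def prs_distribution_report(prs: PrsResult, out_path=None,
                            n_bins: int = 23) -> DistributionReport:
    """Per-group score histograms on a common grid, optionally rendered to a
    figure. Empty bins are kept as zero counts."""
    lo = float(prs.scores.min()) if len(prs.scores) else 0.0
    hi = float(prs.scores.max()) if len(prs.scores) else 1.0
    if lo == hi:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    case_counts, _ = np.histogram(prs.scores[prs.status], bins=edges)
    control_counts, _ = np.histogram(prs.scores[~prs.status], bins=edges)
    path = None
    if out_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        centers = (edges[:-1] + edges[1:]) / 2
        width = (edges[1] - edges[0]) * 0.45
        ax.bar(centers - width / 2, control_counts, width=width,
               label="controls", color="#4878d0")
        ax.bar(centers + width / 2, case_counts, width=width,
               label="cases", color="#d65f5f")
        if prs.status.any():
            ax.axvline(prs.scores[prs.status].mean(), color="#d65f5f", ls="--")
        if (~prs.status).any():
            ax.axvline(prs.scores[~prs.status].mean(), color="#4878d0", ls="--")
        ax.set_xlabel(f"polygenic risk score ({prs.scheme.source})")
        ax.set_ylabel("individuals")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        path = str(out_path)
    return DistributionReport(edges, case_counts, control_counts, path)
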