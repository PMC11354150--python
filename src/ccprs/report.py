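"""End-to-end pipeline runner, configuration, and table rendering.

Display conventions follow the source study's tables: odds ratios and
confidence limits rounded half-away-from-zero to 2 decimals and rendered
"X.XX (L–U)", p-values to 4 decimals, reference levels as
"1 (reference)", with a dagger marking significance after Bonferroni
correction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .association import (DEFAULT_COVARIATES, MODELS, association_scan, bonferroni,
                          covariate_table, scan_frame)
from .cohort import Cohort, Locus, read_cohort_table, validate_cohort
from .errors import ConfigError, PipelineError
from .freq_hwe import summary_table
from .haplotype import em_haplotypes, haplotype_association, ld_stats
from .prs import WeightScheme, compare_groups, compute_prs, prs_distribution_report

logger = logging.getLogger("ccprs")


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (the convention of the study's tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_or_ci(or_: float, lo: float, hi: float, reference: bool = False) -> str:
    if reference:
        return "1 (reference)"
    return (f"{round_half_away(or_, 2):.2f} "
            f"({round_half_away(lo, 2):.2f}–{round_half_away(hi, 2):.2f})")


def format_p(p: float, bonferroni_significant: bool = False) -> str:
    if p != p:  # nan (reference rows)
        return ""
    text = f"{round_half_away(p, 4):.4f}"
    return f"{text} †" if bonferroni_significant else text


@dataclass
class AnalysisConfig:
    loci: list[Locus]
    models: tuple[str, ...] = MODELS
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.05
    n_tests: int | None = None
    weight_source: str = "adjusted_allelic_or"
    haplotype_blocks: list[list[str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = {l.locus_id for l in self.loci}
        for block in self.haplotype_blocks:
            unknown = [l for l in block if l not in ids]
            if unknown:
                raise ConfigError(f"haplotype block references undefined loci: {unknown}")
        if self.n_tests is not None and self.n_tests < 1:
            raise ConfigError("n_tests must be >= 1")

    @property
    def m(self) -> int:
        return self.n_tests if self.n_tests is not None else len(self.loci)

    def to_dict(self) -> dict:
        return {
            "loci": [
                {"locus_id": l.locus_id, "allele_a": l.allele_a, "allele_b": l.allele_b,
                 "risk_allele": l.risk_allele, "rsid": l.rsid}
                for l in self.loci
            ],
            "models": list(self.models),
            "covariates": list(self.covariates),
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "weight_source": self.weight_source,
            "haplotype_blocks": self.haplotype_blocks,
            "seed": self.seed,
        }


def load_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML file mirroring ``to_dict``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    loci = [Locus(**entry) for entry in raw["loci"]]
    return AnalysisConfig(
        loci=loci,
        models=tuple(raw.get("models", MODELS)),
        covariates=tuple(raw.get("covariates", DEFAULT_COVARIATES)),
        alpha=raw.get("alpha", 0.05),
        n_tests=raw.get("n_tests"),
        weight_source=raw.get("weight_source", "adjusted_allelic_or"),
        haplotype_blocks=[list(b) for b in raw.get("haplotype_blocks", [])],
        seed=raw.get("seed", 0),
    )


def render_association(results) -> pd.DataFrame:
    """Human-readable association table in the published layout."""
    crude = {(r.locus_id, r.model): r for r in results if not r.adjusted}
    adjusted = {(r.locus_id, r.model): r for r in results if r.adjusted}
    rows = []
    for key, r in crude.items():
        adj = adjusted.get(key)
        for i, est in enumerate(r.estimates):
            adj_est = adj.estimates[i] if adj and i < len(adj.estimates) else None
            rows.append(
                {
                    "locus": r.locus_id,
                    "model": r.model,
                    "level": est.label,
                    "crude_or": format_or_ci(est.odds_ratio, est.ci_low,
                                             est.ci_high, est.reference),
                    "crude_p": "" if est.reference else
                               format_p(r.p_value, bool(r.significant_bonferroni)),
                    "adjusted_or": "" if adj_est is None else
                                   format_or_ci(adj_est.odds_ratio, adj_est.ci_low,
                                                adj_est.ci_high, adj_est.reference),
                    "adjusted_p": "" if (adj is None or adj_est is None or adj_est.reference)
                                  else format_p(adj.p_value, bool(adj.significant_bonferroni)),
                }
            )
    return pd.DataFrame(rows)


def _weights_from_scan(results, source: str, loci: Sequence[Locus]) -> WeightScheme:
    adjusted = source == "adjusted_allelic_or"
    table = {
        r.locus_id: r.estimates[-1].odds_ratio
        for r in results
        if r.model == "log_additive" and r.adjusted == adjusted
    }
    missing = [l.locus_id for l in loci if l.locus_id not in table]
    if missing:
        raise ConfigError(f"no {source} estimate for loci: {missing}")
    return WeightScheme(source, table)


def run_pipeline(config: AnalysisConfig, cohort_path, out_dir) -> dict[str, str]:
    """Run the full analysis and write the report bundle.

    Outputs (all TSV unless noted): covariates, frequency_hwe, association,
    haplotypes, prs (per-individual), prs_comparison, prs_distribution.png,
    and manifest.json. Deterministic given the config: re-running writes
    byte-identical tables. Any stage failure raises ``PipelineError`` naming
    the stage; files already written are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    def run_stage(name, fn):
        t0 = stage(name)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result

    cohort: Cohort = run_stage("read", lambda: read_cohort_table(cohort_path, config.loci))
    report = run_stage("validate", lambda: validate_cohort(cohort))
    if report.errors:
        raise PipelineError(f"stage 'validate' failed: {report.errors}")

    def write(name, frame: pd.DataFrame):
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = str(path)

    write("covariates", run_stage("covariates", lambda: covariate_table(cohort)))
    write("frequency_hwe", run_stage("frequency_hwe", lambda: summary_table(cohort)))

    results = run_stage("association", lambda: association_scan(
        cohort, config.models, config.covariates, config.alpha, config.m))
    write("association", render_association(results))

    def haplotypes():
        rows = []
        for block in config.haplotype_blocks:
            assoc = haplotype_association(cohort, list(block))
            table = em_haplotypes(cohort, list(block))
            for row in assoc.rows:
                rows.append(
                    {
                        "block": "-".join(block),
                        "haplotype": row.label,
                        "frequency": round(row.frequency, 4),
                        "or": format_or_ci(row.odds_ratio, row.ci_low, row.ci_high,
                                           row.reference),
                        "p": format_p(row.p_value),
                    }
                )
            if len(block) == 2:
                ld = ld_stats(table)
                rows.append({"block": "-".join(block), "haplotype": "(LD)",
                             "frequency": "",
                             "or": f"D'={round_half_away(ld.d_prime, 3):.3f}, "
                                   f"r2={round_half_away(ld.r2, 3):.3f}",
                             "p": format_p(ld.p_value)})
            else:
                for a in range(len(block)):
                    for b in range(a + 1, len(block)):
                        pair = [block[a], block[b]]
                        ld = ld_stats(em_haplotypes(cohort, pair))
                        rows.append({"block": "-".join(pair), "haplotype": "(LD)",
                                     "frequency": "",
                                     "or": f"D'={round_half_away(ld.d_prime, 3):.3f}, "
                                           f"r2={round_half_away(ld.r2, 3):.3f}",
                                     "p": format_p(ld.p_value)})
        return pd.DataFrame(rows, columns=["block", "haplotype", "frequency", "or", "p"])

    write("haplotypes", run_stage("haplotypes", haplotypes))

    def prs_outputs():
        if config.weight_source == "unit":
            scheme = WeightScheme.unit([l.locus_id for l in config.loci])
        else:
            scheme = _weights_from_scan(results, config.weight_source, config.loci)
        unit = compute_prs(cohort, WeightScheme.unit([l.locus_id for l in config.loci]))
        weighted = compute_prs(cohort, scheme)
        per_individual = pd.DataFrame(
            {
                "sample_id": weighted.sample_ids,
                "status": ["case" if c else "control" for c in weighted.status],
                "prs_unweighted": unit.scores,
                "prs_weighted": weighted.scores,
            }
        )
        rows = []
        for label, result in (("unweighted", unit), (config.weight_source, weighted)):
            cmp_ = compare_groups(result)
            rows.append(
                {
                    "scheme": label,
                    "mean_case": round(cmp_.mean_case, 4),
                    "mean_control": round(cmp_.mean_control, 4),
                    "mean_difference": round(cmp_.mean_difference, 4),
                    "pooled_sd": round(cmp_.pooled_sd, 4),
                    "t": round(cmp_.t_statistic, 4),
                    "df": cmp_.df,
                    "p": format_p(cmp_.p_value),
                }
            )
        return per_individual, pd.DataFrame(rows), weighted

    per_individual, comparison, weighted = run_stage("prs", prs_outputs)
    write("prs", per_individual)
    write("prs_comparison", comparison)
    figure = out / "prs_distribution.png"
    run_stage("prs_figure", lambda: prs_distribution_report(weighted, figure))
    paths["prs_distribution"] = str(figure)

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "n_individuals": cohort.n_individuals,
        "n_cases": report.n_cases,
        "n_controls": report.n_controls,
        "outputs": sorted(paths),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = str(manifest_path)
    return paths
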