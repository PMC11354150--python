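"""Published summary statistics of the East Midlands (UK) rheumatoid
arthritis case-control study that this package reanalyses: 137 RA patients
and 150 controls typed at 11 biallelic candidate loci.

Individual-level data for that study are not publicly deposited, so these
printed group-level summaries (allele and genotype frequencies, per-allele
odds ratios, participant characteristics) are the inputs from which synthetic
cohorts are generated and against which closed-form identities are checked.

Conventions: for every locus ``allele_b`` is the risk allele, so genotype
frequency triples are ordered (hom non-risk, het, hom risk). Risk alleles for
TNFR2, TRAF1, PTPN22, HLA-DRB1, TNF-308 and IL4-590 are the study's named
susceptibility alleles; for the remaining five loci (not significant in the
study) the default follows the direction implied by the per-allele odds
ratios: ACE D, VDR Bsm1 T, VDR Fok1 C, VDR Taq1 G (minor allele), STAT4 T.
STAT4's direction is internally inconsistent in the source (T is *rarer* in
patients yet its printed odds ratio exceeds 1); the printed frequencies are
kept as-is.
"""

from __future__ import annotations

from .cohort import Locus
from .simulate import CovariateModel

N_CASES = 137
N_CONTROLS = 150
N_LOCI = 11

LOCI: tuple[Locus, ...] = (
    Locus("ACE", "I", "D", "D", rsid="rs4646994"),
    Locus("VDR_Bsm1", "A", "T", "T", rsid="rs1544410"),
    Locus("VDR_Fok1", "T", "C", "C", rsid="rs10735810"),
    Locus("VDR_Taq1", "A", "G", "G", rsid="rs731236"),
    Locus("TNFR2", "T", "G", "G", rsid="rs1061622"),
    Locus("IL4_590", "C", "T", "T", rsid="rs2243250"),
    Locus("STAT4", "G", "T", "T", rsid="rs7574865"),
    Locus("TRAF1", "G", "A", "A", rsid="rs10818488"),
    Locus("PTPN22", "C", "T", "T", rsid="rs2476601"),
    Locus("HLA_DRB1", "A", "G", "G", rsid="rs660895"),
    Locus("TNF_308", "G", "A", "A", rsid="rs1800629"),
)

LOCUS_IDS = tuple(l.locus_id for l in LOCI)

#: printed risk-allele frequencies per group
RISK_ALLELE_FREQS: dict[str, dict[str, float]] = {
    "ACE":      {"case": 0.56, "control": 0.55},
    "VDR_Bsm1": {"case": 0.50, "control": 0.46},
    "VDR_Fok1": {"case": 0.42, "control": 0.39},
    "VDR_Taq1": {"case": 0.36, "control": 0.34},
    "TNFR2":    {"case": 0.41, "control": 0.28},
    "IL4_590":  {"case": 0.22, "control": 0.14},
    "STAT4":    {"case": 0.24, "control": 0.27},
    "TRAF1":    {"case": 0.54, "control": 0.38},
    "PTPN22":   {"case": 0.23, "control": 0.12},
    "HLA_DRB1": {"case": 0.36, "control": 0.25},
    "TNF_308":  {"case": 0.30, "control": 0.22},
}

#: printed genotype frequencies (hom non-risk, het, hom risk) per group.
#: Some rows do not sum to exactly 1 at the printed 2-decimal precision
#: (VDR Fok1 controls sum to 0.97); they are renormalised downstream.
GENOTYPE_FREQS: dict[str, dict[str, tuple[float, float, float]]] = {
    "ACE":      {"case": (0.28, 0.32, 0.40), "control": (0.19, 0.51, 0.30)},
    "VDR_Bsm1": {"case": (0.28, 0.43, 0.28), "control": (0.33, 0.41, 0.26)},
    "VDR_Fok1": {"case": (0.33, 0.48, 0.18), "control": (0.37, 0.43, 0.17)},
    "VDR_Taq1": {"case": (0.40, 0.48, 0.12), "control": (0.47, 0.38, 0.14)},
    "TNFR2":    {"case": (0.33, 0.53, 0.14), "control": (0.49, 0.46, 0.05)},
    "IL4_590":  {"case": (0.63, 0.31, 0.07), "control": (0.74, 0.25, 0.01)},
    "STAT4":    {"case": (0.52, 0.47, 0.01), "control": (0.49, 0.48, 0.03)},
    "TRAF1":    {"case": (0.21, 0.50, 0.29), "control": (0.35, 0.54, 0.11)},
    "PTPN22":   {"case": (0.59, 0.35, 0.06), "control": (0.77, 0.22, 0.01)},
    "HLA_DRB1": {"case": (0.40, 0.47, 0.13), "control": (0.55, 0.40, 0.05)},
    "TNF_308":  {"case": (0.52, 0.37, 0.11), "control": (0.60, 0.37, 0.03)},
}

#: printed per-allele (log-additive/allelic) odds ratios
CRUDE_ALLELIC_OR: dict[str, float] = {
    "ACE": 1.02, "VDR_Bsm1": 1.14, "VDR_Fok1": 1.15, "VDR_Taq1": 1.11,
    "TNFR2": 1.87, "IL4_590": 1.77, "STAT4": 1.47, "TRAF1": 1.99,
    "PTPN22": 2.15, "HLA_DRB1": 1.73, "TNF_308": 1.49,
}

ADJUSTED_ALLELIC_OR: dict[str, float] = {
    "ACE": 1.10, "VDR_Bsm1": 1.03, "VDR_Fok1": 1.02, "VDR_Taq1": 1.04,
    "TNFR2": 2.28, "IL4_590": 1.83, "STAT4": 1.68, "TRAF1": 1.78,
    "PTPN22": 2.63, "HLA_DRB1": 1.92, "TNF_308": 1.00,
}

#: participant characteristics per group. Mean ages are printed; age SDs are
#: not, so a plausible 12-year SD is assumed for simulation. Categorical
#: probabilities renormalise the printed counts (a few columns have partial
#: missingness in the source).
COVARIATE_MODELS: dict[str, CovariateModel] = {
    "case": CovariateModel(
        age_mean=49.0, age_sd=12.0, p_male=37 / 137,
        diet_probs=(5 / 117, 90 / 117, 22 / 117),
        alcohol_probs=(79 / 137, 33 / 137, 11 / 137, 14 / 137),
    ),
    "control": CovariateModel(
        age_mean=58.9, age_sd=12.0, p_male=64 / 148,
        diet_probs=(15 / 126, 96 / 126, 15 / 126),
        alcohol_probs=(61 / 149, 47 / 149, 14 / 149, 27 / 149),
    ),
}

#: number of comparisons used for the study's Bonferroni correction
BONFERRONI_M = 11


def weight_scheme(source: str = "adjusted_allelic_or"):
    """A WeightScheme over the study panel: unit, crude or adjusted ORs."""
    from .prs import WeightScheme

    if source == "unit":
        return WeightScheme.unit(LOCUS_IDS)
    if source == "crude_allelic_or":
        return WeightScheme(source, dict(CRUDE_ALLELIC_OR))
    if source == "adjusted_allelic_or":
        return WeightScheme(source, dict(ADJUSTED_ALLELIC_OR))
    raise ValueError(f"unknown weight source {source!r}")


def case_control_freqs() -> tuple[dict[str, float], dict[str, float]]:
    cases = {l: RISK_ALLELE_FREQS[l]["case"] for l in LOCUS_IDS}
    controls = {l: RISK_ALLELE_FREQS[l]["control"] for l in LOCUS_IDS}
    return cases, controls
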