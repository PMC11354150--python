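"""Domain types and readers/writers for individual-level case-control genotype data.

Genotypes are stored throughout as *risk-allele dosage*: the number of copies
(0, 1, 2) of the locus' designated risk allele carried by an individual, with
``nan`` marking a missing genotype. Every downstream statistic (inheritance
models, haplotype EM over dosage patterns, polygenic scores) consumes this
coding directly.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

STATUS_LEVELS = ("case", "control")
SEX_LEVELS = ("male", "female")
DIET_LEVELS = ("vegetarian", "mixed", "mostly_meat")
ALCOHOL_LEVELS = ("0", "1-6", "7-13", "14+")  # ordinal bands, scored 0-3
SMOKING_LEVELS = ("never", "ever")
COVARIATE_COLUMNS = ("age", "sex", "diet", "alcohol", "smoking")

#: default mapping of raw status codes to case/control (0/1 coding, 1 = case)
DEFAULT_STATUS_MAP = {
    "case": "case",
    "control": "control",
    "1": "case",
    "0": "control",
}

#: PLINK-style 1/2 phenotype coding
PLINK_STATUS_MAP = {"1": "control", "2": "case"}

_MISSING_TOKENS = {"", "na", "nan", ".", "none"}


@dataclass(frozen=True)
class Locus:
    """A biallelic locus with a designated risk allele.

    ``allele_a`` / ``allele_b`` are single-character labels; "I"/"D" are
    accepted for insertion/deletion polymorphisms.
    """

    locus_id: str
    allele_a: str
    allele_b: str
    risk_allele: str
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise DataError(f"{self.locus_id}: alleles must differ")
        if self.risk_allele not in (self.allele_a, self.allele_b):
            raise DataError(
                f"{self.locus_id}: risk allele {self.risk_allele!r} is not one of "
                f"({self.allele_a!r}, {self.allele_b!r})"
            )

    @property
    def other_allele(self) -> str:
        return self.allele_b if self.risk_allele == self.allele_a else self.allele_a

    def with_risk_allele(self, allele: str) -> "Locus":
        return replace(self, risk_allele=allele)


@dataclass
class Individual:
    sample_id: str
    status: str
    age: float | None = None
    sex: str | None = None
    diet: str | None = None
    alcohol: str | None = None
    smoking: str | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUS_LEVELS:
            raise DataError(f"{self.sample_id}: status must be case/control, got {self.status!r}")
        for attr, levels in (("sex", SEX_LEVELS), ("diet", DIET_LEVELS),
                             ("alcohol", ALCOHOL_LEVELS), ("smoking", SMOKING_LEVELS)):
            value = getattr(self, attr)
            if value is not None and value not in levels:
                raise DataError(f"{self.sample_id}: {attr}={value!r} not in {levels}")


@dataclass
class Cohort:
    """Individuals x loci dosage matrix plus phenotype and covariates.

    ``samples`` holds one row per individual (columns ``sample_id``,
    ``status`` and the covariate columns); ``genotypes`` is a float array of
    shape (n_individuals, n_loci) with entries in {0, 1, 2, nan}.
    """

    loci: list[Locus]
    samples: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.size == 0:
            self.genotypes = self.genotypes.reshape(len(self.samples), len(self.loci)) \
                if len(self.samples) == 0 else self.genotypes
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise DataError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} individuals x {len(self.loci)} loci"
            )
        finite = self.genotypes[np.isfinite(self.genotypes)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise DataError("genotype dosages must be 0, 1, 2 or missing")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"unknown locus {locus_id!r}") from None

    def locus(self, locus_id: str) -> Locus:
        return self.loci[self.locus_index(locus_id)]

    @property
    def is_case(self) -> np.ndarray:
        return (self.samples["status"] == "case").to_numpy()

    def dosage(self, locus_id: str) -> np.ndarray:
        return self.genotypes[:, self.locus_index(locus_id)]

    @classmethod
    def from_individuals(cls, loci: Sequence[Locus], individuals: Sequence[Individual],
                         genotypes: np.ndarray) -> "Cohort":
        samples = pd.DataFrame(
            {
                "sample_id": [i.sample_id for i in individuals],
                "status": [i.status for i in individuals],
                "age": [i.age for i in individuals],
                "sex": [i.sex for i in individuals],
                "diet": [i.diet for i in individuals],
                "alcohol": [i.alcohol for i in individuals],
                "smoking": [i.smoking for i in individuals],
            }
        )
        return cls(list(loci), samples, genotypes)

    def recode_risk_allele(self, locus_id: str, risk_allele: str) -> "Cohort":
        """Return a cohort with the risk allele at ``locus_id`` swapped.

        Non-missing dosages map g -> 2 - g when the risk allele actually
        changes (an involution).
        """
        idx = self.locus_index(locus_id)
        locus = self.loci[idx]
        if risk_allele == locus.risk_allele:
            return self
        new_loci = list(self.loci)
        new_loci[idx] = locus.with_risk_allele(risk_allele)
        geno = self.genotypes.copy()
        geno[:, idx] = 2.0 - geno[:, idx]
        return Cohort(new_loci, self.samples.copy(), geno)


@dataclass
class ValidationReport:
    n_cases: int
    n_controls: int
    missingness: dict[str, float] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# -- parsing helpers ----------------------------------------------------------


def _parse_status(raw, status_map: Mapping[str, str], sample_id: str) -> str:
    token = str(raw).strip().lower()
    if token in status_map:
        return status_map[token]
    raise DataError(f"{sample_id}: unrecognised status value {raw!r}")


def _parse_genotype(raw, locus: Locus, sample_id: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    token = str(raw).strip()
    if token.lower() in _MISSING_TOKENS:
        return np.nan
    if "/" in token:
        parts = token.split("/")
        if len(parts) != 2:
            raise DataError(f"{sample_id} @ {locus.locus_id}: malformed genotype {raw!r}")
        valid = {locus.allele_a, locus.allele_b}
        for allele in parts:
            if allele not in valid:
                raise DataError(
                    f"{sample_id} @ {locus.locus_id}: allele {allele!r} not in "
                    f"locus definition {sorted(valid)}"
                )
        return float(sum(a == locus.risk_allele for a in parts))
    try:
        value = float(token)
    except ValueError:
        raise DataError(f"{sample_id} @ {locus.locus_id}: cannot parse genotype {raw!r}") from None
    if value not in (0.0, 1.0, 2.0):
        raise DataError(f"{sample_id} @ {locus.locus_id}: dosage {raw!r} outside 0/1/2")
    return value


def _parse_covariate(raw, column: str, sample_id: str):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None if column != "age" else np.nan
    token = str(raw).strip()
    if token.lower() in _MISSING_TOKENS:
        return None if column != "age" else np.nan
    if column == "age":
        try:
            return float(token)
        except ValueError:
            raise DataError(f"{sample_id}: non-numeric age {raw!r}") from None
    levels = {"sex": SEX_LEVELS, "diet": DIET_LEVELS,
              "alcohol": ALCOHOL_LEVELS, "smoking": SMOKING_LEVELS}[column]
    if token not in levels:
        raise DataError(f"{sample_id}: {column}={raw!r} not in {levels}")
    return token


# -- readers / writers ---------------------------------------------------------


def read_cohort_table(path, loci: Sequence[Locus],
                      status_map: Mapping[str, str] | None = None) -> Cohort:
    """Read a tidy delimited table (comma or tab, auto-detected) into a Cohort.

    Required columns: ``sample_id``, ``status``, one column per locus id.
    Genotype cells hold either a dosage 0/1/2 or an allele pair ``"X/Y"``;
    missing values are ``NA`` or empty. Covariate columns
    (age/sex/diet/alcohol/smoking) are optional.
    """
    status_map = dict(DEFAULT_STATUS_MAP if status_map is None else status_map)
    table = pd.read_csv(path, sep=None, engine="python", dtype=object,
                        keep_default_na=False)
    for column in ("sample_id", "status"):
        if column not in table.columns:
            raise FormatError(f"missing mandatory column {column!r}")
    for locus in loci:
        if locus.locus_id not in table.columns:
            raise FormatError(f"missing genotype column {locus.locus_id!r}")

    rows = []
    geno = np.empty((len(table), len(loci)))
    for i, row in enumerate(table.itertuples(index=False)):
        record = dict(zip(table.columns, row))
        sample_id = str(record["sample_id"])
        covs = {c: _parse_covariate(record.get(c), c, sample_id)
                for c in COVARIATE_COLUMNS if c in table.columns}
        rows.append(
            {
                "sample_id": sample_id,
                "status": _parse_status(record["status"], status_map, sample_id),
                "age": covs.get("age", np.nan),
                "sex": covs.get("sex"),
                "diet": covs.get("diet"),
                "alcohol": covs.get("alcohol"),
                "smoking": covs.get("smoking"),
            }
        )
        for j, locus in enumerate(loci):
            geno[i, j] = _parse_genotype(record[locus.locus_id], locus, sample_id)

    samples = pd.DataFrame(rows, columns=["sample_id", "status", *COVARIATE_COLUMNS])
    if samples.empty:
        samples = pd.DataFrame(columns=["sample_id", "status", *COVARIATE_COLUMNS])
    return Cohort(list(loci), samples, geno)


def write_cohort_table(cohort: Cohort, path) -> None:
    """Write a Cohort as a tab-delimited table that round-trips exactly."""
    out = cohort.samples.copy()
    for j, locus in enumerate(cohort.loci):
        column = cohort.genotypes[:, j]
        out[locus.locus_id] = ["NA" if not np.isfinite(g) else str(int(g)) for g in column]
    buffer = io.StringIO()
    out.to_csv(buffer, sep="\t", index=False, na_rep="NA")
    text = buffer.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_plink_text(ped_path, map_path, loci: Sequence[Locus]) -> Cohort:
    """Read PLINK text PED/MAP files.

    The MAP file's SNP identifiers are matched against ``locus_id`` or
    ``rsid`` of the supplied locus definitions; PED phenotype codes are
    1 = control, 2 = case, 0 / -9 = missing (individuals with a missing
    phenotype are dropped with a warning). Allele code "0" marks a missing
    genotype.
    """
    with open(map_path) as fh:
        map_rows = [line.split() for line in fh if line.strip()]
    if any(len(r) < 2 for r in map_rows):
        raise FormatError("MAP rows need at least chromosome and identifier columns")
    by_key: dict[str, Locus] = {}
    for locus in loci:
        by_key[locus.locus_id] = locus
        if locus.rsid:
            by_key[locus.rsid] = locus
    ordered: list[Locus] = []
    for row in map_rows:
        snp_id = row[1]
        if snp_id not in by_key:
            raise FormatError(f"MAP locus {snp_id!r} has no matching locus definition")
        ordered.append(by_key[snp_id])

    individuals: list[Individual] = []
    dosages: list[list[float]] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(ordered):
                raise FormatError(
                    f"PED line {line_no}: expected {6 + 2 * len(ordered)} fields for "
                    f"{len(ordered)} MAP loci, got {len(fields)}"
                )
            fam, ind, _pat, _mat, sex_code, phenotype = fields[:6]
            if phenotype not in {"0", "1", "2", "-9"}:
                raise DataError(f"PED line {line_no}: phenotype {phenotype!r} outside 0/1/2/-9")
            if phenotype in {"0", "-9"}:
                warnings.warn(f"PED line {line_no}: missing phenotype, individual dropped")
                continue
            sex = {"1": "male", "2": "female"}.get(sex_code)
            sample_id = f"{fam}:{ind}"
            row_dosage = []
            for j, locus in enumerate(ordered):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    row_dosage.append(np.nan)
                    continue
                row_dosage.append(_parse_genotype(f"{a1}/{a2}", locus, sample_id))
            individuals.append(Individual(sample_id, PLINK_STATUS_MAP[phenotype], sex=sex))
            dosages.append(row_dosage)
    geno = np.array(dosages, dtype=float).reshape(len(individuals), len(ordered))
    return Cohort.from_individuals(ordered, individuals, geno)


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Summarise group sizes, per-locus missingness, and data problems.

    Never raises: all problems land in ``report.errors``.
    """
    status = cohort.samples["status"]
    report = ValidationReport(
        n_cases=int((status == "case").sum()),
        n_controls=int((status == "control").sum()),
    )
    ids = cohort.samples["sample_id"]
    for dup in sorted(ids[ids.duplicated()].unique()):
        report.errors.append(f"duplicate sample_id {dup!r}")
    bad_status = sorted(set(status) - set(STATUS_LEVELS))
    for value in bad_status:
        report.errors.append(f"invalid status level {value!r}")
    for column, levels in (("sex", SEX_LEVELS), ("diet", DIET_LEVELS),
                           ("alcohol", ALCOHOL_LEVELS), ("smoking", SMOKING_LEVELS)):
        if column not in cohort.samples.columns:
            continue
        observed = cohort.samples[column].dropna()
        for value in sorted(set(observed) - set(levels)):
            report.errors.append(f"invalid {column} level {value!r}")
    n = cohort.n_individuals
    for j, locus in enumerate(cohort.loci):
        missing = int(np.isnan(cohort.genotypes[:, j]).sum()) if n else 0
        report.missingness[locus.locus_id] = missing / n if n else 0.0
    return report
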