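import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ccprs.cohort import Cohort, Locus

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_cohort(loci, genotypes, status, **covariates) -> Cohort:
    """Assemble a small cohort from plain lists (None = missing genotype)."""
    genotypes = np.array(
        [[np.nan if g is None else float(g) for g in row] for row in genotypes]
    )
    n = len(status)
    samples = pd.DataFrame(
        {
            "sample_id": covariates.get("sample_id", [f"s{i}" for i in range(n)]),
            "status": status,
            "age": covariates.get("age", [np.nan] * n),
            "sex": covariates.get("sex", [None] * n),
            "diet": covariates.get("diet", [None] * n),
            "alcohol": covariates.get("alcohol", [None] * n),
            "smoking": covariates.get("smoking", [None] * n),
        }
    )
    return Cohort(list(loci), samples, genotypes)


@pytest.fixture
def toy_loci():
    return [Locus("PTPN22", "C", "T", "T"), Locus("TNFR2", "T", "G", "G")]


@pytest.fixture
def two_locus_cohort(toy_loci):
    # 4x double non-risk homozygote, 2x double heterozygote, 4x double risk homozygote
    geno = [[0, 0]] * 4 + [[1, 1]] * 2 + [[2, 2]] * 4
    return make_cohort(toy_loci, geno, ["case"] * 5 + ["control"] * 5)
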