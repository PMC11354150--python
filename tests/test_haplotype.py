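import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ccprs.cohort import Cohort, Locus
from ccprs.errors import EstimationError, UndefinedStatisticError
from ccprs.haplotype import (HaplotypeTable, em_haplotypes, haplotype_association,
                             ld_stats)
from conftest import make_cohort

LOCI = [Locus("L1", "A", "a", "a"), Locus("L2", "B", "b", "b")]


def _cohort(dosage_rows, status=None):
    status = status or ["case"] * (len(dosage_rows) // 2) + \
        ["control"] * (len(dosage_rows) - len(dosage_rows) // 2)
    return make_cohort(LOCI[: len(dosage_rows[0])], dosage_rows, status)


# -- EM examples ----------------------------------------------------------------


def test_em_resolves_coupling_phase_from_homozygote_anchors(two_locus_cohort):
    table = em_haplotypes(two_locus_cohort, ["PTPN22", "TNFR2"])
    freqs = table.freqs
    assert freqs["CT"] == pytest.approx(0.5, abs=1e-6)
    assert freqs["TG"] == pytest.approx(0.5, abs=1e-6)
    assert freqs["CG"] == pytest.approx(0.0, abs=1e-6)
    assert freqs["TT"] == pytest.approx(0.0, abs=1e-6)
    assert table.converged


def test_single_double_homozygote_is_phase_unambiguous():
    table = em_haplotypes(_cohort([[2, 2]]), ["L1", "L2"])
    assert table.freqs["ab"] == pytest.approx(1.0)
    assert table.n_iterations <= 2


def test_phase_known_data_reduce_to_direct_counting():
    # no multi-heterozygote: every individual's haplotypes are determined
    rows = [[0, 0], [0, 2], [2, 2], [1, 0], [0, 1], [2, 1]]
    table = em_haplotypes(_cohort(rows), ["L1", "L2"])
    # direct haplotype count: (0,0)->AB,AB ; (0,2)->Ab,Ab ; (2,2)->ab,ab ;
    # (1,0)->AB,aB ; (0,1)->AB,Ab ; (2,1)->ab,aB
    counts = {"AB": 4, "Ab": 3, "aB": 2, "ab": 3}
    total = sum(counts.values())
    for hap, c in counts.items():
        assert table.freqs[hap] == pytest.approx(c / total, abs=1e-9)


def test_em_without_complete_observations_raises():
    with pytest.raises(EstimationError):
        em_haplotypes(_cohort([[None, 0], [0, None]]), ["L1", "L2"])


# -- EM vs exhaustive likelihood maximisation -------------------------------------


def _grid_oracle(cohort, grid=1e-3):
    """1-parameter exhaustive likelihood search for 2 loci: marginal allele
    frequencies are fixed at their sample values and h(ab) sweeps its
    feasible interval."""
    g = cohort.genotypes
    complete = np.isfinite(g).all(axis=1)
    g = g[complete]
    p1 = g[:, 0].mean() / 2  # freq of allele 'a' (bit 1) at L1
    p2 = g[:, 1].mean() / 2
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)
    best, best_ll = None, -np.inf
    for h11 in np.arange(lo, hi + grid / 2, grid):
        h10 = p1 - h11
        h01 = p2 - h11
        h00 = 1 - h11 - h10 - h01
        f = {(0, 0): h00, (0, 1): h01, (1, 0): h10, (1, 1): h11}
        if min(f.values()) < -1e-12:
            continue
        ll = 0.0
        for row in g.astype(int):
            prob = 0.0
            for hap1 in itertools.product((0, 1), repeat=2):
                for hap2 in itertools.product((0, 1), repeat=2):
                    if tuple(a + b for a, b in zip(hap1, hap2)) == tuple(row):
                        prob += f[hap1] * f[hap2]
            ll += math.log(max(prob, 1e-300))
        if ll > best_ll:
            best_ll, best = ll, f
    return best


FIXTURES = [
    [[0, 0]] * 4 + [[1, 1]] * 2 + [[2, 2]] * 4,
    [[1, 1]] * 4 + [[0, 0]] * 2,
    [[0, 0], [1, 1], [2, 2], [1, 0], [0, 1], [2, 1], [1, 2]],
    [[2, 0]] * 3 + [[0, 2]] * 3 + [[1, 1]] * 4,
    [[0, 0], [0, 0], [1, 1], [1, 1], [2, 2], [1, 0]],
    [[2, 2]] * 5 + [[1, 1]] * 5 + [[0, 1]] * 2,
]


@pytest.mark.parametrize("rows", FIXTURES)
def test_em_matches_grid_search_likelihood_maximum(rows):
    cohort = _cohort(rows)
    table = em_haplotypes(cohort, ["L1", "L2"])
    oracle = _grid_oracle(cohort)
    for bits, freq in zip(table.hap_bits, table.frequencies):
        assert freq == pytest.approx(oracle[bits], abs=1.5e-3)


# -- LD statistics ---------------------------------------------------------------


def _table(freqs):
    bits = [(0, 0), (0, 1), (1, 0), (1, 1)]
    arr = np.array([freqs[b] for b in bits])
    return HaplotypeTable(LOCI, bits, arr, 0.0, 1, True, 100)


def test_ld_matches_hand_formulas():
    # h(11)=0.5, h(10)=0.1, h(01)=0.2, h(00)=0.2 -> D=0.08, D'=0.444, r2=0.127
    table = _table({(1, 1): 0.5, (1, 0): 0.1, (0, 1): 0.2, (0, 0): 0.2})
    ld = ld_stats(table, n=100)
    assert ld.d == pytest.approx(0.08)
    assert ld.d_prime == pytest.approx(0.08 / 0.18)
    p1, p2 = 0.6, 0.7
    assert ld.r2 == pytest.approx(0.08**2 / (p1 * (1 - p1) * p2 * (1 - p2)))


def test_independent_haplotypes_have_zero_ld():
    p1, p2 = 0.6, 0.3
    table = _table({(1, 1): p1 * p2, (1, 0): p1 * (1 - p2),
                    (0, 1): (1 - p1) * p2, (0, 0): (1 - p1) * (1 - p2)})
    ld = ld_stats(table)
    assert ld.d == pytest.approx(0.0, abs=1e-12)
    assert ld.d_prime == pytest.approx(0.0, abs=1e-9)
    assert ld.r2 == pytest.approx(0.0, abs=1e-12)


def test_two_haplotype_system_is_complete_ld():
    table = _table({(1, 1): 0.7, (0, 0): 0.3, (1, 0): 0.0, (0, 1): 0.0})
    assert ld_stats(table).d_prime == pytest.approx(1.0)


def test_monomorphic_locus_has_undefined_ld():
    table = _table({(1, 1): 0.7, (1, 0): 0.3, (0, 1): 0.0, (0, 0): 0.0})
    with pytest.raises(UndefinedStatisticError):
        ld_stats(table)


def test_ld_is_invariant_under_allele_relabelling(two_locus_cohort):
    base = ld_stats(em_haplotypes(two_locus_cohort, ["PTPN22", "TNFR2"]))
    recoded = two_locus_cohort.recode_risk_allele("PTPN22", "C")
    other = ld_stats(em_haplotypes(recoded, ["PTPN22", "TNFR2"]))
    assert other.d_prime == pytest.approx(base.d_prime, abs=1e-9)
    assert other.r2 == pytest.approx(base.r2, abs=1e-9)


# -- haplotype association --------------------------------------------------------


def _tilted_haplotype_cohort(n, or_target, seed):
    """Phase-level simulation: haplotype 'ab' multiplies disease odds by
    or_target per copy under a prospective logistic disease model, so the
    retrospective per-copy odds ratio equals or_target exactly."""
    rng = np.random.default_rng(seed)
    hap_freqs = {(0, 0): 0.4, (0, 1): 0.25, (1, 0): 0.2, (1, 1): 0.15}
    haps = list(hap_freqs)
    probs = np.array(list(hap_freqs.values()))
    pick = rng.choice(len(haps), size=(n, 2), p=probs)
    arr = np.array(haps)
    dosage_h = ((arr[pick[:, 0]] == 1).all(axis=1).astype(int)
                + (arr[pick[:, 1]] == 1).all(axis=1).astype(int))
    geno = arr[pick[:, 0]] + arr[pick[:, 1]]
    lp = -0.8 + math.log(or_target) * dosage_h
    is_case = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))
    status = np.where(is_case, "case", "control")
    return _cohort(geno.tolist(), status=list(status))


def test_haplotype_association_recovers_a_strong_effect():
    cohort = _tilted_haplotype_cohort(6000, 3.0, seed=99)
    result = haplotype_association(cohort, ["L1", "L2"])
    row = next(r for r in result.rows if r.label == "ab")
    assert 2.2 < row.odds_ratio < 4.0
    assert row.p_value < 1e-4


def test_null_haplotype_effects_are_near_one():
    cohort = _tilted_haplotype_cohort(3000, 1.0, seed=5)
    result = haplotype_association(cohort, ["L1", "L2"])
    for row in result.rows:
        if not row.reference:
            assert abs(math.log(row.odds_ratio)) < 0.5


def test_absent_haplotype_does_not_appear_in_output():
    # only AB and ab present (complete coupling): Ab/aB should not be reported
    rows = [[0, 0]] * 6 + [[2, 2]] * 6 + [[1, 1]] * 4
    result = haplotype_association(_cohort(rows), ["L1", "L2"])
    labels = {r.label for r in result.rows}
    assert "Ab" not in labels and "aB" not in labels


def test_reference_is_the_most_frequent_haplotype():
    cohort = _tilted_haplotype_cohort(2000, 1.0, seed=17)
    result = haplotype_association(cohort, ["L1", "L2"])
    assert result.rows[0].reference
    assert result.rows[0].frequency == max(r.frequency for r in result.rows)
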