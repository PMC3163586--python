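"""Shared fixtures and independent brute-force oracles.

The oracles here recompute every quantity from first principles (raw
matrix loops, exact rational arithmetic) and are deliberately ignorant of
the package's bitset/streaming machinery.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations, product

import numpy as np
import pytest

from combosnp import CohortSpec, GenotypeMatrix, SnpRecord, generate_null_cohort
from combosnp.genotype_data import MISSING


# ---------------------------------------------------------------------------
# matrix constructors
# ---------------------------------------------------------------------------

def make_matrix(calls, labels, genes=None, ids=None) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    genes = genes or [f"G{j}" for j in range(m)]
    panel = [SnpRecord(f"rs{j}", genes[j], "1", 1000 + j, j) for j in range(m)]
    ids = ids or [f"I{i}" for i in range(n)]
    return GenotypeMatrix(calls, np.array(labels, dtype=object), panel,
                          np.array(ids, dtype=object))


def random_matrix(rng, n_snps=8, n_individuals=30, missing_rate=0.1,
                  n_cases=None) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n_individuals, n_snps)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = MISSING
    n_cases = n_cases or n_individuals // 3 or 1
    labels = ["case"] * n_cases + ["control"] * (n_individuals - n_cases)
    return make_matrix(calls, labels)


@pytest.fixture
def small_null_cohort():
    return generate_null_cohort(
        CohortSpec(n_cases=40, n_controls=80, n_snps=10, seed=7)
    )


# ---------------------------------------------------------------------------
# brute-force combination oracle (raw triple loops over the calls matrix)
# ---------------------------------------------------------------------------

def brute_force_combos(matrix: GenotypeMatrix, k: int, min_carriers: int = 1):
    """Every k-combination with >= min_carriers carriers, by direct loops.

    Yields (pairs, case_carriers, control_carriers, carrier_row_indices).
    """
    calls = matrix.calls
    case = matrix.case_mask
    n, m = calls.shape
    for snps in combinations(range(m), k):
        for codes in product((0, 1, 2), repeat=k):
            carriers = np.ones(n, dtype=bool)
            for s, g in zip(snps, codes):
                carriers &= calls[:, s] == g
            total = int(carriers.sum())
            if total >= min_carriers:
                nc = int((carriers & case).sum())
                yield (tuple(zip(snps, codes)), nc, total - nc,
                       np.flatnonzero(carriers))


def brute_force_tally(matrix: GenotypeMatrix, k: int):
    """(observed, common, control_only, patient_only, histogram dict)."""
    observed = common = ctrl_only = pat_only = 0
    hist: dict[int, int] = {}
    for _pairs, nc, nt, _rows in brute_force_combos(matrix, k):
        observed += 1
        if nc and nt:
            common += 1
        elif nt:
            ctrl_only += 1
        else:
            pat_only += 1
            hist[nc] = hist.get(nc, 0) + 1
    return observed, common, ctrl_only, pat_only, hist


def brute_force_clusters(matrix: GenotypeMatrix, min_patients_per_combo: int,
                         min_combos: int, min_patients: int = 1):
    """Cluster predicate evaluated over all genotypes by raw set arithmetic."""
    patient_specific = [
        (pairs, set(rows))
        for pairs, nc, nt, rows in brute_force_combos(matrix, 3,
                                                      min_patients_per_combo)
        if nt == 0 and nc >= min_patients_per_combo
    ]
    case_rows = np.flatnonzero(matrix.case_mask)
    clusters = {}
    genotypes = {p for pairs, _ in patient_specific for p in pairs}
    for g in genotypes:
        members = [(pairs, rows) for pairs, rows in patient_specific
                   if g in pairs]
        if len(members) < min_combos:
            continue
        union = set().union(*(rows for _, rows in members))
        all_carriers = {
            int(i) for i in case_rows if matrix.calls[i, g[0]] == g[1]
        }
        if union == all_carriers and len(union) >= min_patients:
            clusters[g] = (len(members), union)
    return clusters


# ---------------------------------------------------------------------------
# exact-test oracles (full enumeration, exact rationals)
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=None)
def _hwe_distribution(n: int, na: int) -> dict[int, Fraction]:
    """P(het = h | n individuals, na minor alleles) by the direct
    factorial formula, for every admissible h."""
    f = math.factorial
    nb = 2 * n - na
    probs = {}
    for h in range(na % 2, na + 1, 2):
        rare = (na - h) // 2
        common = n - rare - h
        probs[h] = Fraction(2 ** h * f(n) * f(na) * f(nb),
                            f(rare) * f(h) * f(common) * f(2 * n))
    return probs


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """HWE exact p by direct factorial-formula enumeration over all
    heterozygote counts sharing the allele totals and parity."""
    n = n_hom_ref + n_het + n_hom_alt
    na = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if na == 0:
        return Fraction(1)
    probs = _hwe_distribution(n, na)
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)


def freeman_halton_oracle(table) -> Fraction:
    """Exact 2x3 p by brute force: every (a0, a1) pair in the full margin
    box is visited and checked for table validity; probabilities use the
    plain factorial formula."""
    t = np.asarray(table, dtype=int)
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = int(t.sum())
    f = math.factorial

    def prob(tab):
        denom = 1
        for x in tab.ravel():
            denom *= f(int(x))
        return Fraction(f(r[0]) * f(r[1]) * f(c[0]) * f(c[1]) * f(c[2]),
                        f(n) * denom)

    p_obs = prob(t)
    total = Fraction(0)
    for a0 in range(int(c[0]) + 1):
        for a1 in range(int(c[1]) + 1):
            a2 = int(r[0]) - a0 - a1
            if 0 <= a2 <= int(c[2]):
                tab = np.array([[a0, a1, a2],
                                [c[0] - a0, c[1] - a1, c[2] - a2]])
                p = prob(tab)
                if p <= p_obs:
                    total += p
    return total
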