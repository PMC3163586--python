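"""Carrier index, combination enumeration and penetrance tallies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from combosnp import (GenotypeCombo, build_carrier_index,
                      collect_patient_specific, enumerate_combos,
                      tally_combos, tally_matrix,
                      theoretical_combination_count)
from combosnp import _bitset
from combosnp.genotype_data import MISSING

from conftest import brute_force_combos, brute_force_tally, make_matrix, random_matrix


# ---------------------------------------------------------------------------
# theoretical counts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,k,expected", [
    (803, 3, 2_321_319_627),
    (803, 2, 2_898_027),
    (469, 3, 461_262_438),
    (3, 3, 27),
    (10, 1, 30),
])
def test_theoretical_combination_count(n, k, expected):
    assert theoretical_combination_count(n, k) == expected


def test_theoretical_count_rejects_k_above_n():
    with pytest.raises(ValueError):
        theoretical_combination_count(2, 3)


# ---------------------------------------------------------------------------
# carrier index
# ---------------------------------------------------------------------------

def test_missing_call_carries_no_genotype():
    m = make_matrix([[0], [MISSING]], ["case", "control"])
    idx = build_carrier_index(m)
    assert list(idx.carriers(0, 0)) == [0]
    assert idx.carriers(0, 1).size == 0
    assert idx.carriers(0, 2).size == 0


def test_uniform_genotype_fills_one_bitset():
    m = make_matrix([[1]] * 6, ["case"] * 2 + ["control"] * 4)
    idx = build_carrier_index(m)
    assert list(idx.carriers(0, 1)) == list(range(6))
    assert idx.carriers(0, 0).size == idx.carriers(0, 2).size == 0


def test_bitsets_partition_nonmissing_rows():
    rng = np.random.default_rng(5)
    m = random_matrix(rng, n_snps=8, n_individuals=30)
    idx = build_carrier_index(m)
    for j in range(m.n_snps):
        sets = [set(idx.carriers(j, g)) for g in (0, 1, 2)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        nonmissing = set(np.flatnonzero(m.calls[:, j] != MISSING))
        assert sets[0] | sets[1] | sets[2] == nonmissing
    case = set(np.flatnonzero(m.case_mask))
    ctrl = set(_bitset.indices(idx.control_words, m.n_individuals))
    assert case.isdisjoint(ctrl) and case | ctrl == set(range(m.n_individuals))


def test_combo_canonical_form_and_validation():
    a = GenotypeCombo.of((3, 1), (0, 2), (5, 0))
    assert a.snps == (0, 3, 5)
    assert a == GenotypeCombo.of((0, 2), (5, 0), (3, 1))
    with pytest.raises(ValueError):
        GenotypeCombo(((0, 1), (0, 2), (3, 0)))  # duplicate SNP
    with pytest.raises(ValueError):
        GenotypeCombo(((0, 3),))  # bad code


# ---------------------------------------------------------------------------
# enumeration vs brute force
# ---------------------------------------------------------------------------

def _stream_as_set(matrix, k, min_carriers=1):
    idx = build_carrier_index(matrix)
    return {(c.pairs, nc, nt)
            for c, nc, nt in enumerate_combos(idx, k, min_carriers)}


def _brute_as_set(matrix, k, min_carriers=1):
    return {(pairs, nc, nt)
            for pairs, nc, nt, _ in brute_force_combos(matrix, k, min_carriers)}


@pytest.mark.parametrize("k", [1, 2, 3])
def test_enumeration_equals_brute_force_fixed_fixture(k):
    rng = np.random.default_rng(42)
    m = random_matrix(rng, n_snps=5, n_individuals=12, missing_rate=0.1)
    assert _stream_as_set(m, k) == _brute_as_set(m, k)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(3, 8), st.integers(6, 30))
def test_enumeration_equals_brute_force_property(seed, n_snps, n_ind):
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, n_snps=n_snps, n_individuals=n_ind, missing_rate=0.1)
    assert _stream_as_set(m, 3) == _brute_as_set(m, 3)


def test_single_carrier_combo_is_reported():
    calls = np.full((4, 3), MISSING, dtype=np.int8)
    calls[0] = [0, 1, 2]
    m = make_matrix(calls, ["case", "case", "control", "control"])
    idx = build_carrier_index(m)
    found = dict(
        ((c.pairs), (nc, nt)) for c, nc, nt in enumerate_combos(idx, 3, 1)
    )
    assert found == {(((0, 0), (1, 1), (2, 2))): (1, 0)}


def test_carrier_monotonicity_under_extension():
    rng = np.random.default_rng(7)
    m = random_matrix(rng, n_snps=6, n_individuals=25, missing_rate=0.05)
    idx = build_carrier_index(m)
    pair_counts = {c.pairs: nc + nt for c, nc, nt in enumerate_combos(idx, 2, 1)}
    for combo, nc, nt in enumerate_combos(idx, 3, 1):
        for drop in range(3):
            sub = tuple(p for i, p in enumerate(combo.pairs) if i != drop)
            assert nc + nt <= pair_counts.get(sub, 0)


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

def test_tally_matches_brute_force_and_identities():
    rng = np.random.default_rng(11)
    m = random_matrix(rng, n_snps=6, n_individuals=20, missing_rate=0.1)
    idx = build_carrier_index(m)
    tally = tally_matrix(idx, 3)
    assert (tally.observed, tally.common, tally.control_only,
            tally.patient_only, tally.histogram) == brute_force_tally(m, 3)
    tally.validate()


def test_identical_case_control_rows_leave_only_common():
    rng = np.random.default_rng(3)
    block = rng.integers(0, 3, size=(10, 5)).astype(np.int8)
    calls = np.vstack([block, block])
    m = make_matrix(calls, ["case"] * 10 + ["control"] * 10)
    tally = tally_matrix(build_carrier_index(m), 3)
    assert tally.control_only == 0 and tally.patient_only == 0
    assert tally.observed == tally.common


def test_label_swap_exchanges_penetrance_classes():
    rng = np.random.default_rng(19)
    m = random_matrix(rng, n_snps=6, n_individuals=24, missing_rate=0.05)
    swapped = make_matrix(
        m.calls,
        ["control" if lab == "case" else "case" for lab in m.labels],
    )
    t1 = tally_matrix(build_carrier_index(m), 3)
    t2 = tally_matrix(build_carrier_index(swapped), 3)
    assert (t1.observed, t1.common) == (t2.observed, t2.common)
    assert t1.patient_only == t2.control_only
    assert t1.control_only == t2.patient_only


def test_streaming_tally_equals_fast_tally(small_null_cohort):
    idx = build_carrier_index(small_null_cohort)
    fast = tally_matrix(idx, 3)
    slow = tally_combos(enumerate_combos(idx, 3, 1), idx.n_cases,
                        idx.n_controls, idx.n_snps, 3)
    assert (fast.observed, fast.common, fast.control_only, fast.patient_only,
            fast.histogram) == (slow.observed, slow.common, slow.control_only,
                                slow.patient_only, slow.histogram)


def test_planted_case_exclusive_triple_lands_in_histogram():
    rng = np.random.default_rng(23)
    m = random_matrix(rng, n_snps=6, n_individuals=20, missing_rate=0.0,
                      n_cases=8)
    # make code 2 at SNPs 0,1,2 exclusive to cases 0..2
    for j in (0, 1, 2):
        col = m.calls[:, j]
        col[col == 2] = 1
        col[[0, 1, 2]] = 2
    tally = tally_matrix(build_carrier_index(m), 3)
    assert tally.histogram.get(3, 0) >= 1


# ---------------------------------------------------------------------------
# patient-specific collection
# ---------------------------------------------------------------------------

def test_collect_consistent_with_tally():
    rng = np.random.default_rng(31)
    m = random_matrix(rng, n_snps=7, n_individuals=25, missing_rate=0.1)
    idx = build_carrier_index(m)
    collected = collect_patient_specific(idx, 3, min_patients=1)
    tally = tally_matrix(idx, 3)
    assert len(collected) == tally.patient_only
    brute = {
        pairs: set(rows)
        for pairs, nc, nt, rows in brute_force_combos(m, 3, 1) if nt == 0
    }
    for combo, bits in collected:
        assert set(_bitset.indices(bits, m.n_individuals)) == brute[combo.pairs]


def test_collect_is_antimonotone_in_min_patients():
    rng = np.random.default_rng(37)
    m = random_matrix(rng, n_snps=7, n_individuals=30, missing_rate=0.05)
    idx = build_carrier_index(m)
    previous = None
    for mp in (1, 2, 3, 5):
        combos = {c.pairs for c, _ in collect_patient_specific(idx, 3, mp)}
        if previous is not None:
            assert combos <= previous
        previous = combos


def test_high_threshold_on_null_cohort_is_typically_empty():
    from combosnp import CohortSpec, generate_null_cohort

    m = generate_null_cohort(
        CohortSpec(n_cases=100, n_controls=200, n_snps=50, seed=41)
    )
    idx = build_carrier_index(m)
    collected = collect_patient_specific(idx, 3, min_patients=9)
    brute = [
        pairs for pairs, nc, nt, _ in brute_force_combos(m, 3, 9)
        if nt == 0 and nc >= 9
    ]
    assert sorted(c.pairs for c, _ in collected) == sorted(brute)
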