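"""Carrier-set construction and exhaustive k-SNP genotype combination mining.

A *k-combination* is an unordered set of k (SNP, genotype-code) pairs over k
distinct SNPs; an individual carries it iff they carry all k genotypes.  The
engine enumerates every combination carried by at least one individual and
classifies it by penetrance: common to both groups, control-only, or
patient-only (carried by >= 1 case and no control).  Individuals missing a
call at any of the combination's SNPs are not carriers of it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Iterator

import numpy as np

from . import _bitset
from ._kernels import collect_patient_specific_k3, tally_k3
from .genotype_data import MISSING, GenotypeMatrix

#: Above this panel size exhaustive triple enumeration gets expensive on a
#: single workstation; operations warn and expect an explicit override.
MAX_SNPS_GUARD = 300


@dataclass(frozen=True, order=True)
class GenotypeCombo:
    """k (SNP index, genotype code) pairs with strictly increasing SNP indices."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        snps = [s for s, _ in self.pairs]
        if sorted(set(snps)) != snps:
            raise ValueError("SNP indices must be distinct and increasing")
        if not all(g in (0, 1, 2) for _, g in self.pairs):
            raise ValueError("genotype codes must be in {0,1,2}")

    @classmethod
    def of(cls, *pairs: tuple[int, int]) -> "GenotypeCombo":
        return cls(tuple(sorted(pairs)))

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def snps(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.pairs)

    def genotype_at(self, snp: int) -> int:
        for s, g in self.pairs:
            if s == snp:
                return g
        raise KeyError(snp)

    def __contains__(self, genotype: tuple[int, int]) -> bool:
        return genotype in self.pairs


class CarrierIndex:
    """Per-(SNP, genotype) carrier bitsets plus case/control masks.

    Carrier sets depend only on the genotype calls, so a single index serves
    both the observed analysis and every label permutation: permutations swap
    in a new case mask via :meth:`relabel` without touching the carrier words.
    """

    def __init__(self, words: np.ndarray, case_mask: np.ndarray,
                 rsids: list[str] | None = None):
        self.words = words                       # (S, 3, W) uint64
        self.case_mask = np.asarray(case_mask, dtype=bool)
        self.n_individuals = self.case_mask.size
        self.n_snps = words.shape[0]
        self.rsids = rsids or [f"snp{j}" for j in range(self.n_snps)]
        self.case_words = _bitset.pack(self.case_mask)
        self.control_words = _bitset.pack(~self.case_mask)

    @classmethod
    def from_matrix(cls, matrix: GenotypeMatrix) -> "CarrierIndex":
        n, m = matrix.calls.shape
        W = _bitset.n_words(n)
        words = np.zeros((m, 3, W), dtype=np.uint64)
        for j in range(m):
            col = matrix.calls[:, j]
            for g in (0, 1, 2):
                words[j, g] = _bitset.pack(col == g)
        return cls(words, matrix.case_mask, [r.rsid for r in matrix.panel])

    def relabel(self, case_mask: np.ndarray) -> "CarrierIndex":
        """Same carrier words under a different case/control labelling."""
        if case_mask.size != self.n_individuals:
            raise ValueError("case mask length mismatch")
        out = CarrierIndex.__new__(CarrierIndex)
        out.words = self.words
        out.case_mask = np.asarray(case_mask, dtype=bool)
        out.n_individuals = self.n_individuals
        out.n_snps = self.n_snps
        out.rsids = self.rsids
        out.case_words = _bitset.pack(out.case_mask)
        out.control_words = _bitset.pack(~out.case_mask)
        return out

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return self.n_individuals - self.n_cases

    def genotype_words(self, snp: int, code: int) -> np.ndarray:
        return self.words[snp, code]

    def carriers(self, snp: int, code: int) -> np.ndarray:
        """0-based individual indices carrying genotype ``code`` at ``snp``."""
        return _bitset.indices(self.words[snp, code], self.n_individuals)

    def combo_words(self, combo: GenotypeCombo) -> np.ndarray:
        w = self.words[combo.pairs[0][0], combo.pairs[0][1]].copy()
        for s, g in combo.pairs[1:]:
            w &= self.words[s, g]
        return w

    def case_masked(self) -> np.ndarray:
        return self.words & self.case_words[None, None, :]

    def control_masked(self) -> np.ndarray:
        return self.words & self.control_words[None, None, :]


@dataclass
class ComboTally:
    """Penetrance accounting over the full k-combination space.

    ``histogram[j]`` counts patient-only combinations carried by exactly j
    patients; identities ``observed = common + control_only + patient_only``
    and ``sum(histogram) = patient_only`` hold by construction and are
    re-checked by :meth:`validate`.
    """

    k: int
    n_snps: int
    theoretical: int
    observed: int
    common: int
    control_only: int
    patient_only: int
    histogram: dict[int, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.observed != self.common + self.control_only + self.patient_only:
            raise AssertionError("tally identity violated: observed != sum of classes")
        if sum(self.histogram.values()) != self.patient_only:
            raise AssertionError("tally identity violated: histogram != patient_only")
        if self.observed > self.theoretical:
            raise AssertionError("observed exceeds theoretical count")

    def patient_only_at_least(self, min_patients: int) -> int:
        return sum(c for j, c in self.histogram.items() if j >= min_patients)

    def to_frame(self):
        import pandas as pd

        rows = [
            (f"Theoretical number with {self.n_snps} SNPs", self.theoretical),
            (f"Found in the material of {self.n_snps} SNPs", self.observed),
            ("Common for control persons and patients", self.common),
            ("Found in the control persons only", self.control_only),
            ("Found in the patients only", self.patient_only),
        ]
        for j in sorted(self.histogram):
            label = ("Found in single patients only and no control person"
                     if j == 1 else
                     f"Common for {j} patients and no control person")
            rows.append((label, self.histogram[j]))
        return pd.DataFrame(rows, columns=["class", f"n_{self.k}_combinations"])


def theoretical_combination_count(n_snps: int, k: int) -> int:
    """C(n_snps, k) * 3**k — the size of the k-combination genotype space."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_snps:
        raise ValueError(f"k={k} exceeds n_snps={n_snps}")
    return math.comb(n_snps, k) * 3 ** k


def build_carrier_index(matrix: GenotypeMatrix) -> CarrierIndex:
    return CarrierIndex.from_matrix(matrix)


def _check_guard(n_snps: int, max_snps: int | None) -> None:
    limit = MAX_SNPS_GUARD if max_snps is None else max_snps
    if n_snps > limit:
        warnings.warn(
            f"exhaustive enumeration over {n_snps} SNPs exceeds the "
            f"{limit}-SNP guard and may take very long",
            stacklevel=3,
        )


def enumerate_combos(index: CarrierIndex, k: int, min_carriers: int = 1,
                     max_snps: int | None = None,
                     ) -> Iterator[tuple[GenotypeCombo, int, int]]:
    """Stream every k-combination with >= min_carriers carriers.

    Yields ``(combo, case_carriers, control_carriers)`` in lexicographic
    order over SNP index tuples, genotype codes in base-3 order.  SNP pairs
    with empty carrier intersections are pruned before extension to triples.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    _check_guard(index.n_snps, max_snps)
    words = index.words
    case_w = index.case_words
    ctrl_w = index.control_words
    S = index.n_snps

    def counts(w):
        return (_bitset.popcount(w & case_w), _bitset.popcount(w & ctrl_w))

    if k == 1:
        for i in range(S):
            for gi in range(3):
                nc, nt = counts(words[i, gi])
                if nc + nt >= min_carriers:
                    yield GenotypeCombo.of((i, gi)), nc, nt
        return
    if k == 2:
        for i, j in combinations(range(S), 2):
            for gi, gj in product(range(3), range(3)):
                w = words[i, gi] & words[j, gj]
                nc, nt = counts(w)
                if nc + nt >= min_carriers:
                    yield GenotypeCombo.of((i, gi), (j, gj)), nc, nt
        return
    for i, j in combinations(range(S), 2):
        for gi, gj in product(range(3), range(3)):
            pair = words[i, gi] & words[j, gj]
            if not pair.any():
                continue
            for kk in range(j + 1, S):
                for gk in range(3):
                    w = pair & words[kk, gk]
                    nc, nt = counts(w)
                    if nc + nt >= min_carriers:
                        yield GenotypeCombo.of((i, gi), (j, gj), (kk, gk)), nc, nt


def tally_combos(stream: Iterable[tuple[GenotypeCombo, int, int]],
                 n_cases: int, n_controls: int, n_snps: int, k: int) -> ComboTally:
    """Fold an enumeration stream (min_carriers=1) into a ComboTally."""
    observed = common = ctrl_only = pat_only = 0
    hist: dict[int, int] = {}
    for _combo, nc, nt in stream:
        observed += 1
        if nc > 0 and nt > 0:
            common += 1
        elif nt > 0:
            ctrl_only += 1
        else:
            pat_only += 1
            hist[nc] = hist.get(nc, 0) + 1
    tally = ComboTally(
        k=k, n_snps=n_snps,
        theoretical=theoretical_combination_count(n_snps, k),
        observed=observed, common=common, control_only=ctrl_only,
        patient_only=pat_only, histogram=hist,
    )
    tally.validate()
    return tally


def tally_matrix(index: CarrierIndex, k: int, max_snps: int | None = None) -> ComboTally:
    """ComboTally over the full k-combination space (fast path for k=3)."""
    if k == 3:
        _check_guard(index.n_snps, max_snps)
        observed, common, ctrl_only, pat_only, hist_arr = tally_k3(
            index.case_masked(), index.control_masked(), index.n_cases
        )
        hist = {j: int(c) for j, c in enumerate(hist_arr) if c > 0}
        tally = ComboTally(
            k=3, n_snps=index.n_snps,
            theoretical=theoretical_combination_count(index.n_snps, 3),
            observed=int(observed), common=int(common),
            control_only=int(ctrl_only), patient_only=int(pat_only),
            histogram=hist,
        )
        tally.validate()
        return tally
    return tally_combos(
        enumerate_combos(index, k, 1, max_snps=max_snps),
        index.n_cases, index.n_controls, index.n_snps, k,
    )


def collect_patient_specific(index: CarrierIndex, k: int = 3, min_patients: int = 9,
                             max_snps: int | None = None,
                             ) -> list[tuple[GenotypeCombo, np.ndarray]]:
    """Combinations carried by >= min_patients cases and zero controls.

    Returns ``(combo, carrier_words)`` pairs; carrier words are packed
    bitsets over individuals (all carriers are cases by construction).
    Memory scales with the size of this filtered set, not the combo space.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    if k == 3:
        _check_guard(index.n_snps, max_snps)
        wc = index.case_masked()
        wt = index.control_masked()
        max_out = 1 << 14
        while True:
            n_out, combos, bits = collect_patient_specific_k3(
                wc, wt, min_patients, max_out
            )
            if n_out >= 0:
                break
            max_out *= 4
        return [
            (GenotypeCombo.of((int(combos[r, 0]), int(combos[r, 1])),
                              (int(combos[r, 2]), int(combos[r, 3])),
                              (int(combos[r, 4]), int(combos[r, 5]))),
             bits[r].copy())
            for r in range(n_out)
        ]
    out = []
    for combo, nc, nt in enumerate_combos(index, k, min_patients, max_snps=max_snps):
        if nt == 0 and nc >= min_patients:
            out.append((combo, index.combo_words(combo) & index.case_words))
    return out


def write_patient_specific_tsv(combos, index: CarrierIndex,
                               individual_ids: np.ndarray, path) -> None:
    """TSV export: rsid/genotype columns, patient count, patient id list."""
    import pandas as pd

    rows = []
    for combo, bits in combos:
        idx = _bitset.indices(bits, index.n_individuals)
        row = {}
        for pos, (s, g) in enumerate(combo.pairs, start=1):
            row[f"rsid{pos}"] = index.rsids[s]
            row[f"gt{pos}"] = g
        row["n_patients"] = len(idx)
        row["patient_ids"] = ";".join(str(individual_ids[i]) for i in idx)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
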