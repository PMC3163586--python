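"""Single-SNP case-control genotype association.

Each SNP's 2x3 genotype table (case/control x codes 0/1/2, missing calls
excluded per SNP) is tested with a chi-square test when every expected cell
count is >= 5, otherwise with the Freeman-Halton exact test (the 2x3
generalisation of Fisher's exact test).  Bonferroni correction multiplies
nominal p-values by the number of SNPs tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .genotype_data import MISSING, GenotypeMatrix


@dataclass
class SnpAssociationResult:
    rsid: str
    gene: str
    table: np.ndarray          # 2x3: rows case/control, columns codes 0/1/2
    test_used: str             # "chisq" | "fisher" | "degenerate"
    statistic: float | None
    p: float
    p_bonferroni: float = float("nan")


def freeman_halton_2x3(table: np.ndarray) -> float:
    """Exact p for a 2x3 table: sum of probabilities, over all tables with
    the observed margins, of every table whose conditional (multivariate
    hypergeometric) probability does not exceed the observed one.

    Table probabilities are handled as exact rationals so that ties between
    equally probable tables are resolved unambiguously.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 3) or (t < 0).any():
        raise ValueError("need a non-negative 2x3 table")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty table")
    comb = math.comb

    def weight(a0, a1, a2):
        # integer multinomial coefficient n!/prod(cells!), proportional to
        # the table's conditional probability (margin constant cancels)
        b0, b1 = int(c[0]) - a0, int(c[1]) - a1
        b2 = int(c[2]) - a2
        w = comb(n, a0)
        rest = n - a0
        for cell in (a1, a2, b0, b1):
            w *= comb(rest, cell)
            rest -= cell
        return w

    w_obs = weight(int(t[0, 0]), int(t[0, 1]), int(t[0, 2]))
    tail = 0
    total = 0
    for a0 in range(max(0, int(r[0] - c[1] - c[2])), min(int(r[0]), int(c[0])) + 1):
        for a1 in range(max(0, int(r[0]) - a0 - int(c[2])),
                        min(int(r[0]) - a0, int(c[1])) + 1):
            w = weight(a0, a1, int(r[0]) - a0 - a1)
            total += w
            if w <= w_obs:
                tail += w
    return min(1.0, float(Fraction(tail, total)))


def genotype_association_test(table: np.ndarray,
                              ) -> tuple[float | None, float, str]:
    """Test a 2x3 genotype table; returns (statistic_or_None, p, test_used).

    Genotype columns empty in both groups are dropped; if a single column
    remains the distributions are identical by construction and p = 1.
    Chi-square (df = columns - 1) is used when all expected counts are >= 5,
    else the Freeman-Halton exact test.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 3) or (t < 0).any():
        raise ValueError("need a non-negative 2x3 table")
    if t.sum(axis=1).min() == 0 or t.sum() == 0:
        raise ValueError("each group needs at least one observation")
    nonempty = t.sum(axis=0) > 0
    t_red = t[:, nonempty]
    if t_red.shape[1] <= 1:
        return None, 1.0, "degenerate"
    expected = np.outer(t_red.sum(axis=1), t_red.sum(axis=0)) / t_red.sum()
    if (expected >= 5).all():
        stat, p, _, _ = chi2_contingency(t_red, correction=False)
        return float(stat), float(p), "chisq"
    padded = np.zeros((2, 3), dtype=np.int64)
    padded[:, : t_red.shape[1]] = t_red
    return None, freeman_halton_2x3(padded), "fisher"


def bonferroni_adjust(pvals) -> np.ndarray:
    """min(1, p * m) for m = number of tests; empty input -> empty output."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0,1]")
    return np.minimum(1.0, p * p.size)


def genotype_table(matrix: GenotypeMatrix, snp: int) -> np.ndarray:
    """2x3 case/control genotype counts for one SNP, complete-case."""
    col = matrix.calls[:, snp]
    case = matrix.case_mask
    out = np.zeros((2, 3), dtype=np.int64)
    for g in (0, 1, 2):
        out[0, g] = int(((col == g) & case).sum())
        out[1, g] = int(((col == g) & ~case).sum())
    return out


def associate_snps(matrix: GenotypeMatrix) -> list[SnpAssociationResult]:
    """Association test per SNP, Bonferroni-adjusted over the panel."""
    results = []
    for rec in matrix.panel:
        table = genotype_table(matrix, rec.index)
        stat, p, used = genotype_association_test(table)
        results.append(SnpAssociationResult(
            rsid=rec.rsid, gene=rec.gene, table=table,
            test_used=used, statistic=stat, p=p,
        ))
    adjusted = bonferroni_adjust([r.p for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_bonferroni = float(p_adj)
    return results


def association_frame(results: list[SnpAssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in results],
            "gene": [r.gene for r in results],
            "case_0": [r.table[0, 0] for r in results],
            "case_1": [r.table[0, 1] for r in results],
            "case_2": [r.table[0, 2] for r in results],
            "control_0": [r.table[1, 0] for r in results],
            "control_1": [r.table[1, 1] for r in results],
            "control_2": [r.table[1, 2] for r in results],
            "test": [r.test_used for r in results],
            "p": [r.p for r in results],
            "p_bonf": [r.p_bonferroni for r in results],
        }
    )
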