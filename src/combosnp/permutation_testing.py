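"""Label-permutation null for the combination/cluster pipeline.

The carrier sets depend only on genotypes, so each permutation re-labels a
random subset of individuals as pseudo-patients and re-runs the identical
patient-specific-combination and cluster analysis against the fixed carrier
index.  Empirical p-values are exceedance fractions ``count / B``; a zero
count is displayed as ``p < 1/B``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .cluster_analysis import (find_clusters, find_pair_subgroups,
                               find_same_gene_subgroups)
from .combination_engine import CarrierIndex, collect_patient_specific
from .genotype_data import GenotypeMatrix

#: Statistics tracked per permutation, in reporting order.
STATISTICS = ("patient_specific_combos", "clusters", "pair_subgroups",
              "same_gene_combos")


@dataclass
class Thresholds:
    """Fixed thresholds applied identically to the observed run and every
    permutation (they are never re-tuned per permutation)."""

    min_patients_per_combo: int = 9     # patients per patient-specific combo
    min_combos: int = 30                # member combos per cluster
    min_patients: int = 1               # patients per cluster
    min_third_snps: int = 4             # distinct third SNPs per pair subgroup


@dataclass
class PermutationConfig:
    B: int = 1000
    n_cases: int | None = None          # default: observed case count
    seed: int = 0
    statistics: tuple[str, ...] = STATISTICS
    thresholds: Thresholds = field(default_factory=Thresholds)
    estimator: str = "plugin"           # "plugin" (count/B) or "add_one"
    max_seconds: float | None = None    # projected-runtime guard
    force: bool = False

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        unknown = set(self.statistics) - set(STATISTICS)
        if unknown:
            raise ValueError(f"unknown statistics {sorted(unknown)}")


@dataclass
class PermutationResult:
    observed: dict[str, int]
    null_counts: dict[str, int]
    B: int
    seed: int
    pvalues: dict[str, float]
    displays: dict[str, str]
    log: list[dict[str, int]]           # per-permutation statistic values

    def tier_exceedance(self, statistic: str, threshold: int) -> int:
        """Number of permutations with ``statistic >= threshold``."""
        return sum(1 for row in self.log if row[statistic] >= threshold)


def permute_labels(n_total: int, n_cases: int, rng: np.random.Generator,
                   ) -> np.ndarray:
    """Uniformly random case mask of size n_cases; genotypes untouched."""
    if not 0 < n_cases < n_total:
        raise ValueError("need 0 < n_cases < n_total")
    mask = np.zeros(n_total, dtype=bool)
    mask[rng.permutation(n_total)[:n_cases]] = True
    return mask


def null_statistics_one_perm(carrier_index: CarrierIndex, case_mask: np.ndarray,
                             thresholds: Thresholds, panel=None,
                             ) -> dict[str, int]:
    """Recompute all tracked statistics under one labelling.

    Runs the same code path as the observed analysis: patient-specific
    3-combination collection, cluster detection, pair subgroups and
    same-gene subgroups.  ``panel`` (SnpRecord list) is needed only for the
    same-gene statistic; without it that statistic is 0.
    """
    index = carrier_index.relabel(case_mask)
    combos = collect_patient_specific(
        index, k=3, min_patients=thresholds.min_patients_per_combo
    )
    clusters = find_clusters(combos, index, min_combos=thresholds.min_combos,
                             min_patients=thresholds.min_patients)
    n_subgroups = 0
    n_same_gene_combos = 0
    for cl in clusters:
        subs = find_pair_subgroups(cl, min_third_snps=thresholds.min_third_snps)
        n_subgroups += len(subs)
        if panel is not None:
            for sg in find_same_gene_subgroups(subs, panel):
                n_same_gene_combos += len(sg.member_combos)
    return {
        "patient_specific_combos": len(combos),
        "clusters": len(clusters),
        "pair_subgroups": n_subgroups,
        "same_gene_combos": n_same_gene_combos,
    }


def empirical_pvalue(null_count: int, B: int, estimator: str = "plugin",
                     ) -> tuple[float, str]:
    """Exceedance fraction and its display string.

    ``plugin`` reproduces the count/B arithmetic (113/1000 -> "0.11",
    42/1000 -> "0.042", 0/1000 -> "p<0.001"); ``add_one`` uses the
    conservative (count+1)/(B+1) estimator.
    """
    if not 0 <= null_count <= B:
        raise ValueError("null_count must be in [0, B]")
    if estimator == "plugin":
        p = null_count / B
        display = f"p<{1.0 / B:.2g}" if null_count == 0 else f"{p:.2g}"
    elif estimator == "add_one":
        p = (null_count + 1) / (B + 1)
        display = f"{p:.2g}"
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return p, display


def run_permutation_study(matrix_or_index, config: PermutationConfig,
                          panel=None) -> PermutationResult:
    """Observed statistics plus B label permutations, seed-reproducible.

    Exceedance is one-sided (null value >= observed value counts against
    the observed feature) with thresholds fixed from the configuration.
    """
    if isinstance(matrix_or_index, GenotypeMatrix):
        index = CarrierIndex.from_matrix(matrix_or_index)
        if panel is None:
            panel = matrix_or_index.panel
    else:
        index = matrix_or_index
    n_total = index.n_individuals
    n_cases = config.n_cases if config.n_cases is not None else index.n_cases
    thresholds = config.thresholds

    observed = null_statistics_one_perm(index, index.case_mask, thresholds, panel)
    observed = {s: observed[s] for s in config.statistics}

    rng = np.random.default_rng(config.seed)
    null_counts = {s: 0 for s in config.statistics}
    log: list[dict[str, int]] = []
    t0 = time.perf_counter()
    for b in range(config.B):
        mask = permute_labels(n_total, n_cases, rng)
        stats = null_statistics_one_perm(index, mask, thresholds, panel)
        log.append(stats)
        for s in config.statistics:
            if stats[s] >= observed[s]:
                null_counts[s] += 1
        if b == 2 and config.max_seconds is not None and not config.force:
            projected = (time.perf_counter() - t0) / 3 * config.B
            if projected > config.max_seconds:
                raise RuntimeError(
                    f"projected permutation runtime {projected:.0f}s exceeds "
                    f"budget {config.max_seconds:.0f}s; pass force=True to "
                    "override"
                )

    pvalues, displays = {}, {}
    for s in config.statistics:
        p, disp = empirical_pvalue(null_counts[s], config.B, config.estimator)
        pvalues[s] = p
        displays[s] = disp
    return PermutationResult(
        observed=observed, null_counts=null_counts, B=config.B,
        seed=config.seed, pvalues=pvalues, displays=displays, log=log,
    )
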