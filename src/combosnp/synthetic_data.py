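"""Synthetic case-control genotype cohorts with optional planted structure.

Null cohorts draw each SNP's genotypes from Hardy-Weinberg proportions at a
minor allele frequency sampled uniformly above a floor, independently of
the case/control labels, with uniform missingness and an optional
copy-with-flip LD block model.  Planted cohorts deterministically insert a
case-exclusive *defining genotype* plus partner genotypes arranged so the
resulting patient-specific 3-combinations form a recoverable cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_data import MISSING, GenotypeMatrix, SnpRecord


@dataclass
class LdSpec:
    """Copy-with-flip LD blocks: within a block of ``block_len`` SNPs, each
    non-seed genotype copies the block seed's with probability ``copy_prob``
    and is drawn from its own HWE law otherwise."""

    block_len: int = 5
    copy_prob: float = 0.8


@dataclass
class CohortSpec:
    """Cohort dimensions and noise levels; defaults mirror a 607-case /
    1355-control panel of 803 SNPs with MAF >= 0.05 and a 99.6% per-SNP
    call rate (0.4% missingness)."""

    n_cases: int = 607
    n_controls: int = 1355
    n_snps: int = 803
    maf_min: float = 0.05
    maf_max: float = 0.5
    missing_rate: float = 0.004
    ld: LdSpec | None = None
    n_genes: int | None = None          # default: ~15 SNPs per gene
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1 or self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort dimensions must be >= 1")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0,1]")
        if not 0 < self.maf_min <= self.maf_max <= 0.5:
            raise ValueError("need 0 < maf_min <= maf_max <= 0.5")


@dataclass
class PlantSpec:
    """A planted cluster: a defining genotype made exclusive to the given
    cases, plus partner genotypes written onto (subsets of) those cases so
    that every 3-combination of {defining} u partners is patient-specific."""

    defining_snp: int
    defining_code: int = 2
    carrier_cases: tuple[int, ...] = ()        # row indices, must be cases
    partners: tuple[tuple[int, int], ...] = ()  # (snp, code) pairs
    partner_subsets: tuple[tuple[int, ...], ...] | None = None
    guarantee_exclusive: bool = True

    def __post_init__(self):
        if self.defining_code not in (0, 1, 2):
            raise ValueError("defining_code must be in {0,1,2}")
        if any(s == self.defining_snp for s, _ in self.partners):
            raise ValueError("partner SNPs must differ from the defining SNP")
        if self.partner_subsets is not None:
            if len(self.partner_subsets) != len(self.partners):
                raise ValueError("one subset per partner required")
            carriers = set(self.carrier_cases)
            for sub in self.partner_subsets:
                if not set(sub) <= carriers:
                    raise ValueError("partner subsets must be carrier cases")


def _make_panel(n_snps: int, n_genes: int) -> list[SnpRecord]:
    per_gene = -(-n_snps // n_genes)
    panel = []
    for j in range(n_snps):
        gene = f"GENE{j // per_gene + 1:03d}"
        panel.append(SnpRecord(f"rs{j + 1:06d}", gene, str(j // per_gene % 22 + 1),
                               (j + 1) * 1000, j))
    return panel


def generate_null_cohort(spec: CohortSpec) -> GenotypeMatrix:
    """HWE cohort with labels independent of genotypes (the permutation null)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    mafs = rng.uniform(spec.maf_min, spec.maf_max, size=spec.n_snps)
    calls = np.empty((n, spec.n_snps), dtype=np.int8)
    for j in range(spec.n_snps):
        calls[:, j] = rng.binomial(2, mafs[j], size=n)

    if spec.ld is not None:
        L = spec.ld.block_len
        for start in range(0, spec.n_snps, L):
            seed_col = calls[:, start].copy()
            for j in range(start + 1, min(start + L, spec.n_snps)):
                copy = rng.random(n) < spec.ld.copy_prob
                calls[copy, j] = seed_col[copy]

    if spec.missing_rate > 0:
        calls[rng.random(calls.shape) < spec.missing_rate] = MISSING

    labels = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls,
                      dtype=object)
    ids = np.array([f"case{i + 1:05d}" for i in range(spec.n_cases)]
                   + [f"ctrl{i + 1:05d}" for i in range(spec.n_controls)],
                   dtype=object)
    n_genes = spec.n_genes or max(1, round(spec.n_snps / 15))
    matrix = GenotypeMatrix(calls, labels, _make_panel(spec.n_snps, n_genes), ids)
    matrix.load_report = {"mafs": mafs}
    return matrix


def _nearest_other_code(code: int) -> int:
    return 1 if code != 1 else 0


def plant_cluster(matrix: GenotypeMatrix, plant: PlantSpec,
                  rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Write a planted cluster into a copy of ``matrix``.

    Post-conditions: exactly ``plant.carrier_cases`` carry the defining
    genotype (no control, no other case); each partner genotype is written
    onto its subset of carrier cases (default: all of them), so every
    3-combination containing the defining genotype is patient-specific and
    their union covers all carrier cases.
    """
    case_mask = matrix.case_mask
    carriers = np.asarray(plant.carrier_cases, dtype=int)
    if carriers.size == 0:
        raise ValueError("plant needs at least one carrier case")
    if not case_mask[carriers].all():
        raise ValueError("carrier_cases must all be cases")

    calls = matrix.calls.copy()
    s, g = plant.defining_snp, plant.defining_code
    holders = np.flatnonzero(calls[:, s] == g)
    conflict = np.setdiff1d(holders, carriers)
    if conflict.size and not plant.guarantee_exclusive:
        raise ValueError(
            f"{conflict.size} non-selected individuals carry the defining "
            "genotype and guarantee_exclusive is off"
        )
    calls[conflict, s] = _nearest_other_code(g)
    calls[carriers, s] = g

    subsets = plant.partner_subsets or tuple(
        tuple(carriers.tolist()) for _ in plant.partners
    )
    for (ps, pg), sub in zip(plant.partners, subsets):
        calls[np.asarray(sub, dtype=int), ps] = pg

    out = GenotypeMatrix(calls, matrix.labels.copy(), matrix.panel,
                         matrix.individual_ids.copy())
    out.load_report = dict(matrix.load_report)
    return out


def design_plants(matrix: GenotypeMatrix, n_plants: int, carriers_per_plant: int,
                  n_partners: int, rng: np.random.Generator,
                  ) -> list[PlantSpec]:
    """Choose plant positions on a generated cohort.

    Defining genotypes use the variant-homozygote code of the lowest-MAF
    SNPs (so making them case-exclusive barely perturbs the genotype
    distribution); partner genotypes are heterozygotes of common SNPs (so
    partner-only combinations keep control carriers and cannot produce
    spurious clusters).  Plants use disjoint case subsets and disjoint SNPs.
    """
    mafs = matrix.load_report.get("mafs")
    if mafs is None:
        col = matrix.calls
        mafs = np.array([
            min(m, 1 - m) for m in
            (np.where(col[:, j] != MISSING, col[:, j], 0).sum()
             / max(1, 2 * (col[:, j] != MISSING).sum())
             for j in range(matrix.n_snps))
        ])
    order = np.argsort(mafs)
    defining_snps = order[:n_plants]
    common_snps = order[::-1]

    case_indices = np.flatnonzero(matrix.case_mask)
    rng.shuffle(case_indices)
    needed = n_plants * carriers_per_plant
    if needed > case_indices.size:
        raise ValueError("not enough cases for the requested plants")

    plants = []
    used = set(defining_snps.tolist())
    partner_pool = [int(j) for j in common_snps if int(j) not in used]
    for p in range(n_plants):
        carriers = tuple(int(i) for i in
                         case_indices[p * carriers_per_plant:
                                      (p + 1) * carriers_per_plant])
        partners = tuple((partner_pool.pop(0), 1) for _ in range(n_partners))
        plants.append(PlantSpec(
            defining_snp=int(defining_snps[p]), defining_code=2,
            carrier_cases=carriers, partners=partners,
        ))
    return plants


def generate_planted_cohort(spec: CohortSpec, n_plants: int = 1,
                            carriers_per_plant: int = 12, n_partners: int = 8,
                            ) -> tuple[GenotypeMatrix, list[PlantSpec]]:
    """Null cohort plus ``n_plants`` disjoint planted clusters."""
    matrix = generate_null_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1)
    plants = design_plants(matrix, n_plants, carriers_per_plant, n_partners, rng)
    for plant in plants:
        matrix = plant_cluster(matrix, plant, rng)
    return matrix, plants
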