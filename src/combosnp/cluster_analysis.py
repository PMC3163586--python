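"""Genotype-defined clusters among patient-specific combinations.

A *cluster* is a single defining (SNP, genotype) pair that (a) appears in
"relatively many" patient-specific 3-combinations and (b) whose member
combinations together cover *every* case carrying the defining genotype.
Nested inside a cluster, *pair subgroups* collect the member combinations
that additionally share a second genotype across several distinct third
SNPs, and *same-gene subgroups* collect pair-subgroup combinations whose
third SNPs all lie in one gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _bitset
from .combination_engine import CarrierIndex, GenotypeCombo

ComboList = list[tuple[GenotypeCombo, np.ndarray]]


@dataclass
class Cluster:
    defining: tuple[int, int]                  # (SNP index, genotype code)
    member_combos: ComboList
    member_patient_words: np.ndarray           # union over member combos
    all_carrier_words: np.ndarray              # every case carrying defining
    n_patients: int
    n_combos: int
    rsid: str = ""

    def patient_indices(self, n_individuals: int) -> np.ndarray:
        return _bitset.indices(self.member_patient_words, n_individuals)


@dataclass
class PairSubgroup:
    defining: tuple[int, int]
    second: tuple[int, int]
    member_combos: ComboList
    third_snps: tuple[int, ...]
    member_patient_words: np.ndarray
    n_patients: int


@dataclass
class SameGeneSubgroup:
    parent: PairSubgroup
    gene: str
    member_combos: ComboList


def find_clusters(patient_specific_combos: ComboList, carrier_index: CarrierIndex,
                  min_combos: int = 30, min_patients: int = 1) -> list[Cluster]:
    """Detect defining genotypes satisfying the cluster condition.

    For every genotype present in >= min_combos of the patient-specific
    combinations, a cluster is emitted iff the union of patients over the
    combinations containing it equals the full set of cases carrying it,
    and that patient count is >= min_patients.  Sorted by patient count
    descending, ties broken by (rsid, genotype code).
    """
    if min_combos < 1 or min_patients < 1:
        raise ValueError("min_combos and min_patients must be >= 1")
    by_genotype: dict[tuple[int, int], list[int]] = {}
    for idx, (combo, _bits) in enumerate(patient_specific_combos):
        for pair in combo.pairs:
            by_genotype.setdefault(pair, []).append(idx)

    case_w = carrier_index.case_words
    clusters = []
    for genotype, members in by_genotype.items():
        if len(members) < min_combos:
            continue
        union = np.zeros_like(case_w)
        for idx in members:
            union |= patient_specific_combos[idx][1]
        all_carriers = carrier_index.genotype_words(*genotype) & case_w
        if not np.array_equal(union, all_carriers):
            continue
        n_pat = _bitset.popcount(union)
        if n_pat < min_patients:
            continue
        snp, code = genotype
        clusters.append(Cluster(
            defining=genotype,
            member_combos=[patient_specific_combos[i] for i in members],
            member_patient_words=union,
            all_carrier_words=all_carriers,
            n_patients=n_pat,
            n_combos=len(members),
            rsid=carrier_index.rsids[snp],
        ))
    clusters.sort(key=lambda c: (-c.n_patients, c.rsid, c.defining[1]))
    return clusters


def find_pair_subgroups(cluster: Cluster, min_third_snps: int = 4,
                        count_mode: str = "third_snps") -> list[PairSubgroup]:
    """Second-genotype subgroups nested in a cluster.

    Each member combination contributes its two non-defining genotypes as
    candidate second genotypes (the remaining one being the third).  A
    subgroup is emitted when the distinct-third-SNP count (or, with
    ``count_mode="combos"``, the raw member-combination count) reaches
    ``min_third_snps``.
    """
    if min_third_snps < 2:
        raise ValueError("min_third_snps must be >= 2")
    if count_mode not in ("third_snps", "combos"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    grouped: dict[tuple[int, int], ComboList] = {}
    for combo, bits in cluster.member_combos:
        others = [p for p in combo.pairs if p != cluster.defining]
        for second in others:
            grouped.setdefault(second, []).append((combo, bits))

    out = []
    for second, members in sorted(grouped.items()):
        third_snps = sorted({
            p[0] for combo, _ in members for p in combo.pairs
            if p != cluster.defining and p != second
        })
        size = len(third_snps) if count_mode == "third_snps" else len(members)
        if size < min_third_snps:
            continue
        union = np.zeros_like(cluster.member_patient_words)
        for _, bits in members:
            union |= bits
        out.append(PairSubgroup(
            defining=cluster.defining, second=second,
            member_combos=members, third_snps=tuple(third_snps),
            member_patient_words=union, n_patients=_bitset.popcount(union),
        ))
    out.sort(key=lambda s: (-len(s.member_combos), s.second))
    return out


def find_same_gene_subgroups(pair_subgroups: list[PairSubgroup],
                             panel) -> list[SameGeneSubgroup]:
    """Group each pair subgroup's combinations by the gene of the third SNP.

    ``panel`` is the SnpRecord list mapping SNP index to gene symbol; third
    SNPs without a gene annotation are excluded from grouping.  Groups of
    >= 2 combinations are emitted.
    """
    index_to_gene = {rec.index: rec.gene for rec in panel}
    out = []
    for sub in pair_subgroups:
        by_gene: dict[str, ComboList] = {}
        for combo, bits in sub.member_combos:
            third = next(p for p in combo.pairs
                         if p != sub.defining and p != sub.second)
            gene = index_to_gene.get(third[0], "")
            if not gene:
                continue
            by_gene.setdefault(gene, []).append((combo, bits))
        for gene, members in sorted(by_gene.items()):
            if len(members) >= 2:
                out.append(SameGeneSubgroup(parent=sub, gene=gene,
                                            member_combos=members))
    return out


def cluster_overlap(clusters: list[Cluster], n_individuals: int,
                    ) -> tuple[np.ndarray, int]:
    """Pairwise shared-patient counts and total distinct patients.

    Returns a symmetric matrix whose diagonal holds cluster sizes, plus the
    number of distinct patients appearing in any cluster.
    """
    if not clusters:
        raise ValueError("cluster_overlap requires >= 1 cluster")
    m = len(clusters)
    mat = np.zeros((m, m), dtype=int)
    union = np.zeros_like(clusters[0].member_patient_words)
    for i, ci in enumerate(clusters):
        union |= ci.member_patient_words
        for j, cj in enumerate(clusters):
            mat[i, j] = _bitset.popcount(
                ci.member_patient_words & cj.member_patient_words
            )
    return mat, _bitset.popcount(union)


def membership_counts(clusters: list[Cluster], n_individuals: int) -> np.ndarray:
    """histogram[c] = number of patients belonging to exactly c clusters."""
    counts = np.zeros(n_individuals, dtype=int)
    for cl in clusters:
        counts[cl.patient_indices(n_individuals)] += 1
    return np.bincount(counts, minlength=len(clusters) + 1)


def cluster_report(clusters: list[Cluster], carrier_index: CarrierIndex,
                   panel, min_third_snps: int = 4) -> str:
    """Human-readable markdown: one section per cluster, with its nested
    pair subgroups (defining | second | third SNPs) and same-gene subgroups."""
    lines = ["# Genotype-defined clusters", ""]
    if not clusters:
        lines.append("No clusters detected at the configured thresholds.")
        return "\n".join(lines) + "\n"
    gene_of = {rec.index: rec.gene for rec in panel}
    for n, cl in enumerate(clusters, start=1):
        snp, code = cl.defining
        gene = gene_of.get(snp, "")
        tag = f"{gene}_{cl.rsid}" if gene else cl.rsid
        lines += [
            f"## Cluster {n}: {tag} = {code}",
            "",
            f"- member 3-combinations: {cl.n_combos}",
            f"- patients (all carriers of the defining genotype): {cl.n_patients}",
            "",
        ]
        subs = find_pair_subgroups(cl, min_third_snps=min_third_snps)
        if subs:
            lines.append("| second genotype | third SNPs | combos | patients |")
            lines.append("|---|---|---|---|")
            for sub in subs:
                s2, c2 = sub.second
                second_tag = f"{gene_of.get(s2, '')}_{carrier_index.rsids[s2]}={c2}"
                thirds = ", ".join(carrier_index.rsids[t] for t in sub.third_snps)
                lines.append(f"| {second_tag} | {thirds} | "
                             f"{len(sub.member_combos)} | {sub.n_patients} |")
            lines.append("")
            same = find_same_gene_subgroups(subs, panel)
            for sg in same:
                s2, c2 = sg.parent.second
                lines.append(
                    f"- same-gene third-SNP subgroup under "
                    f"{carrier_index.rsids[s2]}={c2}: gene {sg.gene}, "
                    f"{len(sg.member_combos)} combos"
                )
            if same:
                lines.append("")
    mat, total = cluster_overlap(clusters, carrier_index.n_individuals)
    lines += [f"Total distinct patients across clusters: {total}", ""]
    return "\n".join(lines)
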