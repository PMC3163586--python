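"""Genotype matrices, SNP annotation, file I/O and cohort-level QC.

Genotype codes follow the usual minor-allele-count convention:
``0`` normal homozygote, ``1`` heterozygote, ``2`` variant (minor-allele)
homozygote; missing calls are stored as :data:`MISSING` (= -1).  Phenotype
labels are binary ``case`` / ``control``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

#: Internal sentinel for a missing genotype call (distinct from {0,1,2}).
MISSING: int = -1

#: Token written/accepted for a missing call in the TSV dialect.
NA_TOKEN = "NA"

_CASE_ALIASES = {"case", "patient", "affected", "1"}
_CONTROL_ALIASES = {"control", "ctrl", "unaffected", "healthy", "0"}


@dataclass(frozen=True)
class SnpRecord:
    """One SNP of the panel: identity, gene annotation, and matrix column."""

    rsid: str
    gene: str
    chromosome: str
    position: int
    index: int

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"negative position for {self.rsid}")


@dataclass
class GenotypeMatrix:
    """A case-control cohort: coded calls, labels, panel and individual ids.

    Attributes
    ----------
    calls
        ``(n_individuals, n_snps)`` int8 array with entries in
        ``{0, 1, 2, MISSING}``.
    labels
        Per-individual phenotype, each ``"case"`` or ``"control"``.
    panel
        Ordered :class:`SnpRecord` list; ``panel[j].index == j``.
    individual_ids
        Unique identifier per row.
    """

    calls: np.ndarray
    labels: np.ndarray
    panel: list[SnpRecord]
    individual_ids: np.ndarray
    load_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x SNPs)")
        n, m = self.calls.shape
        if len(self.panel) != m:
            raise ValueError(f"panel has {len(self.panel)} SNPs, matrix has {m} columns")
        for j, rec in enumerate(self.panel):
            if rec.index != j:
                raise ValueError(f"panel index mismatch at column {j} ({rec.rsid})")
        rsids = [r.rsid for r in self.panel]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in panel")
        if self.labels.shape != (n,) or self.individual_ids.shape != (n,):
            raise ValueError("labels / individual_ids length mismatch")
        ids, counts = np.unique(self.individual_ids.astype(str), return_counts=True)
        dup = ids[counts > 1]
        if dup.size:
            raise ValueError(f"duplicate individual id {dup[0]!r}")
        bad = set(self.labels) - {"case", "control"}
        if bad:
            raise ValueError(f"invalid labels {sorted(bad)}; expected case/control")
        if not ((self.labels == "case").any() and (self.labels == "control").any()):
            raise ValueError("labels must contain both cases and controls")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("calls contain codes outside {0,1,2,MISSING}")

    # -- convenience -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == "case"

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return self.n_individuals - self.n_cases

    def rsid_to_gene(self) -> dict[str, str]:
        return {r.rsid: r.gene for r in self.panel}

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to panel columns ``keep`` (bool or index array)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        panel = [
            SnpRecord(r.rsid, r.gene, r.chromosome, r.position, new_j)
            for new_j, r in enumerate(self.panel[j] for j in keep)
        ]
        return GenotypeMatrix(
            self.calls[:, keep], self.labels.copy(), panel, self.individual_ids.copy()
        )


@dataclass
class QcReport:
    """Per-SNP QC metrics plus the removal ledger of :func:`qc_filter`."""

    rsids: list[str]
    call_rate: np.ndarray
    hwe_p: np.ndarray
    maf: np.ndarray
    removed: dict[str, list[str]]  # rsid -> reason codes

    @property
    def retained(self) -> list[str]:
        return [r for r in self.rsids if r not in self.removed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "call_rate": self.call_rate,
                "hwe_p": self.hwe_p,
                "maf": self.maf,
                "removed": [";".join(self.removed.get(r, [])) for r in self.rsids],
            }
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _normalise_label(raw: str, row_id: str) -> str:
    token = str(raw).strip().lower()
    if token in _CASE_ALIASES:
        return "case"
    if token in _CONTROL_ALIASES:
        return "control"
    raise ValueError(f"individual {row_id!r}: unrecognised phenotype label {raw!r}")


def read_genotype_table(path, dialect: str = "tsv", annotation=None,
                        phenotypes=None, orient_minor: bool = True) -> GenotypeMatrix:
    """Load a cohort from a genotype TSV or a VCF.

    TSV dialect: header ``id<TAB>label<TAB>rsid1<TAB>...``; one row per
    individual; genotype tokens ``{0,1,2,NA}`` (anything unparseable becomes
    missing and is counted in ``matrix.load_report``).

    VCF dialect: genotype codes are derived as counts of the alternate
    allele from the GT field (``./.`` missing); phenotype labels must be
    supplied via ``phenotypes`` (path to an ``id<TAB>label`` TSV or a
    mapping).  With ``orient_minor`` (default) columns are flipped so code 2
    is the cohort minor-allele homozygote.

    ``annotation`` optionally points to an ``rsid gene chrom pos`` TSV used
    to build the panel; otherwise the panel carries placeholder annotation.
    """
    if dialect == "tsv":
        matrix = _read_tsv(path)
    elif dialect == "vcf":
        matrix = _read_vcf(path, phenotypes, orient_minor=orient_minor)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if annotation is not None:
        matrix = attach_annotation(matrix, read_annotation(annotation))
    return matrix


def _read_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError("genotype TSV needs id, label and >=1 SNP column")
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    labels = np.array(
        [_normalise_label(lab, ids[i]) for i, lab in enumerate(df.iloc[:, 1])],
        dtype=object,
    )
    rsids = list(df.columns[2:])
    raw = df.iloc[:, 2:].to_numpy(dtype=object)
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    n_unparseable = 0
    for code in (0, 1, 2):
        calls[raw == str(code)] = code
    recognised = np.isin(raw, ("0", "1", "2", NA_TOKEN, "")).sum()
    n_unparseable = raw.size - int(recognised)
    panel = [SnpRecord(rs, "", "", 0, j) for j, rs in enumerate(rsids)]
    matrix = GenotypeMatrix(calls, labels, panel, ids)
    matrix.load_report = {
        "n_unparseable": n_unparseable,
        "n_missing": int((calls == MISSING).sum()),
    }
    return matrix


def _read_vcf(path, phenotypes, orient_minor: bool = True) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if phenotypes is None:
        raise ValueError("VCF input requires phenotype labels (id\\tlabel TSV or mapping)")
    import os

    if isinstance(phenotypes, (str, bytes, os.PathLike)) or hasattr(phenotypes, "read"):
        ph = pd.read_csv(phenotypes, sep="\t", dtype=str, header=None,
                         names=["id", "label"], comment="#")
        pheno_map = dict(zip(ph["id"], ph["label"]))
    else:
        pheno_map = dict(phenotypes)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, panel = [], []
    for j, var in enumerate(vcf):
        gts = np.array([g[0] + g[1] if (g[0] >= 0 and g[1] >= 0) else MISSING
                        for g in var.genotypes], dtype=np.int8)
        cols.append(gts)
        rsid = var.ID or f"{var.CHROM}:{var.POS}"
        panel.append(SnpRecord(rsid, "", str(var.CHROM), int(var.POS), j))
    calls = np.column_stack(cols) if cols else np.zeros((len(samples), 0), np.int8)
    missing_pheno = [s for s in samples if s not in pheno_map]
    if missing_pheno:
        raise ValueError(f"no phenotype label for sample {missing_pheno[0]!r}")
    labels = np.array(
        [_normalise_label(pheno_map[s], s) for s in samples], dtype=object
    )
    matrix = GenotypeMatrix(calls, labels, panel, np.array(samples, dtype=object))
    if orient_minor:
        matrix = orient_to_minor(matrix)
    matrix.load_report = {"n_missing": int((matrix.calls == MISSING).sum())}
    return matrix


def orient_to_minor(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Flip columns so genotype code 2 is the cohort minor-allele homozygote."""
    calls = matrix.calls.copy()
    for j in range(matrix.n_snps):
        col = calls[:, j]
        obs = col[col != MISSING]
        if obs.size and obs.mean() > 1.0:  # alt allele frequency > 0.5
            col[col != MISSING] = 2 - col[col != MISSING]
    out = GenotypeMatrix(calls, matrix.labels.copy(), matrix.panel,
                         matrix.individual_ids.copy())
    out.load_report = dict(matrix.load_report)
    return out


def write_genotype_table(matrix: GenotypeMatrix, path) -> None:
    """Write the TSV dialect read back by :func:`read_genotype_table`."""
    tokens = matrix.calls.astype(object)
    tokens[matrix.calls == MISSING] = NA_TOKEN
    df = pd.DataFrame(tokens, columns=[r.rsid for r in matrix.panel])
    df.insert(0, "label", matrix.labels)
    df.insert(0, "id", matrix.individual_ids)
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "gene": str,
                                            "chrom": str, "pos": int})
    expected = ["rsid", "gene", "chrom", "pos"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"annotation TSV must have columns {expected}")
    return df


def write_annotation(matrix: GenotypeMatrix, path) -> None:
    pd.DataFrame(
        {
            "rsid": [r.rsid for r in matrix.panel],
            "gene": [r.gene for r in matrix.panel],
            "chrom": [r.chromosome for r in matrix.panel],
            "pos": [r.position for r in matrix.panel],
        }
    ).to_csv(path, sep="\t", index=False)


def attach_annotation(matrix: GenotypeMatrix, ann: pd.DataFrame) -> GenotypeMatrix:
    lookup = {row.rsid: row for row in ann.itertuples()}
    panel = []
    for rec in matrix.panel:
        row = lookup.get(rec.rsid)
        if row is None:
            panel.append(rec)
        else:
            panel.append(SnpRecord(rec.rsid, row.gene, str(row.chrom),
                                   int(row.pos), rec.index))
    out = GenotypeMatrix(matrix.calls, matrix.labels, panel, matrix.individual_ids)
    out.load_report = dict(matrix.load_report)
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p-value for one SNP's genotype counts.

    The exact method conditions on the observed allele counts and sums the
    probabilities of every heterozygote count (same parity, same allele
    totals) whose conditional probability does not exceed the observed
    one.  A monomorphic SNP returns p = 1 by convention.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("negative genotype counts")
    n = sum(counts)
    if n < 1:
        raise ValueError("empty genotype table")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0
    if method == "exact":
        return _hwe_exact(n, n_minor, n_het)
    if method == "chisq":
        return _hwe_chisq(n_hom_ref, n_het, n_hom_alt)
    raise ValueError(f"unknown method {method!r}")


def hwe_het_support(n: int, n_minor: int) -> range:
    """Admissible heterozygote counts given n individuals, n_minor minor alleles."""
    # h shares the parity of n_minor and cannot exceed it (n_minor <= n).
    return range(n_minor % 2, n_minor + 1, 2)


def _hwe_exact(n: int, n_minor: int, h_obs: int) -> float:
    # Un-normalised weights proportional to P(het = h | n, n_minor), built by
    # the multiplicative recurrence w(h+2)/w(h) = 4 nAA nBB / ((h+2)(h+1)).
    # Exact rational comparison of weights sidesteps floating-point ties in
    # the tail sum, so borderline tables are classified unambiguously.
    weights: dict[int, Fraction] = {}
    w = Fraction(1)
    for h in hwe_het_support(n, n_minor):
        weights[h] = w
        n_rare_hom = (n_minor - h) // 2
        n_common_hom = n - n_rare_hom - h
        w = w * Fraction(4 * n_rare_hom * n_common_hom, (h + 2) * (h + 1))
    w_obs = weights[h_obs]
    tail = sum(wt for wt in weights.values() if wt <= w_obs)
    return min(1.0, float(tail / sum(weights.values())))


def _hwe_chisq(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    from scipy.stats import chi2

    n = n_hom_ref + n_het + n_hom_alt
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum((observed - expected) ** 2 / expected)
    return float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def snp_qc_metrics(matrix: GenotypeMatrix, hwe_subset: str = "controls") -> QcReport:
    """Per-SNP call rate, HWE exact p (in ``hwe_subset``), and MAF."""
    if hwe_subset == "controls":
        hwe_rows = ~matrix.case_mask
    elif hwe_subset == "cases":
        hwe_rows = matrix.case_mask
    elif hwe_subset == "all":
        hwe_rows = np.ones(matrix.n_individuals, dtype=bool)
    else:
        raise ValueError(f"unknown hwe_subset {hwe_subset!r}")

    m = matrix.n_snps
    call_rate = np.empty(m)
    hwe_p = np.empty(m)
    maf = np.empty(m)
    for j in range(m):
        col = matrix.calls[:, j]
        obs = col != MISSING
        call_rate[j] = obs.mean() if col.size else 0.0
        present = col[obs]
        if present.size:
            alt = present.mean() / 2.0
            maf[j] = min(alt, 1.0 - alt)
        else:
            maf[j] = 0.0
        sub = col[hwe_rows & obs]
        hwe_p[j] = hwe_test(
            int((sub == 0).sum()), int((sub == 1).sum()), int((sub == 2).sum())
        ) if sub.size else 1.0
    return QcReport([r.rsid for r in matrix.panel], call_rate, hwe_p, maf, {})


def qc_filter(matrix: GenotypeMatrix, call_rate_min: float = 0.90,
              hwe_alpha: float = 0.001, maf_min: float = 0.05,
              hwe_subset: str = "controls",
              external_exclusions: dict[str, str] | None = None,
              ) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing call-rate, HWE or MAF thresholds.

    Thresholds default to call rate >= 0.90, HWE exact p >= 0.001 (computed
    in controls), MAF >= 0.05.  ``external_exclusions`` passes through
    exclusion reasons decided upstream (e.g. genotyping cluster-plot review),
    keyed by rsid.
    """
    for name, t in (("call_rate_min", call_rate_min), ("hwe_alpha", hwe_alpha),
                    ("maf_min", maf_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0,1]")
    report = snp_qc_metrics(matrix, hwe_subset=hwe_subset)
    removed: dict[str, list[str]] = {}
    for j, rsid in enumerate(report.rsids):
        reasons = []
        if report.call_rate[j] < call_rate_min:
            reasons.append("call_rate")
        if report.hwe_p[j] < hwe_alpha:
            reasons.append("hwe")
        if report.maf[j] < maf_min:
            reasons.append("maf")
        if external_exclusions and rsid in external_exclusions:
            reasons.append(external_exclusions[rsid])
        if reasons:
            removed[rsid] = reasons
    report.removed = removed
    keep = np.array([r.rsid not in removed for r in matrix.panel])
    if not keep.any():
        raise ValueError("QC removed every SNP; check thresholds and input")
    return matrix.subset_snps(keep), report
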