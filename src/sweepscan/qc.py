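"""Variant-level quality control: call rate, MAF and exact HWE filters.

Defaults follow common WGS practice for cattle panels: drop sites with a
genotype call rate below 95%, a minor allele frequency below 1%, or an
exact Hardy-Weinberg p-value below 1e-5.  The HWE test is the exact
conditional test (the PLINK default): conditioning on the observed minor
allele count, heterozygote counts are distributed as
``P(n_het) ∝ n! / (n_AA! n_Aa! n_aa!) * 2^n_het`` and the two-sided
p-value sums the probabilities of all outcomes no more likely than the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import gammaln

from .types import MISSING, GenotypeMatrix, HaplotypeMatrix


@dataclass
class QCThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-5


@dataclass
class QCReport:
    """Per-filter failure counts; each site is counted once under the
    precedence call rate -> MAF -> HWE (removal is the union regardless)."""
    n_input: int
    n_fail_callrate: int
    n_fail_maf: int
    n_fail_hwe: int
    n_pass: int

    def __post_init__(self):
        total = (self.n_pass + self.n_fail_callrate + self.n_fail_maf
                 + self.n_fail_hwe)
        if total != self.n_input:
            raise ValueError("QCReport counts do not sum to n_input")


@dataclass
class QCResult:
    genotypes: GenotypeMatrix
    haplotypes: Optional[HaplotypeMatrix]
    report: QCReport
    pass_mask: np.ndarray


def call_rate(genotypes: GenotypeMatrix, site: int) -> float:
    """Fraction of individuals with a non-missing call at ``site``."""
    col = genotypes.dosages[:, site]
    if len(col) == 0:
        raise ValueError("empty genotype column")
    return float((col != MISSING).mean())


def maf(genotypes: GenotypeMatrix, site: int) -> float:
    """Minor allele frequency among non-missing alleles at ``site``."""
    col = genotypes.dosages[:, site]
    ok = col != MISSING
    if not ok.any():
        raise ValueError(f"site {site}: no non-missing calls")
    p = col[ok].sum() / (2.0 * ok.sum())
    return float(min(p, 1.0 - p))


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic site.

    Enumerates every heterozygote count compatible with the observed
    sample size and minor-allele count, and sums the conditional
    probabilities that do not exceed the observed outcome's.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    # support: het counts with the parity of the minor count, h <= n_minor,
    # and enough majors to absorb the rest
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    keep = hom_major >= 0
    hs, hom_minor, hom_major = hs[keep], hom_minor[keep], hom_major[keep]
    logp = (hs * np.log(2.0) - gammaln(hom_minor + 1) - gammaln(hs + 1)
            - gammaln(hom_major + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hs == n_Aa][0]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _site_stats(genotypes: GenotypeMatrix) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = genotypes.dosages
    ok = d != MISSING
    n_ok = ok.sum(axis=0)
    cr = n_ok / d.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_ok > 0, np.where(ok, d, 0).sum(axis=0) / (2.0 * n_ok), np.nan)
    mafs = np.minimum(p, 1.0 - p)
    hwe = np.ones(d.shape[1])
    for j in range(d.shape[1]):
        if n_ok[j] == 0:
            hwe[j] = 1.0
            continue
        col = d[ok[:, j], j]
        hwe[j] = hwe_exact_p(int((col == 0).sum()), int((col == 1).sum()),
                             int((col == 2).sum()))
    return cr, mafs, hwe


def apply_qc(genotypes: GenotypeMatrix,
             haplotypes: Optional[HaplotypeMatrix] = None,
             thresholds: QCThresholds = QCThresholds()) -> QCResult:
    """Remove sites failing any filter from both matrices and report counts.

    Idempotent: re-applying the same thresholds to the output removes
    nothing further.
    """
    cr, mafs, hwe = _site_stats(genotypes)
    fail_cr = cr < thresholds.min_call_rate
    no_calls = np.isnan(mafs) & (thresholds.min_maf > 0)
    with np.errstate(invalid="ignore"):
        fail_maf = ~fail_cr & (no_calls | (mafs < thresholds.min_maf))
    fail_hwe = ~fail_cr & ~fail_maf & (hwe < thresholds.min_hwe_p)
    keep = ~(fail_cr | fail_maf | fail_hwe)
    report = QCReport(
        n_input=genotypes.n_sites,
        n_fail_callrate=int(fail_cr.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_hwe=int(fail_hwe.sum()),
        n_pass=int(keep.sum()),
    )
    gm = genotypes.subset_sites(keep)
    hm = haplotypes.subset_sites(keep) if haplotypes is not None else None
    return QCResult(gm, hm, report, keep)
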