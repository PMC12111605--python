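"""Core in-memory containers for phased and unphased genotype panels.

The package works chromosome-wise on ordered biallelic SNPs.  Phased data
live in a :class:`HaplotypeMatrix` (two rows per diploid individual, alleles
coded 0 = ancestral, 1 = derived); unphased analyses (QC, ROH, LD, GRM) use
a :class:`GenotypeMatrix` of derived-allele dosages with ``-1`` for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1


def _as_array(x, dtype=None):
    a = np.asarray(x)
    if dtype is not None:
        a = a.astype(dtype)
    return a


@dataclass
class VariantTable:
    """Ordered biallelic variants of one or more chromosomes.

    Positions are 1-based physical coordinates (bp) and must be strictly
    increasing within each chromosome; chromosomes must form contiguous
    blocks.  ``anc_is_ref`` records, per site, whether the REF allele is the
    one treated as ancestral (allele code 0).
    """

    chrom: np.ndarray
    pos: np.ndarray
    vid: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    anc_is_ref: np.ndarray

    def __post_init__(self):
        self.chrom = _as_array(self.chrom, object)
        self.pos = _as_array(self.pos, np.int64)
        self.vid = _as_array(self.vid, object)
        self.ref_allele = _as_array(self.ref_allele, object)
        self.alt_allele = _as_array(self.alt_allele, object)
        self.anc_is_ref = _as_array(self.anc_is_ref, bool)
        n = len(self.pos)
        for name in ("chrom", "vid", "ref_allele", "alt_allele", "anc_is_ref"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"VariantTable field {name!r} has wrong length")
        # contiguous chromosome blocks, strictly increasing positions within each
        seen = set()
        for c, sl in self.chrom_slices().items():
            if c in seen:
                raise ValueError(f"chromosome {c!r} not contiguous")
            seen.add(c)
            p = self.pos[sl]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c!r}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> slice of its contiguous block of sites."""
        out = {}
        if len(self.chrom) == 0:
            return out
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                out[self.chrom[start]] = slice(start, i)
                start = i
        return out

    def subset(self, mask) -> "VariantTable":
        mask = np.asarray(mask)
        return VariantTable(
            self.chrom[mask], self.pos[mask], self.vid[mask],
            self.ref_allele[mask], self.alt_allele[mask], self.anc_is_ref[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos, "vid": self.vid,
            "ref": self.ref_allele, "alt": self.alt_allele,
            "anc_is_ref": self.anc_is_ref,
        })


@dataclass
class HaplotypeMatrix:
    """Phased, complete haplotypes: ``alleles`` is 2n x m with entries in {0,1}.

    Rows 2i and 2i+1 are the two haplotypes of individual i.  0 is the
    ancestral allele, 1 the derived allele.
    """

    alleles: np.ndarray
    individual_ids: Sequence[str]
    variants: VariantTable

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.individual_ids = list(self.individual_ids)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("row count must be even (two haplotypes per individual)")
        if self.alleles.shape[0] != 2 * len(self.individual_ids):
            raise ValueError("row count does not match individual_ids")
        if self.alleles.shape[1] != self.variants.n_sites:
            raise ValueError("column count does not match variant table")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("haplotype alleles must be 0/1 (no missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def dosages(self) -> "GenotypeMatrix":
        d = (self.alleles[0::2].astype(np.int8) + self.alleles[1::2])
        return GenotypeMatrix(d, self.individual_ids, self.variants)

    def subset_sites(self, mask) -> "HaplotypeMatrix":
        mask = np.asarray(mask)
        return HaplotypeMatrix(self.alleles[:, mask], self.individual_ids,
                               self.variants.subset(mask))

    def subset_individuals(self, ids: Sequence[str]) -> "HaplotypeMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        rows = np.array([[2 * i, 2 * i + 1] for i in idx]).ravel()
        return HaplotypeMatrix(self.alleles[rows], list(ids), self.variants)

    def derived_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)


@dataclass
class GenotypeMatrix:
    """Per-individual derived-allele dosages: n x m, entries in {0,1,2,-1}."""

    dosages: np.ndarray
    individual_ids: Sequence[str]
    variants: VariantTable

    def __post_init__(self):
        self.dosages = np.ascontiguousarray(self.dosages, dtype=np.int8)
        self.individual_ids = list(self.individual_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        if self.dosages.shape[0] != len(self.individual_ids):
            raise ValueError("row count does not match individual_ids")
        if self.dosages.shape[1] != self.variants.n_sites:
            raise ValueError("column count does not match variant table")
        ok = np.isin(self.dosages, [MISSING, 0, 1, 2])
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(self.dosages[:, mask], self.individual_ids,
                              self.variants.subset(mask))

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        return GenotypeMatrix(self.dosages[idx], list(ids), self.variants)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval; coordinates stored half-open 0-based internally."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
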