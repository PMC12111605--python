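"""Readers and writers: phased VCF in, gene annotation in, TSV tracks out.

Only biallelic SNPs with complete, phased genotypes enter the
:class:`~sweepscan.types.HaplotypeMatrix`; anything else is dropped and
counted.  Alleles are recoded so that 0 is the ancestral allele under a
user-selected policy (REF, the INFO/AA tag, or the major allele).
Internal coordinates are half-open 0-based; everything user-facing is
1-based bp, matching VCF.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict, is_dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import GeneAnnotation, GenotypeMatrix, HaplotypeMatrix, VariantTable

log = logging.getLogger(__name__)

ANCESTRAL_POLICIES = ("ref_is_ancestral", "aa_info_tag", "major_is_ancestral")


@dataclass
class VcfReadReport:
    """Counts of sites dropped while reading a phased VCF."""
    n_records: int = 0
    n_multiallelic: int = 0
    n_not_snp: int = 0
    n_incomplete: int = 0       # missing or unphased GT
    n_no_ancestral: int = 0     # aa_info_tag policy, AA absent/unusable
    n_retained: int = 0


@dataclass
class PhasedData:
    haplotypes: HaplotypeMatrix
    genotypes: GenotypeMatrix
    report: VcfReadReport


def read_phased_vcf(path, ancestral_policy: str = "ref_is_ancestral",
                    skip_incomplete: bool = True) -> PhasedData:
    """Read a phased VCF into haplotype and dosage matrices.

    Parameters
    ----------
    ancestral_policy
        ``ref_is_ancestral`` codes REF as 0; ``aa_info_tag`` uses the
        INFO/AA field (sites whose AA matches neither allele are dropped);
        ``major_is_ancestral`` codes the more frequent allele as 0 (ties
        resolved toward REF).
    skip_incomplete
        If True (default), sites with any missing or unphased genotype are
        dropped and counted; if False such a site raises ``ValueError``.
    """
    if ancestral_policy not in ANCESTRAL_POLICIES:
        raise ValueError(f"unknown ancestral_policy {ancestral_policy!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    rep = VcfReadReport()
    cols: List[np.ndarray] = []
    meta = {k: [] for k in ("chrom", "pos", "vid", "ref", "alt", "anc_is_ref")}
    for v in vcf:
        rep.n_records += 1
        if len(v.ALT) != 1:
            rep.n_multiallelic += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            rep.n_not_snp += 1
            continue
        gts = v.genotypes  # [[a, b, phased], ...]
        col = np.empty(2 * n, dtype=np.int16)
        bad = False
        for i, g in enumerate(gts):
            a, b, phased = g[0], g[1], g[-1]
            if a < 0 or b < 0 or not phased:
                bad = True
                break
            col[2 * i] = a
            col[2 * i + 1] = b
        if bad:
            if not skip_incomplete:
                raise ValueError(
                    f"missing/unphased genotype at {v.CHROM}:{v.POS}")
            rep.n_incomplete += 1
            continue
        anc_is_ref = True
        if ancestral_policy == "aa_info_tag":
            aa = v.INFO.get("AA")
            aa = aa.upper() if isinstance(aa, str) else None
            if aa == v.REF.upper():
                anc_is_ref = True
            elif aa == v.ALT[0].upper():
                anc_is_ref = False
            else:
                rep.n_no_ancestral += 1
                continue
        elif ancestral_policy == "major_is_ancestral":
            anc_is_ref = col.mean() <= 0.5  # ALT freq > 0.5 flips
        if not anc_is_ref:
            col = 1 - col
        cols.append(col.astype(np.uint8))
        meta["chrom"].append(v.CHROM)
        meta["pos"].append(v.POS)
        meta["vid"].append(v.ID or f"{v.CHROM}:{v.POS}")
        meta["ref"].append(v.REF)
        meta["alt"].append(v.ALT[0])
        meta["anc_is_ref"].append(anc_is_ref)
        rep.n_retained += 1
    vcf.close()
    if rep.n_retained == 0:
        raise ValueError(f"no phased biallelic SNP records in {path}")
    if rep.n_multiallelic or rep.n_incomplete or rep.n_no_ancestral:
        log.info("read_phased_vcf(%s): dropped %d multiallelic, %d non-SNP, "
                 "%d incomplete, %d without ancestral state", path,
                 rep.n_multiallelic, rep.n_not_snp, rep.n_incomplete,
                 rep.n_no_ancestral)
    variants = VariantTable(meta["chrom"], meta["pos"], meta["vid"],
                            meta["ref"], meta["alt"], meta["anc_is_ref"])
    haps = HaplotypeMatrix(np.column_stack(cols), samples, variants)
    return PhasedData(haps, haps.dosages(), rep)


def write_phased_vcf(haps: HaplotypeMatrix, path) -> None:
    """Write a HaplotypeMatrix as a minimal phased VCF 4.2 text file.

    Allele codes are mapped back to REF/ALT using ``anc_is_ref``.
    """
    vt = haps.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, sl in vt.chrom_slices().items():
            length = int(vt.pos[sl][-1]) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in haps.individual_ids) + "\n")
        A = haps.alleles
        for j in range(vt.n_sites):
            col = A[:, j] if vt.anc_is_ref[j] else 1 - A[:, j]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}"
                            for i in range(haps.n_individuals))
            fh.write(f"{vt.chrom[j]}\t{vt.pos[j]}\t{vt.vid[j]}\t"
                     f"{vt.ref_allele[j]}\t{vt.alt_allele[j]}\t.\tPASS\t.\tGT\t"
                     f"{gts}\n")


def _read_bed_genes(path) -> List[GeneAnnotation]:
    genes, n_bad = [], 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                f = line.split()
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
            if start >= end:
                n_bad += 1
                log.warning("%s line %d: start >= end, record rejected", path, ln)
                continue
            genes.append(GeneAnnotation(name, name, chrom, start, end))
    if n_bad:
        log.info("read_gene_bed(%s): rejected %d malformed records", path, n_bad)
    return genes


def _read_gff3_genes(path) -> List[GeneAnnotation]:
    import gffutils

    with open(path) as fh:
        has_data = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_data:
        return []
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        sym = (feat.attributes.get("Name") or feat.attributes.get("gene_name")
               or [gid])[0]
        # GFF3 is 1-based closed -> half-open 0-based
        start, end = feat.start - 1, feat.end
        if start >= end:
            log.warning("%s: gene %s has start >= end, rejected", path, gid)
            continue
        genes.append(GeneAnnotation(gid, sym, feat.seqid, start, end))
    return genes


def read_gene_bed(path) -> List[GeneAnnotation]:
    """Read gene intervals from BED4+ (0-based half-open) or GFF3 (1-based
    closed, converted).  Format chosen by file extension."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".gff", ".gff3"):
        return _read_gff3_genes(path)
    return _read_bed_genes(path)


def _to_frame(track) -> pd.DataFrame:
    if isinstance(track, pd.DataFrame):
        return track.copy()
    if isinstance(track, (list, tuple)):
        if len(track) == 0:
            return pd.DataFrame()
        if is_dataclass(track[0]):
            return pd.DataFrame([asdict(t) for t in track])
        return pd.DataFrame(list(track))
    if is_dataclass(track):
        return pd.DataFrame([asdict(track)])
    raise TypeError(f"cannot serialize track of type {type(track)}")


def write_track(track, path, float_precision: int = 6) -> pd.DataFrame:
    """Write any result track as a TSV with header and deterministic order.

    Rows are sorted by (chrom, pos) or (chrom, start) when those columns
    exist.  Returns the frame actually written.
    """
    df = _to_frame(track)
    for keys in (["chrom", "pos"], ["chrom", "start"], ["individual_id"]):
        if all(k in df.columns for k in keys):
            df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
            break
    df.to_csv(path, sep="\t", index=False,
              float_format=f"%.{float_precision}f")
    return df


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
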