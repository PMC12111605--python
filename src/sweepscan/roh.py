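"""Runs of homozygosity: sliding-window calling, length spectra, F_ROH and
ROH islands.

The caller reproduces the PLINK ``--homozyg`` window mechanism.  For each
individual and chromosome, every window of ``window_snps`` consecutive SNPs
is classified homozygous if it holds at most ``window_het`` heterozygous
and ``window_missing`` missing calls.  Each SNP's hit proportion is the
fraction of windows covering it that are homozygous; maximal runs of SNPs
with proportion >= ``hit_proportion`` become candidate segments, which are
split at physical gaps larger than ``max_gap_bp`` and then kept only if
they satisfy the minimum SNP count, minimum length and SNP density rules.

F_ROH is the summed length of an individual's segments over the autosomal
length surveyed; a ROH island is a SNP covered by segments in an unusually
high share of individuals (top 0.1% of the coverage distribution by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, VariantTable

log = logging.getLogger(__name__)

# length classes in Mb, half-open (lower, upper]
LENGTH_CLASSES = [(0, 2), (2, 4), (4, 8), (8, 16), (16, np.inf)]


@dataclass
class ROHParams:
    window_snps: int = 50
    window_het: int = 1
    window_missing: int = 5
    hit_proportion: float = 0.05
    min_snps: int = 50
    min_length_bp: int = 300_000
    max_gap_bp: int = 1_000_000
    density_bp_per_snp: int = 50_000


@dataclass
class ROHSegment:
    individual_id: str
    chrom: str
    start: int      # 1-based bp of first SNP in the run
    end: int        # 1-based bp of last SNP in the run
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FrohValue:
    individual_id: str
    froh: float
    l_auto: int


@dataclass
class ROHIslandTrack:
    """Per-SNP percent of individuals covered by a called ROH, with the
    empirical top-fraction threshold; ties at the threshold are flagged."""
    table: pd.DataFrame   # chrom, pos, percent, significant
    threshold: float
    top_fraction: float


def _segments_one(dos: np.ndarray, pos: np.ndarray, chrom: str,
                  ind: str, p: ROHParams) -> List[ROHSegment]:
    m = len(dos)
    W = p.window_snps
    if m < W:
        return []
    het = (dos == 1).astype(np.int32)
    mis = (dos == MISSING).astype(np.int32)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    # window w spans SNPs [w, w+W-1], w = 0..m-W
    nwin = m - W + 1
    win_het = chet[W:] - chet[:-W]
    win_mis = cmis[W:] - cmis[:-W]
    hom_win = ((win_het <= p.window_het) & (win_mis <= p.window_missing)).astype(np.int32)
    chom = np.concatenate([[0], np.cumsum(hom_win)])
    j = np.arange(m)
    lo = np.maximum(0, j - W + 1)
    hi = np.minimum(j, nwin - 1)
    cover = hi - lo + 1
    hits = chom[hi + 1] - chom[lo]
    in_roh = hits / cover >= p.hit_proportion
    segs: List[ROHSegment] = []
    start = None
    for k in range(m + 1):
        inside = k < m and in_roh[k]
        if inside and start is None:
            start = k
        elif not inside and start is not None:
            segs.extend(_finish_run(dos, pos, chrom, ind, start, k - 1, p))
            start = None
    return segs


def _finish_run(dos, pos, chrom, ind, a, b, p: ROHParams) -> List[ROHSegment]:
    # split at gaps, then apply the segment-level filters
    out = []
    run_start = a
    for k in range(a + 1, b + 2):
        if k > b or pos[k] - pos[k - 1] > p.max_gap_bp:
            s, e = run_start, min(k - 1, b)
            n_snps = e - s + 1
            length = int(pos[e] - pos[s] + 1)
            if (n_snps >= p.min_snps and length >= p.min_length_bp
                    and length <= n_snps * p.density_bp_per_snp):
                out.append(ROHSegment(ind, chrom, int(pos[s]), int(pos[e]),
                                      n_snps, int((dos[s:e + 1] == 1).sum())))
            run_start = k
    return out


def call_roh(genotypes: GenotypeMatrix,
             params: ROHParams = ROHParams()) -> List[ROHSegment]:
    """Call ROH segments for every individual, chromosome-wise."""
    segs: List[ROHSegment] = []
    vt = genotypes.variants
    slices = vt.chrom_slices()
    for c, sl in slices.items():
        if sl.stop - sl.start < params.window_snps:
            log.info("chromosome %s has fewer SNPs (%d) than one window; "
                     "no ROH called", c, sl.stop - sl.start)
            continue
        pos = vt.pos[sl]
        for i, ind in enumerate(genotypes.individual_ids):
            dos = genotypes.dosages[i, sl]
            segs.extend(_segments_one(dos, pos, c, str(ind), params))
    return segs


def classify_spectrum(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    """Count and mean length per length class (Mb, half-open (lower, upper])."""
    rows = []
    lengths = np.array([s.length for s in segments], dtype=float)
    for lo, hi in LENGTH_CLASSES:
        sel = (lengths > lo * 1e6) & (lengths <= hi * 1e6)
        label = f">{lo} Mb" if np.isinf(hi) else f"{lo}-{hi} Mb"
        rows.append({
            "length_class": label,
            "count": int(sel.sum()),
            "mean_length_bp": float(lengths[sel].mean()) if sel.any() else np.nan,
        })
    return pd.DataFrame(rows)


def froh(segments: Sequence[ROHSegment], l_auto: int,
         individual_id: Optional[str] = None) -> FrohValue:
    """Genomic inbreeding of one individual: summed ROH length over the
    autosomal length."""
    if l_auto <= 0:
        raise ValueError("l_auto must be positive")
    total = sum(s.length for s in segments)
    if total > l_auto:
        raise ValueError("summed ROH length exceeds the autosomal length")
    ind = individual_id or (segments[0].individual_id if segments else "")
    return FrohValue(ind, total / l_auto, l_auto)


def autosome_length(variants: VariantTable) -> int:
    """Default F_ROH denominator: the SNP-covered span, summed over
    chromosomes."""
    return int(sum(int(variants.pos[sl][-1] - variants.pos[sl][0] + 1)
                   for _, sl in variants.chrom_slices().items()))


def froh_table(segments: Sequence[ROHSegment], individual_ids: Sequence[str],
               l_auto: int) -> pd.DataFrame:
    by_ind: Dict[str, List[ROHSegment]] = {str(i): [] for i in individual_ids}
    for s in segments:
        by_ind.setdefault(s.individual_id, []).append(s)
    rows = [{"individual_id": i, "froh": froh(by_ind[i], l_auto, i).froh,
             "l_auto": l_auto} for i in by_ind]
    return pd.DataFrame(rows)


def island_track(segments: Sequence[ROHSegment], variants: VariantTable,
                 n_individuals: int, top_fraction: float = 0.001) -> ROHIslandTrack:
    """Per-SNP percentage of individuals whose ROH covers it, with the
    empirical (1 - top_fraction) quantile as significance threshold."""
    m = variants.n_sites
    count = np.zeros(m, dtype=np.int64)
    slices = variants.chrom_slices()
    for s in segments:
        sl = slices.get(s.chrom)
        if sl is None:
            continue
        pos = variants.pos[sl]
        a = int(np.searchsorted(pos, s.start, side="left"))
        b = int(np.searchsorted(pos, s.end, side="right"))
        count[sl.start + a: sl.start + b] += 1
    percent = 100.0 * count / n_individuals
    threshold = float(np.quantile(percent, 1.0 - top_fraction)) if m else np.nan
    table = pd.DataFrame({"chrom": variants.chrom, "pos": variants.pos,
                          "percent": percent,
                          "significant": percent >= threshold})
    return ROHIslandTrack(table, threshold, top_fraction)
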