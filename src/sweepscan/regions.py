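"""Significance calling and candidate regions.

Each scan has its own significance rule: iHS uses a fixed -log10(p) > 4
cut, XP-EHH and Rsb control the false discovery rate at 5% with the
Benjamini-Hochberg step-up over the genome-wide two-sided p-values, and
the ROH island track takes the top 0.1% of the per-SNP coverage
distribution.  Significant SNPs are expanded into 1 Mb windows (±500 kb),
overlapping windows merged into candidate regions, and regions annotated
with every overlapping gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .roh import ROHIslandTrack
from .types import GeneAnnotation

log = logging.getLogger(__name__)

METHODS = ("ihs", "xpehh", "rsb", "roh")


@dataclass
class Region:
    """Candidate region; start/end are half-open 0-based bp, the peak SNP
    position 1-based."""
    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_score: float
    method: str

    def __post_init__(self):
        if not (self.start < self.end):
            raise ValueError("region start must be < end")
        if not (self.start < self.peak_pos <= self.end):
            raise ValueError("peak must lie inside the region")


@dataclass
class OverlapSummary:
    """Venn-style overlap counts of significant variants across methods."""
    venn: Dict[frozenset, int]          # exclusive counts per combination
    pairwise: Dict[Tuple[str, str], int]  # plain intersection sizes

    def to_frame(self) -> pd.DataFrame:
        rows = [{"methods": "+".join(sorted(k)), "exclusive_count": v}
                for k, v in sorted(self.venn.items(),
                                   key=lambda kv: (len(kv[0]), sorted(kv[0])))]
        return pd.DataFrame(rows)


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def significant_snps(track, method: str, *, ihs_neglogp: float = 4.0,
                     fdr_q: float = 0.05,
                     score_col: str = "score") -> pd.DataFrame:
    """Rows of the track that pass the method's significance rule.

    ``track`` is a scan DataFrame for ihs/xpehh/rsb, or a
    :class:`~sweepscan.roh.ROHIslandTrack` for roh.
    """
    if method == "ihs":
        sel = track["neglog10_p"] > ihs_neglogp
        return track.loc[sel.fillna(False)].copy()
    if method in ("xpehh", "rsb"):
        scored = track["neglog10_p"].notna()
        p = np.power(10.0, -track.loc[scored, "neglog10_p"].to_numpy())
        flags = bh_fdr(p, fdr_q)
        out = track.loc[scored].loc[flags].copy()
        return out
    if method == "roh":
        if isinstance(track, ROHIslandTrack):
            tab, thr = track.table, track.threshold
        else:
            raise TypeError("roh significance needs a ROHIslandTrack")
        out = tab.loc[tab["percent"] >= thr].copy()
        out["score"] = out["percent"]
        return out
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def merge_regions(snps: pd.DataFrame, window_bp: int = 1_000_000,
                  method: str = "", score_col: str = "score") -> List[Region]:
    """Union of per-SNP windows (±window_bp/2 by default, i.e. a total
    1 Mb window around each significant SNP) merged into disjoint regions.

    The peak of each region is its SNP with the largest |score|.
    """
    if len(snps) == 0:
        return []
    half = window_bp // 2
    regions: List[Region] = []
    for chrom, sub in snps.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        score = sub[score_col].to_numpy(dtype=float) if score_col in sub else \
            np.zeros(len(sub))
        starts = np.maximum(pos - 1 - half, 0)   # half-open 0-based
        ends = pos - 1 + half                    # exactly window_bp per SNP
        cur_a, cur_b = starts[0], ends[0]
        members = [0]
        for i in range(1, len(pos)):
            if starts[i] <= cur_b:
                cur_b = max(cur_b, ends[i])
                members.append(i)
            else:
                regions.append(_mk_region(str(chrom), cur_a, cur_b, pos,
                                          score, members, method))
                cur_a, cur_b, members = starts[i], ends[i], [i]
        regions.append(_mk_region(str(chrom), cur_a, cur_b, pos, score,
                                  members, method))
    return regions


def _mk_region(chrom, a, b, pos, score, members, method) -> Region:
    members = np.asarray(members)
    sc = score[members]
    k = members[int(np.nanargmax(np.abs(sc)))] if np.isfinite(sc).any() \
        else members[0]
    return Region(chrom, int(a), int(b), int(pos[k]), float(score[k]), method)


def annotate_genes(regions: Sequence[Region],
                   genes: Sequence[GeneAnnotation]) -> Dict[int, List[GeneAnnotation]]:
    """Map region index -> genes overlapping it (half-open intervals, any
    overlap counts), ordered by gene start."""
    if not genes:
        log.warning("no gene annotation loaded; every region maps to []")
    by_chrom: Dict[str, List[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gl in by_chrom.values():
        gl.sort(key=lambda g: g.start)
    out: Dict[int, List[GeneAnnotation]] = {}
    for i, r in enumerate(regions):
        out[i] = [g for g in by_chrom.get(r.chrom, [])
                  if g.start < r.end and g.end > r.start]
    return out


def annotation_table(regions: Sequence[Region],
                     mapping: Mapping[int, List[GeneAnnotation]]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(regions):
        genes = mapping.get(i, [])
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "peak_pos": r.peak_pos, "peak_score": r.peak_score,
            "method": r.method,
            "genes": ",".join(g.symbol for g in genes) if genes else ".",
        })
    return pd.DataFrame(rows)


def overlap_summary(snp_sets_by_method: Mapping[str, Set]) -> OverlapSummary:
    """Venn decomposition of significant-variant sets keyed by (chrom, pos).

    ``venn`` holds exclusive counts (variants in exactly that combination
    of methods); ``pairwise`` holds plain intersection sizes, so pairwise
    counts are always >= any higher-order exclusive count they contain.
    """
    names = list(snp_sets_by_method)
    if len(names) < 2:
        raise ValueError("need at least two methods to overlap")
    sets = {k: set(v) for k, v in snp_sets_by_method.items()}
    venn: Dict[frozenset, int] = {}
    universe = set().union(*sets.values())
    for v in universe:
        key = frozenset(k for k in names if v in sets[k])
        venn[key] = venn.get(key, 0) + 1
    pairwise = {(a, b): len(sets[a] & sets[b])
                for a, b in combinations(names, 2)}
    return OverlapSummary(venn, pairwise)


def track_to_keyset(snps: pd.DataFrame) -> Set[Tuple[str, int]]:
    return {(str(c), int(p)) for c, p in zip(snps["chrom"], snps["pos"])}
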