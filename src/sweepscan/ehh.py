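"""Extended haplotype homozygosity statistics: iHS, XP-EHH and Rsb.

Extended haplotype homozygosity (EHH) at a focal SNP *s* measures, among
the ``n_a`` haplotypes carrying a given core allele *a*, the probability
that two randomly drawn carriers are identical over every marker from *s*
out to a flanking marker *t*:

    EHH(s, t | a) = sum_k n_k (n_k - 1) / (n_a (n_a - 1)),

where the groups *k* partition the carriers by their allele sequence over
``[s..t]``.  The site-specific variant EHHS applies the same homozygosity
to *all* haplotypes at the site, the focal SNP's own alleles included, so
its value at the focal SNP is the focal-site haplotype homozygosity.

Decay curves are integrated over physical distance (bp) with the
trapezoidal rule to give iHH (per core allele) and iES (per population).
The three statistics are

    uniHS    = ln(iHH_ancestral / iHH_derived)           (within population)
    unXP-EHH = ln(iES_pop1 / iES_pop2)                   (between populations)
    unRsb    = inES_pop1 - inES_pop2,  inES = ln iES centered on its
               population-wide median                    (between populations)

each standardized to zero mean and unit variance (iHS within
derived-allele-frequency bins; XP-EHH and Rsb globally) and converted to a
two-sided Gaussian p-value reported as -log10 p.

Long sweeps of elevated homozygosity produce large |iHS| (ongoing sweeps)
or extreme XP-EHH/Rsb (sweeps complete in one population only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .types import HaplotypeMatrix

LN10 = np.log(10.0)


@dataclass
class EHHScanParams:
    """Knobs shared by every EHH-based scan.

    stop_threshold
        The outward scan stops once the curve falls below this value
        (0.05 by default); the final trapezoid is interpolated down to
        the threshold crossing.
    max_extension
        Maximum scan distance per side, bp (1 Mb by default).
    max_gap_bp
        Inter-marker distances larger than this contribute only this much
        width to the integral, so sparse stretches cannot dominate iHH;
        ``None`` disables the cap.
    """

    stop_threshold: float = 0.05
    max_extension: int = 1_000_000
    max_gap_bp: Optional[int] = 20_000
    min_carriers: int = 2
    include_focal_in_ehhs: bool = True


@dataclass
class EHHDecay:
    """One focal SNP's decay curve; ``left``/``right`` hold (pos, value)
    points ordered outward from the focal SNP."""

    focal_index: int
    focal_pos: int
    value_at_focal: float
    left: List[Tuple[int, float]]
    right: List[Tuple[int, float]]
    stop_threshold: float
    left_truncated: bool   # fell below stop_threshold
    right_truncated: bool
    edge: bool             # a side hit the chromosome end / max_extension first


def _decay_side(alleles: np.ndarray, positions: np.ndarray, focal: int,
                rows: np.ndarray, init_groups: np.ndarray, step: int,
                stop: float, max_ext: int) -> Tuple[List[Tuple[int, float]], bool]:
    """Scan one side, refining identity groups marker by marker."""
    na = len(rows)
    denom = na * (na - 1)
    groups = init_groups
    n_groups = int(groups.max()) + 1
    pts: List[Tuple[int, float]] = []
    m = len(positions)
    j = focal + step
    all_rows = len(rows) == alleles.shape[0]
    focal_pos = int(positions[focal])
    while 0 <= j < m and abs(int(positions[j]) - focal_pos) <= max_ext:
        # relabel (group, allele) pairs without sorting
        col = alleles[:, j] if all_rows else alleles[rows, j]
        codes = groups * 2 + col
        counts = np.bincount(codes, minlength=2 * n_groups)
        occupied = counts > 0
        remap = np.cumsum(occupied) - 1
        groups = remap[codes]
        n_groups = int(remap[-1]) + 1
        ehh = float((counts * (counts - 1)).sum() / denom)
        pts.append((int(positions[j]), ehh))
        if ehh < stop or ehh == 0.0:
            return pts, True
        j += step
    return pts, False


def ehh_at(haps: HaplotypeMatrix, focal: int, core_allele: int,
           params: EHHScanParams = EHHScanParams()) -> Optional[EHHDecay]:
    """EHH decay for one core allele at one focal SNP (both sides).

    Returns ``None`` when fewer than ``min_carriers`` haplotypes carry the
    core allele (the SNP is then flagged not-computable by the scans).
    """
    alleles = haps.alleles
    pos = haps.variants.pos
    rows = np.flatnonzero(alleles[:, focal] == core_allele)
    if len(rows) < max(2, params.min_carriers):
        return None
    init = np.zeros(len(rows), dtype=np.int64)
    left, lt = _decay_side(alleles, pos, focal, rows, init, -1,
                           params.stop_threshold, params.max_extension)
    right, rt = _decay_side(alleles, pos, focal, rows, init, +1,
                            params.stop_threshold, params.max_extension)
    return EHHDecay(focal, int(pos[focal]), 1.0, left, right,
                    params.stop_threshold, lt, rt, edge=not (lt and rt))


def ehhs_at(haps: HaplotypeMatrix, focal: int,
            params: EHHScanParams = EHHScanParams()) -> Optional[EHHDecay]:
    """Site-specific EHH decay over all haplotypes at one focal SNP.

    By default the focal SNP's own alleles take part in the grouping, so
    the curve starts at the focal-site homozygosity rather than at 1.
    """
    alleles = haps.alleles
    pos = haps.variants.pos
    n = haps.n_haplotypes
    if n < 2:
        return None
    rows = np.arange(n)
    if params.include_focal_in_ehhs:
        init = alleles[:, focal].astype(np.int64)
    else:
        init = np.zeros(n, dtype=np.int64)
    counts = np.bincount(init)
    at_focal = float((counts * (counts - 1)).sum() / (n * (n - 1)))
    if at_focal < params.stop_threshold or at_focal == 0.0:
        return EHHDecay(focal, int(pos[focal]), at_focal, [], [],
                        params.stop_threshold, True, True, edge=False)
    left, lt = _decay_side(alleles, pos, focal, rows, init, -1,
                           params.stop_threshold, params.max_extension)
    right, rt = _decay_side(alleles, pos, focal, rows, init, +1,
                            params.stop_threshold, params.max_extension)
    return EHHDecay(focal, int(pos[focal]), at_focal, left, right,
                    params.stop_threshold, lt, rt, edge=not (lt and rt))


def _side_area(focal_pos: int, value_at_focal: float,
               pts: Sequence[Tuple[int, float]], stop: float,
               max_gap_bp: Optional[int]) -> float:
    area = 0.0
    prev_pos, prev_val = focal_pos, value_at_focal
    for p, v in pts:
        w = abs(p - prev_pos)
        if max_gap_bp is not None:
            w = min(w, max_gap_bp)
        if stop > 0.0 and v < stop:
            # interpolate down to the threshold crossing
            frac = (prev_val - stop) / (prev_val - v)
            area += w * frac * (prev_val + stop) / 2.0
            return area
        area += w * (prev_val + v) / 2.0
        prev_pos, prev_val = p, v
    return area


def integrate_decay(decay: EHHDecay,
                    max_gap_bp: Optional[int] = 20_000) -> float:
    """Trapezoidal area under both sides of a decay curve, in bp.

    The curve is anchored at the focal SNP at its own starting value (1
    for EHH, the focal-site homozygosity for EHHS).  When a side was
    truncated by the stop threshold, its last trapezoid is cut at the
    linear interpolation of the threshold crossing.
    """
    return (_side_area(decay.focal_pos, decay.value_at_focal, decay.left,
                       decay.stop_threshold, max_gap_bp)
            + _side_area(decay.focal_pos, decay.value_at_focal, decay.right,
                         decay.stop_threshold, max_gap_bp))


def pvalue_transform(x, cap: float = 320.0):
    """Two-sided Gaussian tail probability of a standardized score, on the
    -log10 scale: ``-log10(1 - 2|Phi(x) - 0.5|)``.

    Computed through the log CDF for accuracy far in the tail; clamped at
    ``cap``.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        neglog = -(np.log(2.0) + log_ndtr(-np.abs(x))) / LN10
    out = np.minimum(neglog, cap)
    return float(out) if out.ndim == 0 else out


def standardize(values: np.ndarray, strata: np.ndarray) -> np.ndarray:
    """Zero-mean unit-sd (ddof 0) within each stratum; NaNs are ignored in
    the moments and propagate.  A zero-variance stratum yields zeros with a
    warning."""
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    out = np.full_like(values, np.nan)
    for s in np.unique(strata[~pd.isna(strata)]):
        idx = np.flatnonzero((strata == s) & ~np.isnan(values))
        if len(idx) == 0:
            continue
        mu = values[idx].mean()
        sd = values[idx].std(ddof=0)
        if sd == 0.0:
            warnings.warn(f"stratum {s!r} has zero variance; scores set to 0")
            out[idx] = 0.0
        else:
            out[idx] = (values[idx] - mu) / sd
    return out


def frequency_bins(daf: np.ndarray, width: float = 0.025,
                   min_count: int = 10) -> np.ndarray:
    """Assign derived-allele frequencies to standardization bins.

    Bins of the given width on [0, 1]; bins holding fewer than
    ``min_count`` scored SNPs are merged with the neighbouring occupied
    bin (the one with fewer members when both sides are occupied).
    Returns an integer label per SNP (-1 for NaN input).
    """
    daf = np.asarray(daf, dtype=float)
    nbins = int(np.ceil(1.0 / width))
    labels = np.where(np.isnan(daf), -1,
                      np.minimum((daf / width).astype(int), nbins - 1))
    occupied = sorted(int(b) for b in np.unique(labels) if b >= 0)
    if not occupied:
        return labels
    # iterative neighbour merging on the ordered list of occupied bins
    groups = [[b] for b in occupied]
    counts = [int((labels == b).sum()) for b in occupied]
    while len(groups) > 1 and min(counts) < min_count:
        i = int(np.argmin(counts))
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            j = i - 1 if counts[i - 1] <= counts[i + 1] else i + 1
        lo, hi = sorted((i, j))
        groups[lo] = groups[lo] + groups[hi]
        counts[lo] = counts[lo] + counts[hi]
        del groups[hi], counts[hi]
    remap = {}
    for gi, g in enumerate(groups):
        for b in g:
            remap[b] = gi
    return np.array([remap.get(int(b), -1) for b in labels])


def _finalize_track(variants, daf, raw, flags, strata) -> pd.DataFrame:
    score = standardize(raw, strata)
    with np.errstate(invalid="ignore"):
        neglogp = np.where(np.isnan(score), np.nan, pvalue_transform(score))
    return pd.DataFrame({
        "chrom": variants.chrom, "pos": variants.pos, "daf": daf,
        "raw": raw, "score": score, "neglog10_p": neglogp, "flag": flags,
    })


def scan_ihs(haps: HaplotypeMatrix,
             params: EHHScanParams = EHHScanParams(),
             bin_width: float = 0.025, min_bin_count: int = 10) -> pd.DataFrame:
    """Genome scan of the integrated haplotype score.

    For each SNP, EHH decay is integrated separately for the ancestral and
    derived core alleles; ``raw = ln(iHH_A / iHH_D)`` and the score is
    standardized within derived-allele-frequency bins.  SNPs where either
    allele has too few carriers or a zero integral are flagged and carry
    NaN scores.
    """
    from ._kernels import ihs_kernel

    m = haps.n_sites
    vt = haps.variants
    daf = haps.derived_freq().astype(float)
    raw = np.full(m, np.nan)
    flags = np.array(["ok"] * m, dtype=object)
    gap = float(params.max_gap_bp) if params.max_gap_bp is not None else np.inf
    for c, sl in vt.chrom_slices().items():
        ihh, status = ihs_kernel(
            haps.alleles[:, sl], vt.pos[sl].astype(np.float64),
            float(params.stop_threshold), float(params.max_extension),
            gap, int(params.min_carriers))
        with np.errstate(invalid="ignore", divide="ignore"):
            # log difference: exact sign flip when ancestral/derived swap
            raw[sl] = np.log(ihh[:, 0]) - np.log(ihh[:, 1])
        flags[sl] = np.array(["ok", "low_carriers", "zero_ihh", "edge"],
                             dtype=object)[status]
    strata = frequency_bins(np.where(np.isnan(raw), np.nan, daf),
                            bin_width, min_bin_count)
    return _finalize_track(vt, daf, raw, flags, strata)


def site_ies(haps: HaplotypeMatrix,
             params: EHHScanParams = EHHScanParams()) -> pd.DataFrame:
    """Per-SNP integrated EHHS (iES) for one population."""
    from ._kernels import ies_kernel

    m = haps.n_sites
    vt = haps.variants
    ies = np.full(m, np.nan)
    edge = np.zeros(m, dtype=bool)
    gap = float(params.max_gap_bp) if params.max_gap_bp is not None else np.inf
    for c, sl in vt.chrom_slices().items():
        vals, status = ies_kernel(
            haps.alleles[:, sl], vt.pos[sl].astype(np.float64),
            float(params.stop_threshold), float(params.max_extension),
            gap, params.include_focal_in_ehhs)
        ies[sl] = vals
        edge[sl] = status == 3
    return pd.DataFrame({"chrom": vt.chrom, "pos": vt.pos,
                         "ies": ies, "edge": edge})


def _check_same_sites(h1: HaplotypeMatrix, h2: HaplotypeMatrix):
    v1, v2 = h1.variants, h2.variants
    if v1.n_sites != v2.n_sites or not (np.all(v1.pos == v2.pos)
                                        and np.all(v1.chrom == v2.chrom)):
        raise ValueError("populations must share the same variant table")


def scan_xpehh(haps_pop1: HaplotypeMatrix, haps_pop2: HaplotypeMatrix,
               params: EHHScanParams = EHHScanParams(),
               ies1: Optional[pd.DataFrame] = None,
               ies2: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Cross-population EHH scan: ``raw = ln(iES_pop1 / iES_pop2)``,
    standardized globally.  Precomputed ``site_ies`` frames may be passed
    to avoid repeating the EHHS scans."""
    _check_same_sites(haps_pop1, haps_pop2)
    if ies1 is None:
        ies1 = site_ies(haps_pop1, params)
    if ies2 is None:
        ies2 = site_ies(haps_pop2, params)
    vt = haps_pop1.variants
    with np.errstate(invalid="ignore", divide="ignore"):
        # log difference rather than log of the ratio: exactly antisymmetric
        # under a population swap
        raw = np.log(ies1["ies"].to_numpy()) - np.log(ies2["ies"].to_numpy())
    flags = np.where(np.isnan(raw), "zero_ies",
                     np.where(ies1["edge"].to_numpy() | ies2["edge"].to_numpy(),
                              "edge", "ok")).astype(object)
    daf = (haps_pop1.derived_freq() * haps_pop1.n_haplotypes
           + haps_pop2.derived_freq() * haps_pop2.n_haplotypes) / (
               haps_pop1.n_haplotypes + haps_pop2.n_haplotypes)
    strata = np.zeros(vt.n_sites, dtype=int)
    return _finalize_track(vt, daf, raw, flags, strata)


def scan_rsb(haps_pop1: HaplotypeMatrix, haps_pop2: HaplotypeMatrix,
             params: EHHScanParams = EHHScanParams(),
             ies1: Optional[pd.DataFrame] = None,
             ies2: Optional[pd.DataFrame] = None,
             center: str = "median") -> pd.DataFrame:
    """Rsb scan: per-population log iES are centered on their population-wide
    median (``center="mean"`` switches the statistic) to give inES, and
    ``raw = inES_pop1 - inES_pop2``, standardized globally.

    The centering makes Rsb invariant to any constant rescaling of one
    population's iES values.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    _check_same_sites(haps_pop1, haps_pop2)
    if ies1 is None:
        ies1 = site_ies(haps_pop1, params)
    if ies2 is None:
        ies2 = site_ies(haps_pop2, params)
    vt = haps_pop1.variants
    stat = np.nanmedian if center == "median" else np.nanmean
    with np.errstate(invalid="ignore", divide="ignore"):
        ln1 = np.log(ies1["ies"].to_numpy())
        ln2 = np.log(ies2["ies"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ines1 = ln1 - stat(ln1)
        ines2 = ln2 - stat(ln2)
    raw = ines1 - ines2
    flags = np.where(np.isnan(raw), "zero_ies",
                     np.where(ies1["edge"].to_numpy() | ies2["edge"].to_numpy(),
                              "edge", "ok")).astype(object)
    daf = (haps_pop1.derived_freq() * haps_pop1.n_haplotypes
           + haps_pop2.derived_freq() * haps_pop2.n_haplotypes) / (
               haps_pop1.n_haplotypes + haps_pop2.n_haplotypes)
    strata = np.zeros(vt.n_sites, dtype=int)
    return _finalize_track(vt, daf, raw, flags, strata)
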