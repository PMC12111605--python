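"""Population structure and diversity: GRM, PCA, pairwise LD and the
LD-based effective-population-size trajectory.

The genomic relationship matrix follows the first VanRaden scaling:
``G = Z Z' / sum_j 2 p_j (1 - p_j)`` with ``Z`` the allele dosages
centered by twice the allele frequency.  Historical effective population
size is inferred from the decay of linkage disequilibrium with distance:

    Ne(t) = (1 / (4c)) * (1 / r2 - 1),      t = 1 / (2c),

where ``c`` is the SNP-pair distance in Morgan (physical bp are converted
at a fixed Mb-per-Morgan rate, 100 by default) and ``r2`` the mean squared
dosage correlation in the distance bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix

MB_PER_MORGAN = 100.0


@dataclass
class GRMatrix:
    values: np.ndarray
    individual_ids: Sequence[str]
    n_markers: int


@dataclass
class PCAResult:
    coords: np.ndarray            # n x k, eigenvector * sqrt(eigenvalue)
    percent_variance: np.ndarray  # k, eigenvalue / trace * 100
    individual_ids: Sequence[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords,
                          columns=[f"PC{i+1}" for i in range(self.coords.shape[1])])
        df.insert(0, "individual_id", list(self.individual_ids))
        return df


def _imputed_dosages(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Float dosage matrix with missing entries replaced by the site mean,
    plus per-site allele frequencies."""
    d = genotypes.dosages.astype(float)
    miss = genotypes.dosages == MISSING
    d[miss] = np.nan
    mean = np.nanmean(d, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    ii, jj = np.nonzero(miss)
    d[ii, jj] = mean[jj]
    return d, mean / 2.0


def grm(genotypes: GenotypeMatrix) -> GRMatrix:
    """VanRaden-1 genomic relationship matrix; monomorphic sites excluded,
    missing dosages mean-imputed per site."""
    d, p = _imputed_dosages(genotypes)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites for the GRM")
    d, p = d[:, poly], p[poly]
    z = d - 2.0 * p
    denom = float((2.0 * p * (1.0 - p)).sum())
    return GRMatrix(z @ z.T / denom, list(genotypes.individual_ids),
                    int(poly.sum()))


def pca(g: GRMatrix, k: int) -> PCAResult:
    """Top-k principal components of a GRM (eigenvectors scaled by the
    square root of their eigenvalue)."""
    G = np.asarray(g.values, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("GRM contains non-finite values")
    if k >= G.shape[0]:
        raise ValueError("k must be smaller than the number of individuals")
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:k]
    w_top, v_top = w[order], v[:, order]
    coords = v_top * np.sqrt(np.maximum(w_top, 0.0))
    pct = 100.0 * w_top / w.sum()
    return PCAResult(coords, pct, list(g.individual_ids))


def pairwise_r2(genotypes: GenotypeMatrix, max_dist_bp: int,
                mb_per_morgan: float = MB_PER_MORGAN,
                min_maf: float = 0.0) -> pd.DataFrame:
    """Squared dosage correlation for every SNP pair within ``max_dist_bp``
    on the same chromosome, tagged with the distance in Morgan.

    Zero-variance (and optionally low-MAF) sites are skipped.
    """
    d, p = _imputed_dosages(genotypes)
    vt = genotypes.variants
    out_c, out_r2 = [], []
    bp_per_morgan = mb_per_morgan * 1e6
    for c, sl in vt.chrom_slices().items():
        X = d[:, sl]
        pos = vt.pos[sl].astype(np.int64)
        sd = X.std(axis=0)
        pc = p[sl]
        usable = (sd > 0) & (np.minimum(pc, 1 - pc) >= min_maf)
        X = X[:, usable]
        pos = pos[usable]
        if X.shape[1] < 2:
            continue
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        Xs /= np.sqrt(X.shape[0])
        m = X.shape[1]
        for i in range(m - 1):
            j_hi = int(np.searchsorted(pos, pos[i] + max_dist_bp, side="right"))
            if j_hi <= i + 1:
                continue
            r = Xs[:, i] @ Xs[:, i + 1:j_hi]
            out_r2.append(r * r)
            out_c.append((pos[i + 1:j_hi] - pos[i]) / bp_per_morgan)
    if not out_c:
        return pd.DataFrame({"c": [], "r2": []})
    return pd.DataFrame({"c": np.concatenate(out_c),
                         "r2": np.concatenate(out_r2)})


def ne_point(mean_r2: float, c: float,
             adjust_n: Optional[int] = None) -> float:
    """Plug-in Ne at one genetic distance; ``adjust_n`` subtracts the
    1/n sampling contribution from the observed r2 first."""
    r2 = mean_r2 - (1.0 / adjust_n if adjust_n else 0.0)
    r2 = max(r2, 1e-12)
    return max((1.0 / (4.0 * c)) * (1.0 / r2 - 1.0), 0.0)


def ne_trajectory(r2_pairs: pd.DataFrame, bin_edges_morgan: np.ndarray,
                  min_pairs: int = 30,
                  adjust_n: Optional[int] = None) -> pd.DataFrame:
    """Bin SNP pairs by distance and convert mean r2 per bin into an Ne
    estimate at ``t = 1/(2c)`` generations ago (c at the bin midpoint).

    Bins with fewer than ``min_pairs`` pairs are skipped.
    """
    edges = np.asarray(bin_edges_morgan, dtype=float)
    c_vals = r2_pairs["c"].to_numpy()
    r2_vals = r2_pairs["r2"].to_numpy()
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (c_vals >= lo) & (c_vals < hi)
        n = int(sel.sum())
        if n < min_pairs:
            continue
        mid = (lo + hi) / 2.0
        mean_r2 = float(r2_vals[sel].mean())
        rows.append({
            "c": mid,
            "t": 1.0 / (2.0 * mid),
            "mean_r2": mean_r2,
            "ne": ne_point(mean_r2, mid, adjust_n),
            "n_pairs": n,
        })
    return pd.DataFrame(rows)
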