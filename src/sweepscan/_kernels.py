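"""Compiled inner loops for the chromosome-wide EHH scans.

These kernels mirror, operation for operation, the reference path
``ehh_at``/``ehhs_at`` + ``integrate_decay`` in :mod:`sweepscan.ehh`, so
the two routes agree to floating-point identity; a unit test enforces it.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _scan_side(alleles, positions, focal, rows, init_groups, n_init_groups,
               start_val, step, stop, max_ext, max_gap, denom):
    """Walk one side outward; returns (area, truncated)."""
    m = positions.shape[0]
    na = rows.shape[0]
    groups = init_groups.copy()
    n_groups = n_init_groups
    area = 0.0
    prev_val = start_val
    prev_pos = positions[focal]
    focal_pos = positions[focal]
    j = focal + step
    while 0 <= j < m and abs(positions[j] - focal_pos) <= max_ext:
        counts = np.zeros(2 * n_groups, dtype=np.int64)
        for r in range(na):
            code = groups[r] * 2 + alleles[rows[r], j]
            groups[r] = code
            counts[code] += 1
        # relabel occupied codes and accumulate homozygosity
        remap = np.empty(2 * n_groups, dtype=np.int64)
        nxt = 0
        acc = 0
        for c in range(2 * n_groups):
            if counts[c] > 0:
                remap[c] = nxt
                nxt += 1
                acc += counts[c] * (counts[c] - 1)
        for r in range(na):
            groups[r] = remap[groups[r]]
        n_groups = nxt
        ehh = acc / denom
        # trapezoid, mirroring integrate_decay
        w = abs(positions[j] - prev_pos)
        if w > max_gap:
            w = max_gap
        if stop > 0.0 and ehh < stop:
            frac = (prev_val - stop) / (prev_val - ehh)
            area += w * frac * (prev_val + stop) / 2.0
            return area, True
        area += w * (prev_val + ehh) / 2.0
        if ehh < stop or ehh == 0.0:
            return area, True
        prev_val = ehh
        prev_pos = positions[j]
        j += step
    return area, False


@njit(cache=True)
def ihs_kernel(alleles, positions, stop, max_ext, max_gap, min_carriers):
    """Per-SNP iHH_A (col 0), iHH_D (col 1) and status codes.

    status: 0 ok, 1 too few carriers, 2 zero integral, 3 edge-truncated.
    """
    n, m = alleles.shape
    ihh = np.full((m, 2), np.nan)
    status = np.zeros(m, dtype=np.int64)
    mc = min_carriers if min_carriers > 2 else 2
    for focal in range(m):
        edge = False
        ok = True
        for allele in range(2):
            na = 0
            for r in range(n):
                if alleles[r, focal] == allele:
                    na += 1
            if na < mc:
                status[focal] = 1
                ok = False
                break
            rows = np.empty(na, dtype=np.int64)
            k = 0
            for r in range(n):
                if alleles[r, focal] == allele:
                    rows[k] = r
                    k += 1
            init = np.zeros(na, dtype=np.int64)
            denom = float(na * (na - 1))
            a_l, t_l = _scan_side(alleles, positions, focal, rows, init, 1,
                                  1.0, -1, stop, max_ext, max_gap, denom)
            a_r, t_r = _scan_side(alleles, positions, focal, rows, init, 1,
                                  1.0, 1, stop, max_ext, max_gap, denom)
            ihh[focal, allele] = a_l + a_r
            if not (t_l and t_r):
                edge = True
        if not ok:
            ihh[focal, 0] = np.nan
            ihh[focal, 1] = np.nan
            continue
        if ihh[focal, 0] == 0.0 or ihh[focal, 1] == 0.0:
            status[focal] = 2
            ihh[focal, 0] = np.nan
            ihh[focal, 1] = np.nan
        elif edge:
            status[focal] = 3
    return ihh, status


@njit(cache=True)
def ies_kernel(alleles, positions, stop, max_ext, max_gap, include_focal):
    """Per-SNP integrated EHHS and status codes (0 ok, 2 zero, 3 edge)."""
    n, m = alleles.shape
    ies = np.full(m, np.nan)
    status = np.zeros(m, dtype=np.int64)
    rows = np.arange(n)
    denom = float(n * (n - 1))
    for focal in range(m):
        if include_focal:
            init = alleles[:, focal].astype(np.int64)
            n_init = 2
            c0 = 0
            for r in range(n):
                if alleles[r, focal] == 0:
                    c0 += 1
            c1 = n - c0
            at_focal = (c0 * (c0 - 1) + c1 * (c1 - 1)) / denom
        else:
            init = np.zeros(n, dtype=np.int64)
            n_init = 1
            at_focal = 1.0
        if at_focal < stop or at_focal == 0.0:
            status[focal] = 2
            continue
        a_l, t_l = _scan_side(alleles, positions, focal, rows, init, n_init,
                              at_focal, -1, stop, max_ext, max_gap, denom)
        a_r, t_r = _scan_side(alleles, positions, focal, rows, init, n_init,
                              at_focal, 1, stop, max_ext, max_gap, denom)
        total = a_l + a_r
        if total == 0.0:
            status[focal] = 2
        else:
            ies[focal] = total
            if not (t_l and t_r):
                status[focal] = 3
    return ies, status
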