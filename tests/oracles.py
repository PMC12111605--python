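"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions, with deliberately naive
data structures (tuples, Counters, Fractions), sharing no code with the
package implementation.
"""

from collections import Counter
from fractions import Fraction
from math import factorial

import numpy as np


# ---------------------------------------------------------------- EHH / iHS

def _trap_area(points, start_pos, start_val, stop):
    area = 0.0
    pp, pv = start_pos, start_val
    for p, v in points:
        w = abs(p - pp)
        if stop > 0.0 and v < stop:
            frac = (pv - stop) / (pv - v)
            area += w * frac * (pv + stop) / 2.0
            return area
        area += w * (pv + v) / 2.0
        pp, pv = p, v
    return area


def _group_homozygosity(haps, lo, hi):
    groups = Counter(h[lo:hi + 1] for h in haps)
    n = len(haps)
    return sum(c * (c - 1) for c in groups.values()) / (n * (n - 1))


def brute_ehh_area(hap_tuples, positions, focal, allele, stop, max_ext):
    """Integrated EHH for one core allele, or None if < 2 carriers."""
    carriers = [h for h in hap_tuples if h[focal] == allele]
    if len(carriers) < 2:
        return None

    def one_side(indices):
        pts = []
        for t in indices:
            if abs(positions[t] - positions[focal]) > max_ext:
                break
            lo, hi = min(focal, t), max(focal, t)
            ehh = _group_homozygosity(carriers, lo, hi)
            pts.append((positions[t], ehh))
            if ehh < stop or ehh == 0.0:
                break
        return pts

    left = one_side(range(focal - 1, -1, -1))
    right = one_side(range(focal + 1, len(positions)))
    return (_trap_area(left, positions[focal], 1.0, stop)
            + _trap_area(right, positions[focal], 1.0, stop))


def brute_unihs(hap_tuples, positions, stop=0.05, max_ext=10**12):
    """Per-site ln(iHH_A / iHH_D); NaN where not computable."""
    m = len(positions)
    out = np.full(m, np.nan)
    for s in range(m):
        a = brute_ehh_area(hap_tuples, positions, s, 0, stop, max_ext)
        d = brute_ehh_area(hap_tuples, positions, s, 1, stop, max_ext)
        if a is None or d is None or a == 0.0 or d == 0.0:
            continue
        out[s] = np.log(a / d)
    return out


def brute_ies(hap_tuples, positions, stop=0.05, max_ext=10**12):
    """Per-site integrated EHHS over all haplotypes (focal included)."""
    m = len(positions)
    n = len(hap_tuples)
    out = np.full(m, np.nan)
    for s in range(m):
        at_focal = _group_homozygosity(hap_tuples, s, s)
        if at_focal < stop or at_focal == 0.0:
            continue

        def one_side(indices):
            pts = []
            for t in indices:
                if abs(positions[t] - positions[s]) > max_ext:
                    break
                lo, hi = min(s, t), max(s, t)
                ehhs = _group_homozygosity(hap_tuples, lo, hi)
                pts.append((positions[t], ehhs))
                if ehhs < stop or ehhs == 0.0:
                    break
            return pts

        area = (_trap_area(one_side(range(s - 1, -1, -1)), positions[s],
                           at_focal, stop)
                + _trap_area(one_side(range(s + 1, m)), positions[s],
                             at_focal, stop))
        if area > 0.0:
            out[s] = area
    return out


def brute_unxpehh(ies1, ies2):
    return np.log(ies1 / ies2)


def brute_unrsb(ies1, ies2):
    ln1, ln2 = np.log(ies1), np.log(ies2)
    return (ln1 - np.nanmedian(ln1)) - (ln2 - np.nanmedian(ln2))


def hap_tuples(haplotype_matrix):
    return [tuple(int(x) for x in row) for row in haplotype_matrix.alleles]


# ------------------------------------------------------------------- ROH

def naive_roh(dosages, positions, window, window_het, window_missing,
              hit_proportion, min_snps, min_length, max_gap, density):
    """Direct restatement of the sliding-window ROH rules for one
    individual and chromosome; returns (start, end, n_snps) triples."""
    m = len(dosages)
    if m < window:
        return []
    hom = []
    for w in range(m - window + 1):
        win = dosages[w:w + window]
        het = sum(1 for x in win if x == 1)
        mis = sum(1 for x in win if x == -1)
        hom.append(het <= window_het and mis <= window_missing)
    in_run = []
    for j in range(m):
        covering = [w for w in range(len(hom)) if w <= j < w + window]
        hits = sum(1 for w in covering if hom[w])
        in_run.append(hits / len(covering) >= hit_proportion)
    segs = []
    i = 0
    while i < m:
        if not in_run[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and in_run[j + 1]:
            j += 1
        k = i
        for t in range(i + 1, j + 2):
            if t > j or positions[t] - positions[t - 1] > max_gap:
                e = min(t - 1, j)
                n = e - k + 1
                length = positions[e] - positions[k] + 1
                if (n >= min_snps and length >= min_length
                        and length <= n * density):
                    segs.append((int(positions[k]), int(positions[e]), n))
                k = t
        i = j + 1
    return segs


# ------------------------------------------------------------------- HWE

def hwe_enum_p(n_AA, n_Aa, n_aa):
    """Exact two-sided HWE p-value by full enumeration with rational
    arithmetic."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa

    def weight(h):
        if h > nA or (nA - h) % 2:
            return None
        homA = (nA - h) // 2
        homa = n - h - homA
        if homA < 0 or homa < 0:
            return None
        return (Fraction(factorial(n),
                         factorial(homA) * factorial(h) * factorial(homa))
                * 2 ** h)

    weights = {h: w for h in range(n + 1)
               if (w := weight(h)) is not None}
    total = sum(weights.values())
    obs = weights[n_Aa]
    p = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(p, total))


# -------------------------------------------------------------------- BH

def bh_brute(pvalues, q):
    """Textbook step-up, checking every rank."""
    m = len(pvalues)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = sorted(range(m), key=lambda i: pvalues[i])
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if pvalues[i] <= q * rank / m:
            kmax = rank
    flags = np.zeros(m, dtype=bool)
    if kmax:
        thresh = pvalues[order[kmax - 1]]
        flags[:] = [p <= thresh for p in pvalues]
    return flags
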