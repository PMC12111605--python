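"""EHH decay curves, integration, standardization and the three scans."""

import numpy as np
import pandas as pd
import pytest

from sweepscan import (EHHScanParams, ehh_at, ehhs_at, frequency_bins,
                       integrate_decay, neutral_fixture, pvalue_transform,
                       scan_ihs, scan_rsb, scan_xpehh, site_ies, standardize)
from conftest import make_haps
from oracles import brute_ies, brute_unihs, brute_unrsb, brute_unxpehh, hap_tuples

FREE = EHHScanParams(stop_threshold=0.05, max_extension=10**12,
                     max_gap_bp=None)


def test_ehh_group_example():
    # 4 carriers split (2,2) at the next marker: EHH = 1/3
    hm = make_haps([[1, 0], [1, 0], [1, 1], [1, 1]])
    dec = ehh_at(hm, 0, 1, FREE)
    assert dec.value_at_focal == 1.0
    assert dec.right[0] == (2000, pytest.approx(1 / 3))


def test_ehh_all_distinct_stops_scan():
    hm = make_haps([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]])
    dec = ehh_at(hm, 0, 1, FREE)
    # (2,2) groups at marker 2, all singletons at marker 3 -> 0, stop
    assert [v for _, v in dec.right] == pytest.approx([1 / 3, 0.0])
    assert dec.right_truncated


def test_ehh_low_carriers_flagged_not_raised():
    hm = make_haps([[1, 0], [0, 0], [0, 1], [0, 1]])
    assert ehh_at(hm, 0, 1, FREE) is None


def test_ehhs_includes_focal_alleles():
    hm = make_haps([[0, 0], [0, 0], [1, 1], [1, 1]])
    dec = ehhs_at(hm, 0, FREE)
    assert dec.value_at_focal == pytest.approx(1 / 3)
    assert dec.right[0] == (2000, pytest.approx(1 / 3))
    mono = make_haps(np.zeros((6, 4)))
    d2 = ehhs_at(mono, 1, FREE)
    assert d2.value_at_focal == 1.0
    assert all(v == 1.0 for _, v in d2.left + d2.right)


def test_integrate_decay_worked_values():
    from sweepscan.ehh import EHHDecay
    dec = EHHDecay(0, 0, 1.0, [], [(1000, 0.5), (2000, 0.0)], 0.0,
                   True, True, False)
    assert integrate_decay(dec, None) == pytest.approx(1000.0)  # 750 + 250
    flat = EHHDecay(0, 0, 1.0, [], [(10_000, 1.0)], 0.0, False, False, True)
    assert integrate_decay(flat, None) == pytest.approx(10_000.0)
    single = EHHDecay(0, 0, 1.0, [], [], 0.05, False, False, True)
    assert integrate_decay(single, None) == 0.0


def test_integrate_interpolates_to_threshold_crossing():
    from sweepscan.ehh import EHHDecay
    dec = EHHDecay(0, 0, 1.0, [], [(1000, 0.5), (2000, 0.01)], 0.05,
                   True, True, False)
    # crossing at frac (0.5-0.05)/(0.5-0.01) of the second interval
    frac = 0.45 / 0.49
    assert integrate_decay(dec, None) == pytest.approx(
        750.0 + 1000 * frac * (0.5 + 0.05) / 2)


def test_integrate_gap_cap_limits_interval_width():
    from sweepscan.ehh import EHHDecay
    dec = EHHDecay(0, 0, 1.0, [], [(100_000, 0.5)], 0.0, True, True, False)
    assert integrate_decay(dec, 20_000) == pytest.approx(20_000 * 0.75)


def test_pvalue_transform_values():
    assert pvalue_transform(0.0) == pytest.approx(0.0, abs=1e-12)
    assert pvalue_transform(1.959964) == pytest.approx(1.3010, abs=2e-4)
    x = np.array([-3.3, -0.2, 0.0, 1.1, 4.2])
    np.testing.assert_allclose(pvalue_transform(x), pvalue_transform(-x))
    assert pvalue_transform(400.0) == 320.0  # clamp


def test_standardize_worked_values():
    out = standardize(np.array([1.0, 2.0, 3.0]), np.zeros(3))
    np.testing.assert_allclose(out, [-1.224745, 0.0, 1.224745], atol=1e-6)
    with pytest.warns(UserWarning, match="zero variance"):
        out = standardize(np.array([2.0, 2.0]), np.zeros(2))
    np.testing.assert_array_equal(out, [0.0, 0.0])


def test_standardize_per_stratum_moments(rng):
    vals = rng.normal(size=200) * 3 + 1
    strata = rng.integers(0, 3, size=200)
    out = standardize(vals, strata)
    for s in range(3):
        sel = strata == s
        assert out[sel].mean() == pytest.approx(0.0, abs=1e-12)
        assert out[sel].std() == pytest.approx(1.0, abs=1e-12)


def test_frequency_bins_merges_small_bins():
    daf = np.array([0.01, 0.012, 0.3] + [0.52] * 12)
    bins = frequency_bins(daf, width=0.025, min_count=10)
    # the two tiny low-frequency bins end up merged with a neighbour
    assert len(np.unique(bins)) <= 2
    counts = np.bincount(bins)
    assert counts.min() >= 3  # no unmergeable leftovers beyond one group


def test_ihs_sign_flips_when_polarity_swaps(rng):
    hm = neutral_fixture(12, 30, seed=9, n_founders=6)
    flipped = make_haps(1 - hm.alleles, hm.variants.pos.copy())
    a = scan_ihs(hm, FREE)
    b = scan_ihs(flipped, FREE)
    ok = a["raw"].notna() & b["raw"].notna()
    assert ok.any()
    np.testing.assert_allclose(a.loc[ok, "raw"], -b.loc[ok, "raw"],
                               atol=1e-12)


def test_identical_curves_give_zero_raw():
    # perfectly balanced panel: ancestral and derived decay identically
    hm = make_haps([[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]])
    tr = scan_ihs(hm, FREE)
    assert tr["raw"][1] == pytest.approx(0.0, abs=1e-12)


def test_xpehh_zero_for_identical_populations():
    hm = neutral_fixture(10, 25, seed=3, n_founders=5)
    tr = scan_xpehh(hm, hm, FREE)
    ok = tr["raw"].notna()
    np.testing.assert_allclose(tr.loc[ok, "raw"], 0.0, atol=1e-12)


def test_xpehh_antisymmetric_under_population_swap():
    h1 = neutral_fixture(10, 25, seed=4, n_founders=5)
    h2 = neutral_fixture(10, 25, seed=5, n_founders=5)
    h2 = make_haps(h2.alleles, h1.variants.pos.copy())
    a = scan_xpehh(h1, h2, FREE)
    b = scan_xpehh(h2, h1, FREE)
    ok = a["raw"].notna()
    np.testing.assert_allclose(a.loc[ok, "raw"].to_numpy(),
                               -b.loc[ok, "raw"].to_numpy(), atol=0)


def test_rsb_invariant_to_population_rescaling():
    h1 = neutral_fixture(10, 25, seed=6, n_founders=5)
    h2 = neutral_fixture(10, 25, seed=7, n_founders=5)
    h2 = make_haps(h2.alleles, h1.variants.pos.copy())
    i1, i2 = site_ies(h1, FREE), site_ies(h2, FREE)
    base = scan_rsb(h1, h2, FREE, ies1=i1, ies2=i2)
    scaled = i2.copy()
    scaled["ies"] = scaled["ies"] * 7.3
    res = scan_rsb(h1, h2, FREE, ies1=i1, ies2=scaled)
    ok = base["raw"].notna()
    np.testing.assert_allclose(base.loc[ok, "raw"], res.loc[ok, "raw"],
                               atol=1e-9)


def test_scans_match_brute_force_on_one_panel():
    """Spot check against the independent enumeration oracle (the
    acceptance suite runs hundreds of panels)."""
    h1 = neutral_fixture(9, 30, seed=21, n_founders=4)
    h2 = neutral_fixture(9, 30, seed=22, n_founders=4)
    h2 = make_haps(h2.alleles, h1.variants.pos.copy())
    pos = [int(p) for p in h1.variants.pos]
    t1, t2 = hap_tuples(h1), hap_tuples(h2)
    np.testing.assert_allclose(scan_ihs(h1, FREE)["raw"],
                               brute_unihs(t1, pos), atol=1e-12)
    i1, i2 = site_ies(h1, FREE)["ies"].to_numpy(), site_ies(h2, FREE)["ies"].to_numpy()
    np.testing.assert_allclose(i1, brute_ies(t1, pos), atol=1e-9)
    np.testing.assert_allclose(scan_xpehh(h1, h2, FREE)["raw"],
                               brute_unxpehh(brute_ies(t1, pos),
                                             brute_ies(t2, pos)), atol=1e-12)
    np.testing.assert_allclose(scan_rsb(h1, h2, FREE)["raw"],
                               brute_unrsb(brute_ies(t1, pos),
                                           brute_ies(t2, pos)), atol=1e-12)


def test_kernel_matches_reference_decay_path(rng):
    """The compiled scan kernels agree with the readable numpy decay +
    integration route to floating-point identity."""
    for seed in (31, 32):
        hm = neutral_fixture(10, 30, seed=seed, n_founders=5)
        params = EHHScanParams(stop_threshold=0.05, max_extension=8000,
                               max_gap_bp=1500)
        tr = scan_ihs(hm, params)
        for k in range(hm.n_sites):
            da = ehh_at(hm, k, 0, params)
            dd = ehh_at(hm, k, 1, params)
            if da is None or dd is None:
                assert np.isnan(tr["raw"][k])
                continue
            ia = integrate_decay(da, params.max_gap_bp)
            idd = integrate_decay(dd, params.max_gap_bp)
            if ia == 0.0 or idd == 0.0:
                assert np.isnan(tr["raw"][k])
            else:
                assert tr["raw"][k] == np.log(ia) - np.log(idd)


def test_ehh_curves_bounded_and_monotone(rng):
    hm = neutral_fixture(14, 40, seed=8, n_founders=6)
    for focal in range(0, 40, 5):
        for allele in (0, 1):
            dec = ehh_at(hm, focal, allele, FREE)
            if dec is None:
                continue
            for side in (dec.left, dec.right):
                vals = [1.0] + [v for _, v in side]
                assert all(0.0 <= v <= 1.0 for v in vals)
                assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))


def test_track_standardization_moments_per_bin():
    hm = neutral_fixture(20, 120, seed=10, n_founders=8)
    tr = scan_ihs(hm, FREE)
    bins = frequency_bins(np.where(tr["raw"].isna(), np.nan, tr["daf"]),
                          0.025, 10)
    for b in np.unique(bins[bins >= 0]):
        sel = (bins == b) & tr["score"].notna()
        if sel.sum() < 2:
            continue
        assert tr.loc[sel, "score"].mean() == pytest.approx(0.0, abs=1e-9)
        assert tr.loc[sel, "score"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
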