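"""Wright-Fisher simulator: determinism, drift, selection and structure."""

import numpy as np
import pytest

from sweepscan import SimConfig, neutral_fixture, simulate
from sweepscan.structure import pairwise_r2


def small_cfg(**kw):
    base = dict(n_diploid=30, n_sites=200, chrom_length=10_000_000,
                n_pops=1, split_generation=5, total_generations=25, seed=1)
    base.update(kw)
    return SimConfig(**base)


def test_same_seed_is_bit_identical():
    a = simulate(small_cfg())
    b = simulate(small_cfg())
    np.testing.assert_array_equal(a.populations[0].haplotypes.alleles,
                                  b.populations[0].haplotypes.alleles)
    np.testing.assert_array_equal(a.populations[0].haplotypes.variants.pos,
                                  b.populations[0].haplotypes.variants.pos)
    c = simulate(small_cfg(seed=2))
    assert not np.array_equal(a.populations[0].haplotypes.alleles,
                              c.populations[0].haplotypes.alleles)


def test_shapes_and_dosage_consistency():
    res = simulate(small_cfg(n_pops=2))
    assert len(res.populations) == 2
    for pop_sample in res.populations:
        hm, gm = pop_sample.haplotypes, pop_sample.genotypes
        assert hm.alleles.shape == (60, 200)
        np.testing.assert_array_equal(
            gm.dosages, hm.alleles[0::2].astype(np.int8) + hm.alleles[1::2])


def test_neutral_drift_is_binomial_scale():
    # one neutral generation at large N moves frequencies < 3 SE in ~99% of
    # sites (binomial sampling bound)
    cfg = small_cfg(n_diploid=500, n_sites=400, split_generation=0,
                    total_generations=1, seed=3)
    res = simulate(cfg)
    rng = np.random.default_rng([3, 0])
    from sweepscan.simulate import _burn_in
    _, founders = _burn_in(cfg, rng)
    p0 = founders.mean(axis=0)
    p1 = res.populations[0].haplotypes.alleles.mean(axis=0)
    se = np.sqrt(np.maximum(p0 * (1 - p0), 1e-9) / (2 * 500))
    frac = (np.abs(p1 - p0) <= 3 * se).mean()
    assert frac >= 0.97


def test_strong_selection_fixes_favored_allele():
    fixed = 0
    for seed in range(15):
        cfg = SimConfig(n_diploid=100, n_sites=60, chrom_length=5_000_000,
                        n_pops=1, split_generation=0, total_generations=100,
                        s=0.5, sweep_pos=2_500_000, sweep_start_freq=0.5,
                        seed=100 + seed)
        res = simulate(cfg)
        fixed += res.truth.fixed[1]
    # fixation probability ~ 1 - exp(-4 N s p) >> 0.95 at s=0.5, p=0.5
    assert fixed >= 14


def test_lost_sweep_reported_not_restarted():
    for seed in range(60):
        cfg = SimConfig(n_diploid=50, n_sites=60, chrom_length=5_000_000,
                        n_pops=1, split_generation=0, total_generations=40,
                        s=0.05, sweep_pos=2_500_000, sweep_start_freq=0.01,
                        condition="none", seed=seed)
        res = simulate(cfg)
        assert res.truth.attempts == 1
        if res.truth.lost[1]:
            assert res.truth.final_freqs[1] == 0.0
            return
    pytest.fail("no replicate lost a rare weakly-selected allele")


def test_conditioning_reaches_target_and_logs_attempts():
    cfg = SimConfig(n_diploid=50, n_sites=100, chrom_length=10_000_000,
                    n_pops=1, split_generation=5, total_generations=400,
                    s=0.1, sweep_pos=5_000_000, sweep_start_freq=0.01,
                    condition="sample_at_freq", target_freq=0.6,
                    max_attempts=200, seed=7)
    res = simulate(cfg)
    assert res.truth.final_freqs[1] >= 0.6
    assert res.truth.attempts >= 1
    traj = res.truth.trajectories[1]
    assert len(traj) == res.truth.generations_run - cfg.split_generation + 1
    assert np.all((traj >= 0) & (traj <= 1))


def test_fixation_conditioning():
    cfg = SimConfig(n_diploid=40, n_sites=100, chrom_length=10_000_000,
                    n_pops=2, sweep_pop=2, split_generation=5,
                    total_generations=500, s=0.3, sweep_pos=5_000_000,
                    sweep_start_freq=0.05, condition="fixation",
                    post_fixation_generations=3, max_attempts=200, seed=9)
    res = simulate(cfg)
    assert res.truth.fixed[2]
    assert not res.truth.fixed[1]


def test_neutral_fixture_shape_and_determinism():
    a = neutral_fixture(10, 50, seed=1)
    b = neutral_fixture(10, 50, seed=1)
    assert a.alleles.shape == (20, 50)
    np.testing.assert_array_equal(a.alleles, b.alleles)


def test_two_founder_fixture_has_maximal_ld():
    hm = neutral_fixture(20, 30, seed=4, n_founders=2)
    pairs = pairwise_r2(hm.dosages(), max_dist_bp=10**9)
    assert ((pairs["r2"] > 1 - 1e-9) | (pairs["r2"] < 1e-9)).all()


def test_heterozygosity_decays_at_wright_fisher_rate():
    # expected heterozygosity declines by a factor (1 - 1/(2N)) per
    # generation; fit the log-linear rate pooled over replicates
    from sweepscan.simulate import _next_generation
    # a very long chromosome decouples site genealogies, tightening the fit
    N, gens, reps, m, L = 50, 80, 12, 300, 2_000_000_000
    het = np.zeros((reps, gens + 1))
    for rep in range(reps):
        rng = np.random.default_rng(900 + rep)
        pos = np.sort(np.unique(rng.integers(1, L, size=2 * m))[:m]).astype(float)
        haps = (rng.random((2 * N, m)) < 0.5).astype(np.uint8)
        for g in range(gens + 1):
            p = haps.mean(axis=0)
            het[rep, g] = (2 * p * (1 - p)).mean()
            haps = _next_generation(haps, rng, pos, L, 1e-8, None, 0.0)
    mean_het = het.mean(axis=0)
    slope = np.polyfit(np.arange(gens + 1), np.log(mean_het), 1)[0]
    loss_rate = 1.0 - np.exp(slope)
    assert loss_rate == pytest.approx(1 / (2 * N), rel=0.10)


def test_split_populations_diverge_with_time():
    def fst(res):
        p1 = res.populations[0].haplotypes.alleles.mean(axis=0)
        p2 = res.populations[1].haplotypes.alleles.mean(axis=0)
        pbar = (p1 + p2) / 2
        keep = (pbar > 0.05) & (pbar < 0.95)
        num = ((p1 - p2) ** 2 / 2)[keep].mean()
        den = (2 * pbar * (1 - pbar))[keep].mean()
        return num / den
    vals = []
    for post in (5, 40, 120):
        cfg = SimConfig(n_diploid=50, n_sites=400, chrom_length=20_000_000,
                        n_pops=2, split_generation=10,
                        total_generations=10 + post, seed=77)
        vals.append(fst(simulate(cfg)))
    assert vals[0] < vals[1] < vals[2]


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(condition="bogus")
    with pytest.raises(ValueError):
        SimConfig(sweep_pos=10**12)
    with pytest.raises(ValueError):
        SimConfig(split_generation=10, total_generations=5)
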