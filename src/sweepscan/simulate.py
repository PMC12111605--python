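"""Forward Wright-Fisher simulator of one or two populations with an
optional selective sweep.

The simulator produces phased haplotypes with a known sweep truth and
emulates the statistical structure a two-breed selection-signature scan
needs: an ancestral population of ``n_diploid`` individuals is founded
from a limited pool of founder haplotypes (standing variation only, no new
mutation), drifts and recombines for ``split_generation`` generations,
then splits into ``n_pops`` copies that evolve independently.  From the
split onward an additive viability-selected allele (fitness 1, 1+s, 1+2s)
can sweep in one population; the sweep allele is (re)seeded at the focal
site in ``sweep_start_freq`` of the haplotypes at that moment, so its
carriers start on a small number of haplotype backgrounds, as a recent
beneficial variant would.

Crossovers per transmitted gamete are Poisson with mean
``chrom_length * recomb_rate`` (1e-8 Morgan/bp by default, i.e. 100 Mb per
Morgan), at uniform positions.  Everything is deterministic given the
seed; when a conditioning rule is requested, failed attempts are re-run
with derived seeds and the attempt count is recorded in the truth ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .types import GenotypeMatrix, HaplotypeMatrix, VariantTable

CONDITIONS = ("none", "sample_at_freq", "fixation")


@dataclass
class SimConfig:
    n_diploid: int = 100           # per population, after the split
    ancestral_n_diploid: Optional[int] = None  # size of the shared ancestral
    # population during burn-in; None = n_diploid.  A larger ancestral size
    # emulates the declining-Ne history of livestock breeds.
    n_sites: int = 2000
    chrom_length: int = 100_000_000
    recomb_rate: float = 1e-8      # Morgan per bp
    n_founder_haplotypes: Optional[int] = None  # None = twice the ancestral
    # diploid count, i.e. maximal founder diversity
    init_freq_range: Tuple[float, float] = (0.05, 0.95)
    n_pops: int = 2
    split_generation: int = 100    # generations of shared ancestry
    total_generations: int = 200   # upper bound including the shared phase
    s: float = 0.0
    sweep_pos: Optional[int] = None
    sweep_start_freq: float = 0.02
    sweep_pop: int = 1             # 1-based population index
    condition: str = "none"        # none | sample_at_freq | fixation
    target_freq: float = 0.6       # for sample_at_freq
    max_sweep_duration: Optional[int] = None  # generations allowed from the
    # split to condition satisfaction; None = no bound.  Bounding it near the
    # deterministic sweep time (2/s)*ln(2Ns) conditions on a *recent* sweep
    # rather than one that lingered at low frequency by drift.
    post_fixation_generations: int = 5
    max_attempts: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.recomb_rate < 0 or self.s < -0.5:
            raise ValueError("rates out of range")
        if self.sweep_pos is not None and not (
                0 < self.sweep_pos <= self.chrom_length):
            raise ValueError("sweep_pos outside the chromosome")
        if self.split_generation > self.total_generations:
            raise ValueError("split_generation exceeds total_generations")
        if not (1 <= self.sweep_pop <= self.n_pops):
            raise ValueError("sweep_pop out of range")


@dataclass
class SimTruth:
    """Ledger of one realized simulation."""
    sweep_site: Optional[int]           # column index of the selected site
    sweep_pos: Optional[int]            # its bp position
    selection_coefficient: float
    trajectories: Dict[int, np.ndarray]  # pop (1-based) -> per-gen derived freq
    final_freqs: Dict[int, float]
    fixed: Dict[int, bool]
    lost: Dict[int, bool]
    generations_run: int
    split_generation: int
    attempts: int
    seed: int


@dataclass
class PopulationSample:
    name: str
    haplotypes: HaplotypeMatrix
    genotypes: GenotypeMatrix


@dataclass
class SimResult:
    populations: List[PopulationSample]
    truth: SimTruth


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.5) + 16))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _founder_pool(rng, cfg: SimConfig) -> np.ndarray:
    n_anc = cfg.ancestral_n_diploid or cfg.n_diploid
    n_founders = cfg.n_founder_haplotypes or 2 * n_anc
    lo, hi = cfg.init_freq_range
    freqs = rng.uniform(lo, hi, size=cfg.n_sites)
    founders = (rng.random((n_founders, cfg.n_sites)) < freqs).astype(np.uint8)
    picks = rng.integers(0, n_founders, size=2 * n_anc)
    return founders[picks]


def _next_generation(haps: np.ndarray, rng: np.random.Generator,
                     positions: np.ndarray, length: int, rate: float,
                     sel_site: Optional[int], s: float) -> np.ndarray:
    """One discrete Wright-Fisher generation with recombination and, when
    requested, additive viability selection on ``sel_site``."""
    n2, m = haps.shape
    n = n2 // 2
    if sel_site is not None and s != 0.0:
        g = haps[0::2, sel_site].astype(float) + haps[1::2, sel_site]
        w = 1.0 + s * g
        w = np.maximum(w, 0.0)
        tot = w.sum()
        probs = w / tot if tot > 0 else None
    else:
        probs = None
    parents = rng.choice(n, size=n2, p=probs)
    which = rng.integers(0, 2, size=n2)
    n_co = rng.poisson(length * rate, size=n2)
    out = np.empty_like(haps)
    src = 2 * parents + which
    plain = n_co == 0
    out[plain] = haps[src[plain]]
    for i in np.flatnonzero(~plain):
        h0 = haps[src[i]]
        h1 = haps[2 * parents[i] + 1 - which[i]]
        cuts = np.sort(rng.uniform(0, length, size=n_co[i]))
        parity = np.searchsorted(cuts, positions) & 1
        out[i] = np.where(parity == 0, h0, h1)
    return out


def _variant_table(positions: np.ndarray, chrom: str = "1") -> VariantTable:
    n = len(positions)
    return VariantTable(
        np.repeat(chrom, n), positions,
        np.array([f"snp{i}" for i in range(n)], dtype=object),
        np.repeat("A", n), np.repeat("C", n), np.ones(n, dtype=bool),
    )


def _burn_in(cfg: SimConfig, rng: np.random.Generator):
    """Shared ancestral phase: founder pool drifting neutrally at the
    ancestral population size."""
    positions = _draw_positions(rng, cfg.n_sites, cfg.chrom_length)
    haps = _founder_pool(rng, cfg)
    for _ in range(cfg.split_generation):
        haps = _next_generation(haps, rng, positions, cfg.chrom_length,
                                cfg.recomb_rate, None, 0.0)
    return positions, haps


def _post_split(cfg: SimConfig, rng: np.random.Generator,
                positions: np.ndarray, ancestral: np.ndarray):
    sweep_site = None
    if cfg.sweep_pos is not None:
        sweep_site = int(np.argmin(np.abs(positions - cfg.sweep_pos)))
    n2 = 2 * cfg.n_diploid
    pops = []
    for _ in range(cfg.n_pops):
        if ancestral.shape[0] == n2:
            pops.append(ancestral.copy())
        else:
            rows = rng.choice(ancestral.shape[0], size=n2, replace=False)
            pops.append(ancestral[rows].copy())
    # seed the sweep allele on a fresh set of carrier backgrounds
    selected = cfg.s != 0.0 and sweep_site is not None
    if selected:
        k = max(1, round(2 * cfg.n_diploid * cfg.sweep_start_freq))
        carriers = rng.choice(2 * cfg.n_diploid, size=k, replace=False)
        col = np.zeros(2 * cfg.n_diploid, dtype=np.uint8)
        col[carriers] = 1
        pops[cfg.sweep_pop - 1][:, sweep_site] = col
    traj: Dict[int, List[float]] = {p + 1: [] for p in range(cfg.n_pops)}
    if sweep_site is not None:
        for p in range(cfg.n_pops):
            traj[p + 1].append(float(pops[p][:, sweep_site].mean()))
    gen = cfg.split_generation
    fix_countdown = None
    ok = cfg.condition == "none"
    while gen < cfg.total_generations:
        for p in range(cfg.n_pops):
            sel = sweep_site if (selected and p == cfg.sweep_pop - 1) else None
            pops[p] = _next_generation(pops[p], rng, positions,
                                       cfg.chrom_length, cfg.recomb_rate,
                                       sel, cfg.s)
            if sweep_site is not None:
                traj[p + 1].append(float(pops[p][:, sweep_site].mean()))
        gen += 1
        if selected:
            overdue = (cfg.max_sweep_duration is not None
                       and gen - cfg.split_generation > cfg.max_sweep_duration)
            f = traj[cfg.sweep_pop][-1]
            if cfg.condition == "sample_at_freq":
                if f >= cfg.target_freq:
                    ok = True
                    break
                if f == 0.0 or overdue:
                    break
            elif cfg.condition == "fixation":
                if fix_countdown is None:
                    if f == 1.0:
                        fix_countdown = cfg.post_fixation_generations
                    elif f == 0.0:
                        break
                if fix_countdown is not None:
                    if fix_countdown == 0:
                        ok = True
                        break
                    fix_countdown -= 1
    if cfg.condition == "fixation" and fix_countdown == 0:
        ok = True
    return pops, traj, sweep_site, gen, ok


def simulate(cfg: SimConfig) -> SimResult:
    """Run the simulator, honoring the conditioning rule.

    The shared ancestral phase is simulated once per seed; when a
    conditioning rule is requested, only the post-split phase is re-run
    with derived seeds (up to ``max_attempts`` times, count recorded), so
    every attempt draws the sweep on the same standing variation.
    """
    rng_burn = np.random.default_rng([cfg.seed, 0])
    positions, ancestral = _burn_in(cfg, rng_burn)
    attempts = 0
    while True:
        attempts += 1
        rng = np.random.default_rng([cfg.seed, attempts])
        pops, traj, sweep_site, gen, ok = _post_split(cfg, rng, positions,
                                                      ancestral)
        if ok or cfg.condition == "none":
            break
        if attempts >= cfg.max_attempts:
            raise RuntimeError(
                f"conditioning {cfg.condition!r} not met in "
                f"{cfg.max_attempts} attempts")
    vt = _variant_table(positions)
    samples = []
    for p in range(cfg.n_pops):
        ids = [f"pop{p+1}_ind{i}" for i in range(cfg.n_diploid)]
        hm = HaplotypeMatrix(pops[p], ids, vt)
        samples.append(PopulationSample(f"pop{p+1}", hm, hm.dosages()))
    truth = SimTruth(
        sweep_site=sweep_site,
        sweep_pos=int(positions[sweep_site]) if sweep_site is not None else None,
        selection_coefficient=cfg.s,
        trajectories={p: np.asarray(v) for p, v in traj.items()},
        final_freqs={p + 1: float(pops[p][:, sweep_site].mean())
                     if sweep_site is not None else float("nan")
                     for p in range(cfg.n_pops)},
        fixed={p + 1: sweep_site is not None
               and bool(pops[p][:, sweep_site].all())
               for p in range(cfg.n_pops)},
        lost={p + 1: sweep_site is not None
              and not bool(pops[p][:, sweep_site].any())
              for p in range(cfg.n_pops)},
        generations_run=gen,
        split_generation=cfg.split_generation,
        attempts=attempts,
        seed=cfg.seed,
    )
    return SimResult(samples, truth)


def ongoing_sweep_scenario(seed: int, neutral: bool = False) -> SimConfig:
    """Study conditions for the recent-partial-sweep benchmark.

    One population of 100 diploids sampled from a declining-Ne history
    (ancestral size 1000, 30 burn-in generations) — the demographic shape
    livestock breeds show.  A hard sweep (s = 0.1, additive) starts from a
    single standing copy at the split and is sampled when the derived
    allele first reaches frequency 0.7, with the sweep duration bounded at
    65 generations, near its deterministic time (2/s)·ln(2Ns), so the
    sampled sweep is recent.  ``neutral=True`` gives the matched no-sweep
    control.
    """
    L = 150_000_000
    if neutral:
        return SimConfig(n_diploid=100, ancestral_n_diploid=1000,
                         n_sites=2000, chrom_length=L, n_pops=1,
                         split_generation=30, total_generations=100,
                         s=0.0, sweep_pos=L // 2, seed=seed)
    return SimConfig(n_diploid=100, ancestral_n_diploid=1000, n_sites=2000,
                     chrom_length=L, n_pops=1, split_generation=30,
                     total_generations=130, s=0.1, sweep_pos=L // 2,
                     sweep_start_freq=0.005, condition="sample_at_freq",
                     target_freq=0.7, max_sweep_duration=65,
                     max_attempts=500, seed=seed)


def completed_sweep_scenario(seed: int) -> SimConfig:
    """Study conditions for the fixed-sweep (between-population) benchmark:
    two populations of 100 diploids split from the same declining-Ne
    ancestry; a hard sweep (s = 0.1) in population 2 only, run to fixation
    plus five generations."""
    L = 40_000_000
    return SimConfig(n_diploid=100, ancestral_n_diploid=1000, n_sites=2000,
                     chrom_length=L, n_pops=2, sweep_pop=2,
                     split_generation=30, total_generations=630, s=0.1,
                     sweep_pos=L // 2, sweep_start_freq=0.005,
                     condition="fixation", post_fixation_generations=5,
                     max_attempts=1000, seed=seed)


def neutral_fixture(n: int, m: int, seed: int,
                    n_founders: Optional[int] = None,
                    chrom_length: Optional[int] = None) -> HaplotypeMatrix:
    """Small neutral panel for unit tests: site frequencies uniform on
    (0.05, 0.95), linkage induced by drawing rows from a limited founder
    pool (default 2n founders, i.e. essentially unlinked)."""
    rng = np.random.default_rng(seed)
    if n_founders is None:
        n_founders = 2 * n
    if chrom_length is None:
        chrom_length = max(m * 1000, m + 1)
    positions = _draw_positions(rng, m, chrom_length)
    freqs = rng.uniform(0.05, 0.95, size=m)
    founders = (rng.random((n_founders, m)) < freqs).astype(np.uint8)
    rows = founders[rng.integers(0, n_founders, size=2 * n)]
    vt = _variant_table(positions)
    return HaplotypeMatrix(rows, [f"ind{i}" for i in range(n)], vt)
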