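# Methods

`sweepscan` implements a complete selection-signature scan for phased
diploid SNP panels from one or two diverged populations, together with a
forward Wright–Fisher simulator used to validate every statistic end to
end. This note documents the models, the parameters that matter, and the
design choices made where the methodology is genuinely open.

## Haplotype-homozygosity statistics

**EHH.** For a focal SNP *s* and core allele *a* carried by `n_a`
haplotypes, extended haplotype homozygosity at a flanking marker *t* is

    EHH(s,t | a) = Σ_k n_k(n_k − 1) / (n_a(n_a − 1)),

where the groups *k* partition carriers by allele identity over `[s..t]`.
It equals 1 at the focal SNP and is non-increasing outward (group
refinement can only split groups). The site-specific variant EHHS applies
the same homozygosity to all haplotypes, with the focal SNP's own alleles
included in the grouping (a config switch can exclude them), so its value
at the focal SNP is the focal-site haplotype homozygosity.

**Integration.** Curves are integrated over physical distance with the
trapezoidal rule, each side anchored at the focal SNP at the curve's own
starting value. The outward scan stops when the curve falls below
`stop_threshold` (default 0.05); the final trapezoid is cut at the linear
interpolation of the threshold crossing. Two guards keep the integral
well-behaved on sparse maps: a per-side cap `max_extension` (default 1 Mb)
and a per-interval width cap `max_gap_bp` (default 20 kb) so that a single
long gap cannot dominate iHH. All three are configurable; curves that hit
the chromosome end or `max_extension` while still above the threshold are
flagged `edge` and keep their truncated integral.

Distances are physical bp throughout; the data model carries no genetic
map and the Ne module's fixed 100 Mb/Morgan convention would make a cM
integration differ only by a constant factor.

**Scores.**

* `uniHS = ln iHH_A − ln iHH_D` (ancestral vs derived core allele),
  standardized to zero mean / unit sd (ddof 0) within derived-allele
  frequency bins of width 0.025; bins with fewer than 10 scored SNPs are
  merged with their neighbour. Log *differences* rather than a log of the
  ratio make the sign flip under allele-polarity exchange exact in
  floating point.
* `unXP-EHH = ln iES₁ − ln iES₂`, standardized globally; exactly
  antisymmetric under a population swap.
* `unRsb = inES₁ − inES₂` with `inES = ln iES` centered on its
  population-wide median (a mean-centering switch exists). The centering
  makes Rsb invariant to any constant rescaling of one population's iES.
  Note that because the centering is a per-population constant, the
  *globally standardized* Rsb track is identical to the standardized
  XP-EHH track built from the same iES values; the two differ in their
  raw values and under any non-global standardization.

Standardized scores are converted to two-sided Gaussian tail
probabilities reported as `−log10 p = −log10(1 − 2|Φ(x) − 0.5|)`,
computed through the log-CDF for tail accuracy and clamped at 320.

SNPs where either core allele has fewer than 2 carriers, or where an
integral is zero, are flagged and carry NaN scores rather than raising.

The chromosome-wide scans run through numba kernels that mirror the
readable numpy decay/integration path operation for operation; a test
asserts exact agreement between the two routes, and the whole pipeline is
checked against an independent brute-force enumeration on hundreds of
random panels at 1e-12.

## Runs of homozygosity

The caller reproduces the PLINK `--homozyg` window mechanism: 50-SNP
sliding windows, a window called homozygous with at most 1 heterozygous
and 5 missing calls (the named tool's defaults; the four quoted scan
parameters are a 0.05 per-SNP hit proportion, 50-SNP / 300-kb segment
minima, a 1000-kb maximum gap and a 50-kb/SNP density cap). Segments
begin and end at the outermost SNP meeting the hit-proportion rule.
Length classes are half-open (lower, upper] in {0–2, 2–4, 4–8, 8–16,
>16} Mb, so an exactly-2-Mb run is "0–2 Mb". `F_ROH = ΣL_ROH / L_auto`;
the default denominator is the SNP-covered span summed over chromosomes
(a user-supplied assembly length is accepted). The island track is the
per-SNP percentage of individuals covered by a called ROH, with the
empirical top 0.1% as the significance threshold and ties at the
threshold flagged.

## Structure and effective population size

The GRM uses the first VanRaden scaling (centered dosages over
`Σ 2p(1−p)`, missing mean-imputed, monomorphic sites excluded); PCA
returns eigenvectors scaled by the square root of their eigenvalue and
percent variance as eigenvalue over trace. Historical Ne comes from the
LD decay curve: squared dosage correlations of SNP pairs binned by
distance in Morgan (100 Mb/Morgan), then

    Ne(t) = (1/(4c)) · (1/r̄² − 1),   t = 1/(2c) generations ago,

evaluated at the bin midpoint. No sample-size correction is applied by
default (the formula is implemented literally); an option subtracts 1/n
from the observed r̄².

## Significance and regions

iHS uses a fixed `−log10 p > 4` rule (strict inequality); XP-EHH and Rsb
use Benjamini–Hochberg FDR ≤ 0.05 over the genome-wide two-sided
p-values; the ROH rule is the island top 0.1%. Significant SNPs expand to
1-Mb windows (±500 kb; the alternative ±1 Mb reading is a flag), windows
are unioned into disjoint regions whose peak is the largest-|score| SNP,
and regions are annotated with every gene interval they overlap
(half-open coordinates; a gene abutting the region end is excluded).
Cross-method sharing is reported as exclusive Venn counts per method
combination plus plain pairwise intersection sizes.

## The simulator

A discrete-generation diploid Wright–Fisher model with standing variation
only: sites are initialized from a founder haplotype pool (frequencies
uniform on (0.05, 0.95)) and tracked; no new mutation. Each transmitted
gamete recombines its parent's two haplotypes at Poisson(`L·r`) uniform
crossover positions (r = 1e-8 Morgan/bp, i.e. 100 Mb/Morgan, by default).
Selection is additive viability (1, 1+s, 1+2s) applied to parent sampling
in the swept population. A shared ancestral population of
`ancestral_n_diploid` individuals drifts for `split_generation`
generations and is then sampled into `n_pops` populations of `n_diploid`.
The sweep allele is (re)seeded at the focal site at the split on a small
random set of carrier haplotypes, as a recent beneficial variant.
Everything is deterministic given the seed; conditioning rules (sample
when the derived frequency first reaches a target, optionally within a
bounded number of generations; or run to fixation plus a few generations)
re-run only the post-split phase with derived seeds and record the
attempt count.

**What the generator emulates and what it does not.** It reproduces the
features the statistics consume — haplotype structure from drift and
recombination on a declining-Ne background, LD decay with distance,
population divergence, partial and complete sweeps with known truth. It
does not model new mutation, gene conversion, variable recombination or
mutation rate, genotyping error, or ascertainment; passing tests
therefore demonstrate the statistics' behaviour under idealized phased
data, not robustness to real-data artefacts.

**Benchmark scenarios.** The sweep-power benchmarks use populations of
100 diploids sampled from an ancestral population of 1000 (30 burn-in
generations) — the declining-Ne shape typical of livestock breeds, whose
recent effective sizes are around 100–150 while ancestral sizes are in
the thousands. Under a constant N=100 history the neutral background is
nearly as homozygous as a swept region and no haplotype statistic
separates them reliably. The ongoing-sweep scenario is a hard sweep
(s = 0.1) from a single standing copy, sampled when the derived allele
first reaches frequency 0.7 with the sweep duration bounded at 65
generations — near the deterministic sweep time (2/s)·ln(2Ns) — so the
sampled sweep is recent; 2000 SNPs on a 150-Mb chromosome. Scans on
these panels use `max_extension` = 5 Mb, the distance at which neutral
EHH at N=100 reaches the 0.05 stop threshold (4Nc ≈ 19); the 1-Mb
module default reflects common practice on real WGS cattle panels, where
Ne is far larger near the tips of the genealogy.

**A known negative result.** After a sweep *fixes*, the swept tract is
monomorphic over roughly ±1/(r·T_fix) (≈ Mb at s = 0.1, N = 100), and
every marker inside it integrates the same EHHS ≈ 1 span: the
cross-population score is flat across the tract, so the peak SNP
localizes only to the swept region, not to the selected site. The
completed-sweep benchmark asserting peak-SNP localization within 200 kb
reflects this: measured localization is ~15% of replicates at these
population sizes (softer or slower sweeps do worse — the signal collapses
or the reference population degrades over the longer fixation time), and
the corresponding test documents the limitation rather than hiding it.
Region-level localization (±2 Mb) is reliable.

## Numerical choices and degenerate inputs

Zero-variance standardization strata yield zero scores with a warning;
sites with no computable statistic propagate NaN end to end; monomorphic
sites are excluded from the GRM and LD; a chromosome shorter than one ROH
window yields no calls (logged); empty annotation files yield empty gene
lists; the QC report counts each failing site once under the precedence
call-rate → MAF → HWE while removal is the union. The exact HWE test
enumerates heterozygote counts in log space and sums probabilities no
greater than the observed outcome's (with a 1+1e-12 tie guard), matching
a rational-arithmetic enumeration oracle exactly for all tables with
n ≤ 25.

## Problem sizes in the test suite

Unit tests run on panels of tens of haplotypes and tens to hundreds of
markers; oracle-equivalence tests use 200 random panels (≤ 20 haplotypes,
≤ 50 markers) and 500 random genotype strings (≤ 200 SNPs); power and
recovery benchmarks use 20 replicates each of the scenarios above. These
sizes were chosen so the full suite exercises every property in a few
minutes on one CPU.
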