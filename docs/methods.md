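# Methods

## The UBCS statistic

GC-biased gene conversion enriches weak-to-strong (A/T to G/C) substitutions
in recombining regions, and these substitutions cluster — most visibly near
autosomal telomeres and, on human chromosome 2, around the remnant of the
ancestral fusion site.  The package quantifies this with the UBCS statistic
(*unexpected biased clustered substitutions*): for every 1 Mb region of a
chromosome,

```
UBCS = observed BCS count − expected BCS count under independent labels.
```

A substitution is a *clustered substitution* (CS) when some 300 bp window
contains it together with at least four other substitutions, and a *biased
clustered substitution* (BCS) when such a window additionally has at least
80% weak-to-strong members (the substitution itself need not be biased).
The null model keeps the substitution positions fixed and draws the bias
labels i.i.d. Bernoulli(p̂), with p̂ the region's weak-to-strong fraction —
i.e. it assumes no association between clustering and bias.

### Input: polarized substitution catalogs

Substitutions come from pairwise target/query genome alignments with an
outgroup base per position.  A candidate single-nucleotide difference (SND)
is discarded when its 11 bp context window contains an indel, more than two
target/query differences (the focal SND counts as one), or no outgroup base;
windows truncated by contig or block edges are discarded too (a conservative
reading of "window centred on the SND").  Surviving SNDs are polarized: the
genome matching the outgroup carries the ancestral state; ties to neither
are *inconclusive* and dropped.  A substitution is *biased* when the
ancestral base is A/T and the derived base is C/G.  Catalogs are kept per
derivation direction (derived-in-target vs derived-in-query); clustering is
never computed across directions.  Coordinates are 0-based, intervals
half-open.

### Exact expected counts

The expected BCS count of a region is the sum over its substitutions of the
probability that the substitution is biased-clustered.  For a focal
substitution at position `j`, that event is the union over every window
containing `j` of "the window is a biased cluster".  Windows are restricted
to starts that are multiples of `start_divisor` (default 1 — every window;
150 reproduces the older half-overlapping scheme, and observed and expected
always use the same divisor).  Two reductions make the union tractable:
windows with fewer than 5 substitutions have probability zero, and windows
containing the same substitution set describe the same event, so one
representative (the smallest start) suffices.  The number of representatives
is bounded by the substitution count of the covered region.

The covered region is compressed to `2n − 1` *bins* delimited by the ordered
starts and ends of the `n` representative windows; cluster `k` is the run of
`n` consecutive bins starting at bin `k`, and the focal substitution sits in
the middle bin.  With per-bin biased counts independent given the label
model, the union probability is the telescoping sum

```
P(A1) + P(A2 ∩ ¬A1) + … + P(An ∩ ¬A1 … ¬An−1),
```

each term computed by conditioning on the joint biased counts of the `n − 1`
bins shared between consecutive clusters.  The conditional probability that
all earlier clusters failed is carried forward as a table indexed by those
shared counts — a dynamic programme whose state space is the Cartesian
product of bin capacities, at most `2^c` entries for `c` substitutions in
the covered region.  The implementation evaluates each term as a tensor
contraction (outer-product joint pmf, cumulative sums over the preceding
bin) rather than an explicit loop over the product; the recursion is
mathematically identical and is verified in the test suite against direct
`2^s` enumeration of label assignments to 1e−9 on hundreds of random
configurations.

Numerical choices: the 80% threshold is applied by exact integer arithmetic
(`count · den ≥ num · size`), so boundary cases like 4/5 are never lost to
floating point.  Regions with no substitutions carry an undefined p̂ and
zero UBCS.  p̂ always comes from the 1 Mb region containing the focal
substitution even when its windows straddle a boundary, and clusters are
built chromosome-wide.  Covering regions with more than `max_exact_subs`
(default 22) substitutions — hyperdense overlaps where `2^c` is infeasible —
fall back to a seeded Monte-Carlo estimate of the union probability
(default 10^5 draws) with a logged warning.  The final partial region of a
chromosome is emitted with a `partial` flag and excluded from telomere
arithmetic downstream.

## Divergence-time estimation

Telomeric UBCS accumulates roughly linearly with time since divergence, so
for two species pairs x and y (both using the human genome as target) the
per-arm ratio

```
T(i) = Σ_{j=1..M} U(x, window j) / Σ_{j=1..M} U(y, window j)
```

over the M = 10 outermost 1 Mb windows of an arm (q-arm windows taken from
the chromosome end inward) estimates their divergence-time ratio.  The
distance is the median of T over a fixed pool of 28 control telomeres:
p arms of chromosomes {1, 4, 5, 6, 8, 10, 12, 16, 17, 19} and q arms of all
autosomes except {15, 18, 19, 20} — arms unaffected by large-scale
rearrangement and acrocentric short arms.  Telomeres whose denominator sum
is not positive are excluded with a warning (UBCS can be negative; the
median is robust to the loss).  Multiplying by the fixed human–chimpanzee
split of 6 Mya converts the proportion into a speciation time.

The bootstrap CI draws, per replicate, 15 of the 28 telomeres with
replacement and 8 of the 10 window offsets with replacement (one offset draw
shared across the replicate's telomeres; a per-telomere variant is available
behind a flag), recomputes the median, and reports the replicate range after
trimming 2.5% from each tail — "removing the 5% most extreme values" read
as a central interval.

## Fusion-time estimation

Let R be the fraction of the 6 My since the human–chimpanzee split during
which the two ancestral chromosomes were still separate; the fusion time is
`6 Mya · (1 − R)`.  R is approximated as q1 / q2:

* **q1** — the ratio of human-derived to chimpanzee-derived UBCS summed over
  the two length-L intervals flanking the fusion site (default
  chr2:113,500,000; a one-sided variant is available).  Human-derived signal
  accumulated telomere-style only while the site was a telomere; the
  chimpanzee p-arm telomeres of 2A/2B kept accumulating throughout.
* **q2** — a rescaling factor correcting for the chimpanzee telomere caps
  (hyper-expanded segmental duplications) absent from the human reference,
  which displace the chimp-derived signal inward.  It is the median over
  control telomeres (both arms of chromosomes 1–12, 16, 17) of human-derived
  UBCS in the first L bp of the arm over the same-length interval starting
  5 Mb inward.

The sweep L = 15…20 Mb (scaled in the synthetic experiments) yields R(L);
the point estimate is `6 · (1 − median_L R(L))`, clamped to [0, 6].  The
paper-level description fixes only that a 95% CI accompanies the median; the
CI construction here is a bootstrap that per replicate draws an interval
size uniformly, resamples the control telomeres with replacement (q2) and
resamples the paired 1 Mb windows flanking the site with replacement (q1),
again trimming 2.5% per tail.  The q1 component is this package's design
choice: without it the CI would ignore fusion-site sampling noise entirely
and could not reach nominal coverage on data with realistic counts.

## Synthetic data

The generator produces the statistical structure the method assumes, not
nucleotide-level realism: a homogeneous background point process of
substitutions (bias fraction p0 = 0.25), a Neyman–Scott cluster process
(Poisson centres, 1 + Poisson(6) members scattered over a 300 bp span, bias
fraction p1 = 0.9), cluster rates elevated at chromosome ends with an
exponential decay, and all intensities scaling linearly with a divergence
time factor.  Defaults are a scaled-down genome — 22 autosomes of 20 Mb,
background 5·10⁻⁴/bp, telomeric cluster rate 6·10⁻⁶/bp at the tip with a
2 Mb decay — chosen so that (a) a full species-pair analysis runs in
seconds and (b) background substitutions dominate every region's
weak-to-strong fraction (cluster share ≲ 25%), the regime the statistic's
null assumes; when clusters dominate p̂, the expected-BCS term saturates and
no estimator, including the real one, remains linear.  Cluster members sit
on a 6 bp lattice: the SND density filter would discard closer pairs anyway,
and this makes alignment fixtures round-trip exactly through the caller.
Residual cross-component position collisions are resolved by greedy
minimum-spacing thinning (deterministic given the seed).

The fusion scenario simulates the 14 control chromosomes (including
chromosome 2, whose physical telomeres are intact) and adds two components
at the internal site: human-derived at `R ×` telomere shape, query-derived
at full strength but with the exponential origin shifted outward by the
probe offset — the geometric encoding of the missing telomere caps that q2
corrects.  By construction `q1 = R · e^{offset/λ}` and `q2 = e^{offset/λ}`
in expectation, so the estimator should recover R for every L; the scenario
uses a 1 Mb offset and L ∈ {3, 4, 5} Mb on 20 Mb chromosomes.

What the generator does not emulate: CpG effects, rate heterogeneity beyond
clusters, alignment error, assembly gaps, real isochore structure, and
chromosome-scale rearrangements.  Passing recovery tests therefore shows the
estimators are correct and calibrated under the model's own assumptions at
reduced scale, not that real Great Ape genomes satisfy those assumptions.

## Problem sizes used by the test suite

Oracle equivalence uses 200 random configurations with ≤ 12 substitutions in
the covering region (exhaustive 2^s enumeration as the oracle).  Null
calibration redraws labels 500 times over ~1,060 fixed positions in 2 Mb.
The distance recovery experiment runs 50 independent species-pair
simulations at rate ratio 2 on the default 22 × 20 Mb genome; the fusion
recovery runs 50 simulations of a 1.0 Mya fusion under a 6 Mya split on the
14-chromosome scenario.  At these sizes the distance estimator shows
per-repeat spread of about 7% and the fusion estimator about 0.7 Mya, with
bootstrap coverage near nominal in both.

## Known limitations

* The expected-BCS computation is exact only up to the `max_exact_subs`
  cap; beyond it the seeded Monte-Carlo fallback introduces ~10⁻³-level
  error on those (rare) substitutions.
* Interval sums over profiles weight partially covered 1 Mb regions by
  overlap fraction; sites not aligned to the region grid therefore use an
  approximation at the two boundary regions.
* The q-arm convention reads windows from the chromosome end inward and
  ignores centromere positions; on real assemblies, arms shorter than
  M windows are used as-is with a warning.
* Whole-genome analyses (reproducing the published fusion and speciation
  numbers) require UCSC-scale alignments and are outside the test surface;
  the MAF/TSV readers support the formats but have only been exercised at
  fixture scale.
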