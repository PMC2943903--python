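# Methods

## Model and hypotheses

`readbias` treats a read set as a sample from a generative null model
with three components, each of which yields a testable prediction:

- **Uniform sampling (H1).** Every genome position (either strand) is
  equally likely to start a read. If a k-mer $w$ occupies a fraction
  $p_w$ of genome windows, the number of reads carrying $w$ at a fixed
  offset is $\mathrm{Binomial}(N, p_w)$.
- **Position independence (H2).** The probability that a read carries
  $w$ at offset $i$ does not depend on $i$ (edge effects at the genome
  boundary are neglected). A k-mer's positional count profile is flat;
  a significant regression of count on offset rejects H2 and with it H1.
- **Context-free substitution errors (H3).** Where an error occurs, the
  called base is one of the three alternatives uniformly, independent
  of position context. Errors may (and in practice do) become more
  frequent toward read ends; H3 only constrains what the error is, not
  where.

The three screens test these predictions at increasing depth:
per-position base counts (a $k=1$ special case of the k-mer screen),
binomial tail tests of positional k-mer counts against a background,
and pairwise Kullback-Leibler divergences between smoothed per-position
k-mer distributions, calibrated by simulation under H1+H3.

## Binomial tail p-values in log space

Counts in real screens can sit hundreds of standard deviations from
expectation, far below floating-point range, so all p-values are
computed and reported as log10 values. The log-pmf uses a log-factorial
that is exact (cumulative $\sum \ln i$) for $n \le 20$ and the Stirling
series

$$\ln n! \approx n\ln n - n + \tfrac12\ln(2\pi n) + \tfrac{1}{12n} - \tfrac{1}{360n^3}$$

above. The correction terms matter: the leading-order formula alone has
absolute error $\sim 1/(12n)$ per factorial, which for moderate $n$
already violates a $10^{-3}$ relative accuracy target on the log10
scale near the distribution's centre; with the $1/(12n)$ term the
truncation error drops to $O(n^{-5})$ and the whole p-value path agrees
with exact summation to ~$10^{-6}$ on the log10 scale (measured in the
acceptance run).

The one-sided tail is summed outward from the observed value, each term
obtained from its predecessor by the exact ratio
$t_{x+1}/t_x = p(n-x)/((x+1)(1-p))$, accumulated with `logaddexp`.
Summation stops when the next term falls 40 nats below the running sum
(relative contribution $< 10^{-17}$) or when a term cap of
$30\sigma + 200$ terms is reached, in which case the remaining mass is
bounded by the geometric series $t \cdot r/(1-r)$ with the same ratio
and added in closed form. Degenerate backgrounds ($p \in \{0,1\}$)
return exact answers, including $-\infty$ for impossible observations.

Direction is the side of the mean the observation falls on; p-values
are one-sided and never doubled, since over- and under-representation
are reported as distinct findings. Bonferroni adjustment multiplies by
the number of (k-mer × position) tests actually emitted; both raw and
adjusted log10 values appear in the output.

Background probabilities of exactly zero (k-mer absent from the
reference) are floored at $1/(2\,n_{\mathrm{sites}})$ — half an
observation — before testing, so observed-but-impossible k-mers are
reported as the extreme outliers they are rather than crashing the
logarithm. The reference background counts every valid window on both
strands by default (the simulator samples both strands), with the
denominator equal to the number of windows counted.

## KL divergence and smoothing

Per-position distributions are additively smoothed:
$P_i(w) = (c_{i,w} + \alpha)/(n_i + \alpha 4^k)$ with $\alpha = 0.5$
by default. Smoothing is what makes $\mathrm{KL}(P_i\|P_j)$ finite when
a k-mer is seen at one offset but not another; $\alpha$ is a surfaced
parameter and $\alpha = 0$ (support-intersection semantics, hard error
on $P>0, Q=0$) remains available. Logarithms are base 2, so divergences
are in bits. Default $k = 6$; larger $k$ spreads the same windows over
$4^k$ bins and drowns signal in smoothing noise (the sampling-noise
floor of a smoothed KL cell is roughly $(4^k - 1)/(2 n \ln 2)$ bits),
smaller $k$ loses sequence specificity. Positions with fewer than a
coverage floor of valid windows (default 1000) are dropped from the
matrix and listed, since tail offsets of variable-length read sets are
noise-dominated.

Two summaries are derived from the matrix: the first-position excess
ratio (mean of row 1 + column 1 over the interior off-diagonal grand
mean; values well above 1 indicate start-site bias) and, with a
calibration, per-cell effect sizes.

## Bootstrap calibration and effect sizes

The simulator implements exactly H1+H3: start sites uniform on
$[0, G-L]$, strand fair-coin, per-position substitution probability
taken from an error profile, substitute bases uniform over the three
alternatives. The error profile is the per-position **mean error
probability** of the observed data, $\overline{10^{-Q/10}}$ — averaging
probabilities, not Phred scores, keeps the profile an unbiased rate
estimate (the mean of transformed scores is Jensen-biased). Emitted
qualities are the Phred equivalents of the profile rates. This is a
deliberate simplification relative to resampling whole per-read quality
strings: it preserves the marginal per-cycle error rate, which is the
only quantity the null KL surface depends on, but not quality
covariance within reads.

Calibration simulates $R$ replicate read sets (replicate $r$ seeded
with $\mathrm{seed} + r$), computes each KL matrix, and reports
per-cell mean and standard deviation (ddof 1). The default $R = 100$;
the acceptance run uses $R = 20$, which bounds the standard error of a
cell mean at $\sigma/\sqrt{20} \approx 0.22\sigma$ — ample for the
qualitative structure checks it performs. The average null sd is
reported with a 95% normal-approximation CI across off-diagonal cells
(the diagonal is identically zero and excluded). Effect sizes are
$z = (\mathrm{obs} - \mu)/\sigma$ per cell; cells with $\sigma = 0$ are
listed as degenerate and no number is fabricated. Callers are expected
to match the simulated read count to the observed one so coverage and
genome complexity are preserved.

An error profile that rises along the read reproduces the
characteristic "stingray" null surface: late-position distributions are
pushed toward uniformity, so divergence between early and late offsets
grows while adjacent middle offsets stay close. This effect exists only
when the genome's k-mer composition is itself non-uniform — on an
exactly GC-balanced i.i.d. genome the k-mer distribution is already
uniform and substitutions move nothing. The synthetic studies of this
effect therefore use a GC = 0.4 genome (mammalian-like composition; the
analytic first-vs-last signal there is $3.4\times10^{-4}$ bits at
$k=3$, ~8 replicate standard errors at the study's sizes, versus
exactly zero at GC = 0.5).

## Synthetic data: what it does and does not emulate

`generate_genome` draws i.i.d. bases with a specified GC fraction;
`generate_reads` samples reads under H1 with optional injected biases,
applied by overwriting bases **after** sampling so the genome stays
clean and every injected effect size is exactly computable:

- start-site motif: a fixed fraction of reads has its prefix replaced;
- positional enrichment: extra copies of a k-mer planted at one offset
  to reach a target fold over the empirical base rate;
- homopolymer conversion: windows in the read tail differing from a
  pure run by one base are converted to the run with a given
  probability (emulating the systematic errors that manufacture poly-G
  tails; conversions cascade left-to-right across overlapping windows);
- error gradient: linear per-position substitution rates.

Default study conditions, used by the test suite and the acceptance
script: 100 kb genome, 100,000 reads of length 36, $k = 3$ for
matrix-level analyses (dense bins at this read count) and $k = 6$ for
motif/homopolymer detection, 20 bootstrap replicates, start-motif
fraction 5%, error gradient 0.001→0.05. These sizes keep the full suite
in tens of seconds while leaving every tested effect many standard
errors from its threshold.

An i.i.d. genome has none of the repeat structure, long-range
composition heterogeneity or true k-mer correlations of real genomes,
and the simulator makes no indels and no quality-dependent miscall
identities (e.g. the G→T confusion of some platforms — excluded
deliberately, since H3 is the null being implemented). Passing tests
therefore demonstrate that the detectors recover biases of the modelled
kinds at realistic magnitudes and stay quiet under the exact null; they
do not certify behaviour on platform-specific artefact classes outside
the model.

## Numerical and design choices

- Positions are 1-based in every report and API surface that names a
  position; storage is 0-based, converted only at the boundary.
- Non-ACGT input characters (lowercase is uppercased first) map to N;
  N is counted as a fifth symbol in base-call profiles, while k-mer
  windows containing N are tallied per offset as skipped, keeping the
  window-conservation invariant counts + skipped = covering reads.
- Quality-offset auto-detection: any ASCII code < 59 forces Phred+33;
  all codes ≥ 64 with at least one > 74 indicates Phred+64; samples
  confined to the overlap window resolve to 33 with a warning, since a
  wrong +64 silently yields negative qualities.
- Trend fits are OLS on raw counts against offset (degree 1 or 3, or
  both with the better adjusted R² under "auto"); constant counts give
  r² = 0, p = 1 and a degenerate flag rather than 0/0. p-values come
  from the regression F statistic.
- Poly-A removal threshold: at most 5% of bases non-A (the artefact is
  a near-pure fragment; the cut-off is parameterised). Primer matching
  allows 1 mismatch by default, N counts as mismatch, and reads shorter
  than the primer get a proportionally scaled budget. Whole reads are
  removed, not trimmed; removed reads are always written to a sidecar,
  never dropped silently.
- The combined filter attributes a read matching both criteria to the
  poly-A filter, which runs first, keeping the report a partition.
- All generators and the simulator take explicit integer seeds; a
  calibration's replicate $r$ uses $\mathrm{seed}+r$.

## Known limitations

- The binomial test treats reads as independent trials; at extreme
  coverage of a tiny genome the finite-population correction is
  ignored.
- The read-pool background is itself distorted by strong positional
  biases (the bias being tested contaminates the expectation); a
  reference background is preferred when available.
- KL cells are compared against a simulated null, not against an
  analytic distribution; with few replicates the sd estimates are
  noisy, which effect sizes inherit.
- Variable-length read sets are supported throughout, but the bootstrap
  calibrates at a single (maximal) read length and scores only reads of
  that length.
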