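# readbias

Reference-free assessment of positional bias in short sequencing reads.

High-throughput sequencers are routinely assumed to sample a genome
uniformly and to make context-free substitution errors. Real read sets
violate both assumptions — start-site preferences, leftover primers,
per-cycle base-call artefacts and systematic homopolymer conversion all
leave positional fingerprints in the reads themselves. `readbias` finds
those fingerprints without mapping the reads to a reference, which makes
it usable for novel organisms, metagenomes and any material of unknown
origin. It is aimed at anyone about to assemble, resequence or quantify
from a pool of reads and who wants to know what is wrong with the pool
first.

## The three screens

Let $G$ be the genome length, $L$ the read length, $N$ the number of
reads, and $X_{w,i}$ the number of reads carrying k-mer $w$ at offset
$i$.

1. **Base calls.** Count each symbol A, C, G, T, N at every read
   position. Unbiased data gives flat per-position fractions and
   balanced complementary pairs (A≈T, C≈G); deviations localise the
   problem within the read.

2. **Positional k-mer tests.** Under uniform sampling of start sites, a
   k-mer occupying fraction $p_w$ of genome windows satisfies
   $X_{w,i} \sim \mathrm{Binomial}(N, p_w)$ at any fixed offset.
   `readbias` computes one-sided tail p-values in the deviation
   direction entirely in log space, using a Stirling-series
   log-factorial ($\ln n! \approx n\ln n - n + \tfrac12\ln 2\pi n +
   \tfrac{1}{12n}$) with a geometric bound for the far tail, so counts
   hundreds of standard deviations from their expectation still get
   finite, accurate log10 p-values. The background $p_w$ comes from a
   reference genome's window frequencies or, reference-free, from the
   pooled reads. A per-k-mer polynomial regression of count against
   offset (degree 1 or 3) tests position independence directly.

3. **KL-divergence matrix.** Let $P_i$ be the distribution of all
   $4^k$ k-mers at offset $i$ (default $k=6$, additively smoothed with
   pseudo-count $\alpha = 0.5$). The matrix
   $\mathrm{KL}(P_i \| P_j) = \sum_w P_i(w)\log_2 \frac{P_i(w)}{P_j(w)}$
   over all ordered offset pairs maps where in the reads the k-mer
   composition shifts. Observed values are calibrated by a bootstrap:
   repeatedly simulate read sets under the uniform-sampling null with
   substitution errors drawn from the data's own quality profile,
   and report each observed cell as an effect size
   $z = (\mathrm{obs} - \mu_{\mathrm{null}}) / \sigma_{\mathrm{null}}$.

Artefact filters (poly-A fragments, primer prefixes such as
`GATTACAGGCATGAGC`) run before the screens, and a synthetic-data module
generates genomes and read sets with planted biases so every detector
can be validated against known ground truth.

## Worked example

Generate a read set in which 10% of reads were forced to start with
`ACGTAC`, then ask `readbias` to find the bias:

```
$ readbias synth --genome-length 15000 -n 10000 --length 24 \
      --start-motif ACGTAC:0.1 --seed 7 -o synth_out
wrote genome.fasta, reads.fastq, spec.json to synth_out/

$ readbias report synth_out/reads.fastq --ref synth_out/genome.fasta \
      -k 6 --min-coverage 100 -o report_out
{"bias_detected": true, "flags": {"start_position_bias": true, "first_position_divergence": false}}
```

`report_out/kmer_tests.tsv` ranks every 6-mer tested at the read start;
the top row is the planted motif:

```
kmer    position  observed  expected  log10_pvalue  direction
ACGTAC  1         1036      1.0003    -2700.26      over
```

Read: `ACGTAC` started 1036 reads where ~1 was expected under uniform
sampling — overrepresented with log10 p ≈ −2700, impossible by chance.
(Note the log-space machinery at work: no floating-point p-value could
represent this.) The KL flag stays false here: with only 10,000 reads
spread over 4096 six-mer bins, the matrix in `report_out/kl_matrix.tsv`
is dominated by smoothing noise (interior mean ≈ 0.53 bits) and the
first-position excess ratio, 1.69, sits below the conservative 2×
flagging threshold — at realistic read counts (10⁵ and up, as in the
test suite) the same 5–10% motif pushes the ratio past 3. On an
unbiased fixture every flag is false.

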