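# Methods

## Clonal barcoding model

A clone is a transduced progenitor carrying one barcode from a finite
library. The library is modeled as n unique sequences drawn uniformly
from the 4^18 fills of the degenerate template
`GGNNNACNNNGTNNNTANNNCANNNTGNNN` (12 fixed anchor bases, 18 N); the
default library size is 725. Each clone has a lineage fate — which of the
three sorted populations it contributes to. Every clone contributes to
the progenitor compartment (NMP, self-renewal); uni-lineage fates add one
blast compartment (MB or EB) and the tripotent fate adds both. Within
each population a clone's cell count is log-normal(μ=0, σ=1) — a standard
heavy-tailed model of clonal expansion; no empirical clone-size law is
available for this setting, so this is a stipulation, not a
reconstruction.

Sequencing of a population draws `depth` reads with clone probabilities
proportional to abundance. A read is a 20-nt constant flank, the 30-nt
barcode, and a second 20-nt flank, with i.i.d. substitutions (a hit
always changes the base) at the per-base error rate over the whole read;
indels are not modeled because extraction is exact-match, so any indel in
the barcode region is equivalent to a substitution loss. Defaults:
400 clones, fate mix {NMP-only 0.40, NMP+MB 0.15, NMP+EB 0.15, tripotent
0.30}, 50,000 reads per population, 0.5% substitution rate. These are the
package's reference study conditions: several hundred engrafting clones
out of a 725-barcode library, a tripotent fraction large enough that the
three-way sharing question is well posed (an analytical power calculation
at these fractions puts the expected union-pool 3-way z-score near 8), and
amplicon depths and error rates typical of a benchtop sequencer.

### Extraction and inclusion

Reads are scanned left-to-right for the first window conforming to the
template (anchors exact, N any base; reverse-complement scan is opt-in —
amplicon orientation is library-specific). Only exact whitelist matches
are counted; conforming windows off the whitelist are tallied in QC but
never error-corrected, since with 725 barcodes in a 4^18 space nearest-
neighbour correction would be safe but is not part of the procedure being
modeled. The inclusion rule is a depth-scaled floor: with d_min the depth
of the shallowest sample, barcode b enters sample s iff
counts(b,s)/depth(s) ≥ 1/d_min — i.e. the relative abundance equivalent
of one read in the shallowest sample. The literal raw reading
(counts ≥ 1) is kept as `mode="raw"`; normalization is the default
because it is the only reading under which the shallowest sample's depth
matters, and raw-mode sets always contain normalized-mode sets.

## Overlap nulls

The null: each population's barcode set is an independent uniform
fixed-size subset of an N-pool. Tests are one-sided enrichment tails
P(intersection ≥ k_obs).

* **2-way:** |A ∩ B| is hypergeometric; the tail is evaluated by scipy in
  a numerically stable form (no explicit binomial coefficients, so no
  overflow at any N). The default pool is the library size (725).
* **m-way exact:** the running intersection of a fixed set of size j with
  a fresh uniform n-subset is Hypergeometric(N, j, n) regardless of how j
  arose, so the m-way intersection pmf is an (m−1)-fold product of
  hypergeometric kernels. This is exact at any N — no enumeration guard
  is needed. The tail at k_obs = 0 is returned as exactly 1.
* **m-way Monte-Carlo:** the same sequential-conditioning identity turns
  one random draw of m subsets into a chain of vectorized hypergeometric
  variates, making the reference 10,000,000 iterations run in seconds.
  The estimate is add-one corrected, (hits+1)/(M+1), so a reported p is
  never 0; `correction=False` gives the raw unbiased estimator. The
  reported `mc_se` is the binomial standard error √(p(1−p)/M).
* **Pools:** 2-way tests condition on the library; m-way tests on the
  union of detected barcodes (both overrideable) — the two pools answer
  slightly different questions and both are legitimate, so the choice is
  explicit in every result object.

The m-way fold and the Monte-Carlo chain share the sequential-conditioning
insight; their independence as implementations is backed in the test
suite by a third route, brute-force enumeration over all subset
configurations on tiny pools.

## qRT-PCR model and scoring

The simulator draws, per cell and gene: a `Fail` flag with probability
`fail_rate` (instrument QC, independent of expression), otherwise
detection with a genotype×gene probability, and a detected Ct from a
gene-specific normal truncated into (0, 40]. Housekeeping genes are
detected with probability 1 (minus fails) from N(18, 1); lineage genes
default to N(25, 2). Reference conditions: a myeloid-committed pattern
(erythroid detection 0.1, myeloid 0.9 → design ratio R = 1/9) and an
erythroid-shifted pattern (0.5 vs 0.6 → R = 5/6), 300 cells each, 2%
fail rate. What the simulator does not model: amplification-efficiency
differences between assays, correlated detection across genes within a
cell (bursting, cell size), plate/chip batch effects, or colony-size
effects when the unit is a colony rather than a cell. Passing tests
therefore validate the arithmetic and the statistical calibration of the
pipeline, not the biology of any particular dataset.

Processing: `Fail` → sentinel Ct = 999; a cell is dropped iff any
housekeeping assay is undetected or above the cutoff (a cell exactly at
the cutoff passes); expression is 2^−(Ct − h̄) with h̄ the arithmetic
mean of the cell's housekeeping Ct values (the one-gene panel is the
single-element case); undetected genes are 0 with a False detection flag.
The housekeeping cutoff is a required explicit parameter —
`suggest_hk_cutoff` proposes the deepest histogram valley between the two
largest modes (falling back to the 99.5th percentile when unimodal), but
the choice is always recorded rather than automatic, because the
histogram inspection it replaces is a judgment call. Per-gene outlier
removal is off by default; an optional rule drops detected values more
than k (default 5) scaled MADs from the gene median and itemises removals
in the QC report.

Genotype comparison per gene: two-sided Mann-Whitney rank-sum on the
2^−ΔCt values with zeros included (detection differences are part of the
expression difference), and a two-sided Fisher's exact test on the 2×2
detected/undetected table; the two p-values are combined by Fisher's
method. The rank-sum form is used even though the procedure is sometimes
labeled "signed-rank": a paired design is impossible across genotypes.
Tie handling and the exact-vs-normal switch follow scipy's
`mannwhitneyu(method="auto")` policy (exact for small tie-free samples,
mid-ranks + tie-corrected normal approximation with continuity correction
otherwise). Degenerate inputs are defined explicitly: an all-tied value
vector gives p = 1, as does a degenerate 2×2 table.

### Known limitation: dependence in the combined p-value

Fisher's method assumes independent p-values. Here the level and
frequency tests are computed from the same cells and are strongly
positively correlated under the null (the rank test "sees" the zero mass
that the frequency test counts; corr(ln p) ≈ 0.85 at detection 0.5), so
the combined p is anticonservative: at a nominal α = 0.05 the null
rejection rate is ≈ 0.08-0.10 rather than 0.05 (the acceptance suite
measures this). At detection → 1 the frequency test degenerates to p = 1
and the combination becomes strongly conservative instead. The
combination is reproduced as specified because it is the procedure under
study; users wanting calibrated combined inference should treat
`p_combined` as a ranking score or apply a dependence-aware combination.

## Frequency ratio

R = (mean over erythroid genes of the fraction of cells detecting the
gene) / (same mean over myeloid genes), the `gene_mean` definition; the
`pooled` alternative (total detections over cells×panel) coincides for
complete panels and is exposed because the operational definition behind
the published ratios is not fixed. R is undefined (NaN) when the myeloid
denominator is 0. The ratio choice is recorded in output metadata.

## Reproducibility and problem sizes

All generators and the Monte-Carlo test consume explicit integer seeds;
pipelines split one root seed into per-stage seeds via
`numpy.random.SeedSequence`, and every persisted artifact embeds the seed
and a hash of the configuration (excluding the output directory), so
re-running a config is byte-identical, Monte-Carlo stages included.

Validation problem sizes were chosen so the full suite runs in about two
minutes: 100 simulated transplantations at 3×50k reads for the power
check; Monte-Carlo agreement at M = 200,000 over 100 instances (instances
with exact tails below 2.5×10⁻⁴ are excluded as beneath Monte-Carlo
resolution at that M, and the agreement check uses the uncorrected
estimator against the exact tail); type-I calibration with 1,000
replicates of independent subsets of sizes (400, 380, 360) from the
725-pool — sizes large enough that the discrete null tail has an
achievable rejection level near 0.05, which smaller sets do not; and
1,000 simulated null genes for the combined-test calibration.
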