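# Methods

This note documents the models, parameter choices and numerical decisions
behind `cernet`, and what the synthetic validation does and does not show.

## Design under study

Two conditions — undifferentiated and differentiated preadipocytes — with
three biological replicates each, assayed three ways: lncRNA and mRNA
fragment counts (one RNA-seq library style) and miRNA tag counts
(small-RNA style). All inference is two-group, six-sample. With n = 6 the
Spearman correlation takes few distinct values (for tie-free vectors,
multiples of 1/105 shifted from 1), which shapes several choices below.

## Normalization

FPKM = 10⁹·C/(N·L) for lncRNA/mRNA; TPM = C/total × 10⁶ for miRNA
(length-free, as appropriate for ~22-nt tags). N is the per-sample column
total of the supplied matrix, since alignment is upstream of this package.
Annotated transcript length is used (no effective-length correction). No
pseudocounts at normalization time: zeros stay zeros. Between-sample
normalizations (TMM and relatives) are deliberately out of scope; on the
synthetic data library-size variation is exactly compositional and the
within-sample normalizations remove it.

Numerics: FPKM is computed as counts × (10⁹/(N·L)) so each cell incurs one
rounding beyond the division, and a matrix built from unit-cancelling
values reproduces the definition exactly. An all-zero sample column raises
a degenerate-input error rather than propagating NaNs.

## Differential expression

One record per gene: group means of normalized expression, log₂FC =
log₂((mean_case + c)/(mean_ctrl + c)) with pseudocount c = 1 (configurable;
c stabilizes the ratio when one group mean is near zero at three
replicates), a two-sided p-value, Benjamini–Hochberg FDR computed within
each biotype matrix (lncRNA, miRNA and mRNA are treated as three
experiments), and a strict gate: up iff FDR < 0.05 and log₂FC > 1, down
iff FDR < 0.05 and log₂FC < −1.

The default test is an **empirical-Bayes variance-moderated t** on
log₂(normalized expression + 1): per-gene pooled variances are shrunk
toward a scaled inverse-chi-square prior fitted across all genes by the
standard moment estimator on log sample variances (Newton solve of the
trigamma equation; when observed variances are less dispersed than pure
chi-square sampling noise, shrinkage is complete and the variance is
treated as known). The reason is power: with three replicates per group an
unmoderated per-gene t has ~4 denominator degrees of freedom, and in
simulation at the study conditions (dispersion 0.1, effect 2 log₂ units)
its post-FDR power is a few percent — the screen would find nothing.
Borrowing variance strength across genes is the standard small-n RNA-seq
remedy and restores ~98% power while staying calibrated on null data
(verified by test: per-seed fraction of p < 0.05 inside binomial 99%
bounds). A plain Welch t is available (`method="welch"`), and the test
backend accepts any callable, so an exact-NB backend can be swapped in.
Full NB GLM machinery (dispersion trends, TMM offsets) is intentionally
not re-implemented.

The control group is `undifferentiated` when that label is present,
otherwise the first label in sample order; passing `reference=` swaps the
contrast, which negates every log₂FC exactly and swaps the up/down sets.

## Correlation filters

Spearman rank correlation is computed over **all six samples pooled** —
with three samples per group, within-group correlation at these thresholds
is meaningless, and the pooled statistic is what the screen's |SCC| 0.7/0.9
gates presuppose. Predicted miRNA→target pairs (restricted to DE genes)
pass at SCC < −0.7; all DEL × DEM pairs are scored and pass at SCC > 0.9.
All comparisons are strict, following the screen's wording ("smaller
than", "greater than").

Numerics: ranks are computed with mean-rank ties; for tie-free vectors the
classical rank-difference identity 1 − 6Σd²/(n(n²−1)) is used, which is
exact in floating point for small integer ranks — a pair whose true
correlation sits exactly on a threshold compares exactly equal to it and
is rejected by the strict gate. A constant vector raises an error rather
than returning 0 or NaN.

## Shared-miRNA hypergeometric test

For a candidate lncRNA–mRNA pair, n = shared filter-passing miRNAs, M and
N = filter-passing miRNAs of the lncRNA and mRNA respectively, U = the
miRNA universe. The upper tail P(X ≥ n) is computed with exact integer
arithmetic (big-integer binomials summed over the tail and divided as a
rational), avoiding the cancellation of the 1 − Σ form; it agrees with
exhaustive draw enumeration to < 10⁻¹² everywhere tested. n = 0 returns 1.

Two open choices were resolved as follows:

* **U defaults to all assayed miRNAs** (the miRNA matrix's gene count),
  i.e. "the number of all miRNAs" in the method's own description;
  `universe="demis"` restricts it to the DE set. The DEMis-only choice has
  a degeneracy worth knowing about: disjoint planted triples give
  n = M = N = 1 and p = 1/U, so when U ≈ 20 the p-value sits exactly at
  the 0.05 gate and acceptance flips on single-gene fluctuations.
* **M and N are counted on the correlation-passed interaction sets**, not
  the raw predictions, because the screen combines target prediction and
  correlation before testing; counting on raw predictions is a one-line
  change in the caller.

The pair-level p is replicated onto each (lncRNA, shared miRNA, mRNA)
triple and gated at raw p < 0.05 (strict); no multiple-testing correction
is applied to this gate, matching the original screen.

## Network, hubs, crucial interactions

Accepted triples are rendered as an undirected tripartite graph with two
edge classes (lncRNA–miRNA, miRNA–mRNA; no direct lncRNA–mRNA edges).
Degree is counted on the deduplicated edge set. The average degree
2|E|/|V| is always recomputed from the network at hand; a published
average (e.g. 4.9 for the original study's full network) is a property of
that network, not a constant of the method. Hubs are nodes with degree
strictly above the average — so isolated nodes can never be hubs, and a
regular graph has none.

Crucial interactions are triples whose miRNA is (a) supplied in a
literature-flag list, or (b) a hub **and** highly expressed, with "highly
expressed" = mean TPM across all six samples strictly above 4.5 (per-group
means are a configuration away; the method description does not say which
samples to average). Exports are SIF plus node/edge tables, written in
lexicographic order for byte-stable reruns.

On the bundled 12-interaction published list, the recomputed counts are 12
triples, 7 lncRNAs, 4 miRNAs and **8** distinct mRNAs — the source text's
own tally says seven mRNAs, but its printed list contains eight, and this
package reports what the list yields. Similarly the deduplicated edge
count of that subnetwork is 16 (7 miRNA–lncRNA + 9 miRNA–mRNA).

## Over-representation

Generic hypergeometric over-representation against user-supplied GMT gene
sets, sharing the exact tail implementation above with
(n, M, N, U) = (k, K, n_query, N_bg). The background defaults to all genes
that entered DE testing for the relevant biotype; a database-bound
whole-genome background is out of scope. Significance follows the raw
p < 0.05 gate of the original screen; BH FDR is reported alongside but
does not gate — users preferring the stricter convention can filter on the
`fdr` column.

## Synthetic data generator

Counts are negative binomial, parameterized by mean and dispersion φ
(Var = μ + φμ²; default φ = 0.1, i.e. biological CV ≈ 0.32, typical for
cell-culture replicates). Gene baselines are lognormal around
`baseline_mean` = 200 (σ = 1.0); per-sample depths are drawn uniformly
from `library_size_range` (default 10⁵–2×10⁵ fragments per assay) and
scale all gene means in that sample, so depth variation is exactly what
the normalizations remove. Transcript lengths are uniform on 200–3000 bp;
miRNAs carry no length (TPM is length-free).

**Planted signal.** Each planted triple shifts group means by the effect
size (default 2 log₂ units): the miRNA by −Δ in the differentiated group
while its lncRNA and mRNA shift by +Δ, or the mirrored signs, chosen per
triple from the seed. Within a triple, counts are coupled through one
shared per-sample latent uniform: lncRNA and mRNA are comonotone and the
miRNA anti-comonotone via NB quantile coupling, so marginals remain
exactly NB(μ, φ) while the six-sample Spearman correlations land in the
regime the screen selects for. This coupling is essential, not cosmetic:
with independent NB noise, rank enumeration shows a perfectly
group-separated negative pair reaches SCC ≤ −0.7 only 75% of the time and
a positive pair reaches SCC > 0.9 only ~14% of the time at n = 6, so a
generator without within-group coupling cannot produce triples this screen
accepts at useful rates. Planted members draw their baselines with tighter
spread (σ = 0.5) — correlation-detectable ceRNA members are by assumption
quantifiably expressed.

The latent is **stratified within each group** (the three samples receive
the three equal-probability strata in seeded random order, one uniform per
stratum). Each marginal stays exactly NB; the stratification keeps
realized group means close to the planted means instead of letting a whole
triple drift to an attenuated fold change together, which is what couples
detection failures across a triple's three members otherwise.

Decoy interactions (default 5 per miRNA) are drawn uniformly over
non-planted targets; they are what the correlation filter must reject.
The truth sidecar records planted DE genes with directions, planted
triples, parameters, seed, and the realized per-sample library sizes
(column sums).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: per-triple coupling at full strength (real ceRNA
coupling is partial and confounded), no shared-factor structure across
different triples or batches, no length/GC biases, no zero inflation or
low-expression dropout among planted members, no uncertainty in the
interaction list beyond uniform decoys, and no partial overlap between
planted triples (they are disjoint by construction). Recovery rates on
this generator are a correctness check of the pipeline's selection logic,
not an estimate of sensitivity on real sequencing data.

## Determinism and problem sizes

Identical parameters (including seed) give byte-identical outputs: a
single `numpy` Generator drives the simulation, stage tables are written
with a fixed float format and stable ordering, and the pipeline manifest
records SHA-256 hashes of every output (no timestamps), so a rerun's
manifest is identical.

The validation suite runs at desk scale: the recovery sweep uses the
default generator (200/100/500 genes, 20 planted triples) over ten seeds,
exhaustive hypergeometric enumeration covers all parameter combinations
with U ≤ 12 (~3200 tail probabilities), and the Spearman oracle covers
1000 random vectors of length 3–29. The whole suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

* DE p-values come from a moderated t on log-normalized values, not an
  exact NB test; numerical equivalence with edgeR-style results is neither
  attainable (the test variant and normalization of the original analysis
  are unspecified) nor claimed.
* The dataset-scale results of the original study (235 DELs, 145 DEMis,
  660 DEMs, 251 triples, average degree 4.9) depend on undeposited
  sequencing data and tool versions and are not reproduction targets; the
  published-fixture checks cover the printed 12-interaction subnetwork
  only.
* The seed-match predictor (7-mer, positions 2–8, no wobble, no energy
  model) exists to exercise the pipeline on synthetic sequences, not to
  predict real miRNA targets.
* Interaction lists from multiple prediction tools are assumed already
  merged; no union/intersection policy is applied on ingestion.
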