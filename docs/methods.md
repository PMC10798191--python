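# Methods

## Phylogenetic model

Likelihoods are computed under time-reversible nucleotide models in GTR
parameterization (JC69, K80, HKY85 and GTR constructors provided). The
rate matrix is normalized so one unit of branch length equals one expected
substitution per site at stationarity; the fitted scales are therefore
dimensionless rate multipliers. Transition probabilities use the
symmetrized eigendecomposition of Q (exact for reversible models, stable
for extreme branch lengths); rows are clipped and renormalized to remove
≤1e-15 negative round-off. Column likelihoods use Felsenstein pruning
vectorized across columns, with per-column rescaling of partial
likelihoods so deep trees cannot underflow. Gaps (`-`), `N` and absent
species are all treated as missing data and marginalized, which keeps the
likelihood well defined for any species subset. The default model for the
synthetic pipeline is HKY85 with κ = 3 and π = (0.30, 0.20, 0.20, 0.30),
a generic mammalian-like composition; the neutral model is configuration,
not something the package estimates (neutral-model fitting is out of
scope).

The substitution model's role in each stage:

* conservation HMM: neutral emission at scale 1, conserved emission at
  scale ρ;
* acceleration null: one free element-wide scale *s* ∈ [1e-4, 20];
* acceleration alternative: *s* plus a branch multiplier λ ∈ [1, 20]
  applied multiplicatively on the designated target branch.

Scale fits maximize the log-likelihood over log-scale parameters with
bounded optimizers (Brent for 1-D; L-BFGS-B with a Nelder-Mead polish for
2-D, deterministic start at 1.0). The polish exists because L-BFGS-B
occasionally reports line-search failure when the optimum sits on the
λ = 1 boundary; the polished fit was verified to match 4-start Nelder-Mead
and dense local grid searches. Non-convergence after the polish flags the
element; flagged elements are excluded from FDR with a recorded reason.

## Conserved-element HMM

Two states (neutral, conserved) with switch probabilities
μ (conserved→neutral) and ν (neutral→conserved); the chain starts from its
stationary distribution. Defaults are ρ = 0.3, μ = 1/45 (expected element
length 45 bp) and ν = μ·0.3/0.7 (expected conserved coverage 0.3) — the
values commonly used in conservation scans; ρ, μ, ν are fixed inputs, not
estimated (no EM in this version). Elements are maximal runs of the
Viterbi conserved state; Viterbi ties break toward neutral, so exact ties
never produce spurious 1-bp elements. Element scores are the summed
per-column log-odds of conserved over neutral emission. Posterior
decoding (forward–backward in log space) is available for inspection; the
forward and backward total likelihoods agree to 1e-8 by construction.

The ≥ 90% species-presence filter is applied per alignment block; a
species counts as present only if it contributes at least one non-missing
base.

## Acceleration test

T = 2(lnL₁ − lnL₀) with the null distribution ½δ₀ + ½χ²₁, the standard
boundary mixture for one parameter tested at the edge of a one-sided
alternative; p = 1 when T ≤ 1e-8, else p = ½·P(χ²₁ ≥ T). Under null
simulations the fraction of λ̂ estimates at the boundary is ≈ 0.5 and the
rejection rate at 0.05 is 0.02–0.05 (slightly conservative), as the
mixture predicts. Elements with fewer than 10 informative columns are
flagged rather than tested (ML is unstable there). BH adjustment runs in
one family across all tested elements; the RECE cut is q ≤ 0.05
(inclusive) with Y-chromosome elements removed. The test targets a single
named branch — the tested hypothesis of the pipeline — with the branch
addressed by internal-node label or by the leaf set of its subtree;
testing a whole descendant subtree would be a straightforward extension
(every branch in the subtree scaled) but only the single-branch mode is
wired in.

## Synthetic data: what it emulates and what it does not

The default tree has 20 species (12 simiiform, 8 strepsirrhine) with a
labelled simiiform stem branch of 0.06 substitutions/site and total length
≈ 1.03, chosen to resemble a primate neutral tree; chromosomes are three
1 Mb autosome stand-ins plus a 200 kb "chrY" so the Y-removal rule is
exercised. Alignments are gap-free with species dropout applied per
(block, species), so alignment columns map 1:1 to reference coordinates;
real alignments add indels, alignment error and phylogenetic
misspecification that these fixtures deliberately omit. Peak sets are
placed so the element-overlap rate is an exact multiple of the
uniform-placement rate; loops wire gene-promoter anchors to distal
anchors, a configurable fraction of which are centred on elements, and the
emitted truth table is a brute-force enumeration over the emitted files
(so accidental overlaps are part of the truth, and target-gene recovery
can be checked for exact equality). Expression matrices put a per-unit-age
log2 trend β on a chosen gene set over a flat baseline with Gaussian
log-scale noise. Passing tests therefore demonstrate correctness of the
inference machinery under the generating model, not robustness to the
artifacts of real alignments, peak calling or RNA-seq normalization.

The coexpression-module generator builds a module profile as an age trend
plus an orthogonal "biological wiggle" (default weight 0.7, giving an
eigengene–age correlation of ~0.8) and makes ~40% of module genes genuine
profile-followers. Both choices are deliberate: real developmental
modules correlate with age imperfectly and are coherent by construction,
and with a perfectly age-aligned eigengene the two hub criteria
(p.MM < 0.05 and p.GS < 0.05) would collapse into a single test for noise
genes, making the planted-hub false-discovery behaviour degenerate.

All generator randomness flows from one seed through named substreams
(alignment, dropout, epigenome, expression, module), so identical
manifests are byte-identical and individual stages can be regenerated.

## Enrichment statistics

Control sets are length-multiset-matched to the query and placed uniformly
over the genome (chromosome chosen proportionally to the number of valid
start positions), optionally avoiding an exclusion BED; no GC or
chromatin matching. Overlap is ≥ 1 bp everywhere, and an element counts
once per category regardless of how many features it hits. The
permutation Fisher procedure reports the arithmetic mean of the
per-permutation two-sided p-values and sample odds ratios (Haldane 0.5
correction on zero cells) — the mean is statistically unconventional but
is the procedure as specified, so the median and central 95% quantiles are
reported alongside. The binomial test uses the mean control overlap
fraction as the null rate; a zero null rate with observed overlap is
reported as the limiting p ≈ 0 and flagged.

## Trajectories and hubs

"Expressed" means RPKM ≥ 1 in ≥ 10% of the region's samples (a documented
default; the field has no single convention). Background correction
subtracts the background median on the log2(x+1) scale; a ratio mode
exists behind a flag since the operation is sometimes read
multiplicatively. Eigengenes are unit-norm first right singular vectors
of the gene-standardized module matrix, sign-oriented so the correlation
with the mean standardized profile is non-negative; zero-variance genes
are dropped and reported. MM/GS use Pearson correlation with two-sided
t-based p-values; thresholds are strict inequalities. Numeric sample age
is used as given in the metadata (no log or rank transform).

## Problem sizes and numerical choices

The bundled benchmark experiments run: null calibration on 500 elements
(20 leaves × 200 bp each), sensitivity/FDR on 100 accelerated among 500,
element recovery over 50 replicates, enrichment with 1,000 control sets
(60 query elements, 1,000 peaks), and trajectory/hub recovery at 40
samples — sizes chosen so the whole suite completes in minutes on one CPU
while keeping Monte-Carlo error on the reported rates at the few-percent
level. Under these conditions the measured acceleration sensitivity sits
near 0.80 with single-replicate fluctuation of ±0.05–0.08; the empirical
FDR stays ≤ 0.05. Tolerances: likelihood oracle agreement 1e-8; JC69
closed form 1e-10; exact-test oracles 1e-10/1e-12; optimizer convergence
1e-6 in log-likelihood.

## Known limitations

No indel or context-dependent substitution modelling; no rate variation
across sites; no EM training of HMM parameters; controls are not
GC-matched; WGCNA network construction (soft threshold, TOM, tree cut) is
out of scope — module assignments are inputs; the CLI pipeline operates on
the synthetic manifest layout (tree/model/MAF/BED/BEDPE/TSV files in one
run directory).
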