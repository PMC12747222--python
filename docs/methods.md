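# Methods

This note documents the statistical models, estimators and numerical
choices implemented in `paleopop`, and what the synthetic-data generator
does and does not emulate.

## Genotype model and containers

All analyses operate on per-group derived-allele counts (x, n) per SNP,
where n counts *observed chromosomes*: 2 per covered diploid genotype, 1
per covered pseudo-haploid call. Pseudo-haploid calls represent a diploid
individual by a single randomly sampled allele per site — the standard
representation for low-coverage ancient DNA — and every estimator here is
written to be correct under that sampling. EIGENSTRAT text files are the
interchange format; the `.geno` digit counts reference-allele copies, and
pseudo-haploid columns use the conventional homozygote-like 0/2/9 coding
(a het digit on a pseudo-haploid individual is rejected as malformed).

Jackknife blocks are contiguous runs of at most 0.05 Morgan (5 Mb physical
fallback when no genetic map is present), never spanning chromosome
boundaries. Block size is a convention, not an estimate; 0.05 M is the
value commonly used with SNP-capture data.

## f-statistics

Group frequencies are p = x/n with no shrinkage. The per-SNP estimators

- f2(A,B) = (pA − pB)² − hA/nA − hB/nB, with h = p(1−p)·n/(n−1),
- f3(A;B,C) = (pA − pB)(pA − pC) − hA/nA,
- f4(A,B;C,D) = (pA − pB)(pC − pD),

are averaged within blocks and combined with a Busing-style weighted
delete-one-block jackknife (weights = usable SNPs per block), giving an
estimate, SE and Z. f4 is evaluated internally through its f2
decomposition, (f2(A,D) + f2(B,C) − f2(A,C) − f2(B,D))/2: the h/n
corrections cancel exactly for four distinct populations and remain
correct when a population is repeated across the two sides (needed by the
qpAdm matrix construction). Groups observed as a single chromosome at a
site (n = 1) have no defined h/n correction; the correction is skipped
there with a warning. In outgroup mode f3 omits the hA correction, the
convention for shared-drift (outgroup-f3) statistics.

Hudson Fst is the ratio-of-averages estimator: numerator the corrected
squared frequency difference, denominator pA(1−pB) + pB(1−pA), summed per
block and jackknifed as a ratio. Heterozygosity terms come from observed
chromosome counts, treating each sampled allele as a haploid lineage —
the "inbreed-aware" form that remains valid for pseudo-haploid data. A
floor of 5000 usable SNPs per pair is enforced by default. Large batches
of f4 Z-scores can be corrected with the Benjamini–Yekutieli step-up
(valid under arbitrary dependence); the adjusted score Z_BY is the signed
normal quantile of the adjusted two-sided p.

## qpWave and qpAdm

For left populations L and right references R, X[i,j] =
f4(L1, L_{i+1}; R1, R_{j+1}) measures shared drift between the sets; with
at most r gene-flow streams connecting them, X has rank r. The rank test
minimizes the jackknife-covariance-weighted quadratic form between X and a
rank-r factorization UVᵀ by alternating generalized least squares
(initialized from the SVD of X, relative-objective tolerance 1e−9, 500
iterations max), with (nL−1−r)(nR−1−r) degrees of freedom. Because the
covariance of vec(X) is itself estimated from a finite number B of
jackknife blocks, the asymptotic χ² reference is anticonservative at desk
scale; the test therefore applies the Hotelling-style small-sample mapping
stat·(B−d)/(d(B−1)) ~ F(d, B−d), which converges to the χ² tail as B
grows. Covariance matrices with condition number above 1e12 receive a
ridge of 1e−6·trace/dim.

qpAdm augments the left set with the target, [T, L1..Lk]. Under the
k-source model the augmented matrix has rank k−1 and the left null vector
of the fitted rank-(k−1) matrix, normalized to sum to one, is the weight
vector; SEs come from recomputing the weights on every delete-one-block
replicate and jackknifing. Weights outside [0,1] are returned with
`feasible=False` rather than clipped. The rotation scheme tries
single-source models first and adds sources only when no simpler model
passes (default p ≥ 0.05 and feasible); unused pool candidates rotate into
the references next to the fixed distal outgroups. Passing models sharing
a source can be pooled by inverse-variance meta-analysis. `allsnps`
(default on) lets every f4 entry use all SNPs where its own four
populations are observed; the alternative restricts all entries to the
common intersection.

## Admixture graphs

A graph is a rooted DAG: drift edges carry lengths in f2 units, admixture
nodes have two parents with weights (γ, 1−γ). Writing w_X(e) for the
admixture-weight mass of paths from leaf X through edge e (computed by an
upward sweep), expected f2(A,B) = Σ_e c_e (w_A(e) − w_B(e))², the
linearized drift algebra; all f3/f4 follow from the f2 basis. Fitting
minimizes the inverse-variance-weighted squared deviation between expected
and observed f2 over leaf pairs (block-jackknife variances, diagonal
weighting for speed) with L-BFGS-B under non-negativity/[0,1] bounds and
random multi-starts. A variance floor of (1e−3 × max|f2|)² keeps exact
noise-free inputs well conditioned. The reported `worst_residual` is the
largest |Z| over all implied f4 statistics.

Root placement is not identifiable from f2 between leaves: rooted variants
of one unrooted topology fit identically, so "recovery" means the
generating topology attains the minimum score (ties expected), and
searches report all tied optima. The topology hash is a
Weisfeiler–Lehman-style iterated refinement over parent and child
relations with leaf labels as seeds, invariant to internal relabeling and
to admixture-parent orientation; it is verified exhaustively to be
collision-free for ≤ 5 leaves (105 rooted topologies).

The randomized search starts each iteration from a random topology with
the requested number of admixture nodes and hill-climbs over four moves
(subtree regraft, leaf swap, admixture-edge relocation, orientation flip),
accepting only strict score improvements; results are deduplicated by
hash. Model comparison splits blocks in half, fits both graphs on one
half, scores them per evaluation block, and bootstraps the mean
out-of-sample score difference (two-sided p from the bootstrap tails);
fits are seeded from the topology hash so comparing a graph with itself is
exactly p = 1.

## Pseudo-haploid caller

Directed error rates E(a→b) are estimated from the sample's own reads at
sites assumed monomorphic, stratified by library type, SNP base pair, read
position (more than 10 bp from both read ends = central, ties to the 5′
class), strand, mapping quality (<30 / ≥30) and base quality (<20 / 20–29
/ ≥30). Thresholding a directed rate would bias calls (E(C,T) and E(T,C)
can differ greatly), so the symmetric S = max{E(a,b), E(b,a)} is
thresholded instead, at 0.02 by default; S is thus an upper bound on the
error of every base admitted to the reliable pileup. One reliable base is
drawn uniformly at random with an RNG keyed by (seed, chromosome,
position), making calls order-independent and reproducible under parallel
processing. Strata without observations are treated as failing the
threshold (no pooling or smoothing of sparse strata is attempted), and
bases matching neither SNP allele are never eligible. Libraries are
flagged as potentially contaminated when terminal C→T damage falls below
3% (UDG-treated) or 10% (untreated).

## Kinship from pairwise mismatch rates

Two unrelated pseudo-haploid individuals from one population mismatch at
b = mean 2p(1−p) over overlapping sites; sharing both haplotypes halves
the rate and sharing one haplotype over a fraction φ multiplies it by
(1 − φ/4), giving expected ratios 0.5, 0.75, 0.875, 0.9375 and 1.0 for
identical, 1st-, 2nd-, 3rd-degree and unrelated pairs. The baseline is
the median pair rate of the comparison set (robust to a few relatives);
within-individual replicate comparisons provide the identical-genome
anchor at b/2. Classification uses midpoints between successive expected
ratios (0.625, 0.8125, 0.90625 × b) and additionally requires the
estimate to sit ≥ 2 jackknife SEs below the unrelated boundary before a
relatedness call is asserted. Pairs overlapping at fewer than 5000 sites
are reported uninformative. Second-degree-or-closer pairs are flagged for
exclusion, keeping the higher-coverage member.

## ROH-based effective size

Within an individual, the two copies of a chromosome coalesce at time g ~
Exponential(mean 2Ne) generations; conditional on g, recombination breaks
the chromosome into segments at rate 2g per Morgan. On map length L the
expected number of segments of genetic length l is
[(L−l)(2g)² + 4g]·exp(−2gl) dl (interior plus chromosome-end segments).
Counts are binned into 8 log-spaced bins over the fit range (4–20 cM: 4 cM
is the calling floor of HMM-based ROH callers, segments >20 cM reflect
recent parental relatedness rather than Ne). The likelihood treats bin
counts as Poisson conditional on g and integrates g out numerically
(240-point log grid) chromosome by chromosome — a mixture form chosen
because several long segments co-occur on one recently coalesced
chromosome, and a marginal-intensity Poisson likelihood would be badly
overdispersion-misspecified, destroying CI calibration. The 1-D MLE in Ne
is found by bounded minimization in log Ne; the 95% CI is the
likelihood-ratio interval (drop of 1.92), with the upper bound flagged
unbounded when no segments fall in range. Fractional individual weights
(for individuals shared across groupings) multiply log-likelihood
contributions. The matched simulator draws one g per (individual,
chromosome) and Poisson breakpoints, retaining segments ≥ 4 cM; this is
the same law the estimator assumes, so parameter-recovery experiments test
estimator correctness, not model realism.

Eligibility rules mirror standard practice for these analyses: ≥ 400,000
covered SNPs; for Ne estimation also mean date ≤ 3000 BP and cumulative
ROH > 20 cM strictly below 50 cM (excludes recent inbreeding). Group
differences in Σ(ROH > 20 cM) use the tie-corrected Kruskal–Wallis test
followed by Conover–Iman pairwise tests with Benjamini–Hochberg adjustment
at FDR 0.05 (implemented here directly, validated against independent rank
computations); temporal trends in Σ(ROH 4–12 cM) use OLS on mean date for
individuals younger than 2500 BP, with constant responses reported as
degenerate (slope 0, p = 1).

## Structure summaries

Outgroup-f3 distances are 1/f3(O; P1, P2) (apex at the outgroup; an error
naming the pair is raised if any f3 ≤ 0, signalling an unsuitable
outgroup). Classical MDS is the Torgerson double-centering algorithm;
negative eigenvalues are reported and their axes suppressed, and each
axis is sign-fixed so its largest-magnitude coordinate is positive.
Neighbor joining is the Saitou–Nei algorithm with lexicographic
tie-breaking on equal Q; negative branch lengths are clamped to zero with
the deficit moved to the sibling edge, preserving pairwise path lengths,
and trees may be rooted on a chosen leaf's edge. Fst matrices are
clustered agglomeratively (scipy linkage; average linkage by default,
selectable — the appropriate linkage for Fst dendrograms is genuinely
ambiguous, so it is exposed rather than fixed) with dendrograms serialized
as Newick.

## Synthetic data: what it does and does not emulate

Frequencies evolve by Balding–Nichols drift (child ~ Beta with mean p and
variance F·p(1−p)) down an arbitrary rooted tree with admixture edges
(frequency mixing, optional residual drift), from ancestral frequencies
Uniform(0.05, 0.95) — bounded away from 0/1 to avoid monomorphic sites.
Balding–Nichols was chosen over explicit Wright–Fisher generations for its
closed-form drift parameterization and speed. Genotypes are unlinked
Bernoulli(p) pseudo-haploid calls with independent per-site missingness;
jackknife blocks are equal SNP-count contiguous runs; SNP metadata spreads
sites over 22 chromosomes and a ~35 Morgan map so default block assignment
behaves as on real data. Pileups carry per-read strand, position class,
MQ/BQ bins and library type, with biallelic error flips at stratified
rates. Related pairs share one or both haplotypes at the appropriate
genome fraction, sampled site-wise.

Not emulated: linkage disequilibrium within blocks (no coalescent with
recombination), sequence-level errors (no FASTQ), reference bias,
non-biallelic errors, and real ROH length correlations beyond the
constant-Ne renewal law. Passing tests therefore demonstrate estimator
correctness and calibration under the assumed sampling models, not
robustness to every artifact of empirical capture data.

## Problem sizes and determinism

Validation experiments default to 5×10⁴–2×10⁵ SNPs, 50–200 jackknife
blocks, 100–200 replicates for coverage/uniformity checks, and 40
individuals for Ne recovery — sizes at which every experiment completes
in seconds to a few minutes on one core while keeping Monte Carlo error
well inside the asserted bands. All stochastic stages take explicit seeds;
identical seeds give bit-identical outputs.

## Known limitations

- The ALS rank fit can in principle find a local optimum of the weighted
  low-rank problem; SVD initialization makes this rare at these sizes.
- The graph search is a stochastic hill-climb: with few iterations it can
  miss the global optimum on larger graphs (mitigated by many independent
  starts, as in the search protocol itself).
- The constant-Ne ROH likelihood is a composite approximation (segment
  counts on a chromosome are treated as Poisson given g); its CI coverage
  is verified by simulation at the default design, not proven.
- qpAdm SEs assume the delete-one-block weight replicates are well
  defined; nearly collinear sources inflate them and are reported rather
  than suppressed.
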